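"""Land/sea masking for sea-level-driven NoData patterns.

Glacial periods expose continental shelf that is under water today;
most of those pixels carry values for only one or two periods, so their
low dispersion is an artifact of the short record, not of climatic
stability.  The fix is to mask every output to the *current* land
surface, using the most recent period as template.  Conversely, a few
current-land pixels were submerged during high-sea-level (interglacial)
periods; those are kept in the index but flagged in a companion raster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster import Grid, RasterLayer, RasterStack, assert_aligned


@dataclass
class MaskLayer:
    """Binary raster: 1, 0 or NaN (NoData).

    ``semantics`` documents the polarity: a ``keep-mask`` keeps pixels
    where the value is 1; an ``affected-flag`` merely annotates them.
    """

    grid: Grid
    values: np.ndarray
    semantics: str = "keep-mask"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        finite = self.values[~np.isnan(self.values)]
        if not np.all(np.isin(finite, (0.0, 1.0))):
            raise ValueError("mask values must be 0, 1 or NoData")
        if self.semantics not in ("keep-mask", "affected-flag"):
            raise ValueError(f"unknown mask semantics {self.semantics!r}")

    @property
    def keep(self) -> np.ndarray:
        """Boolean array, True where the mask is exactly 1."""
        return self.values == 1.0

    def as_layer(self, variable_id: str = "mask") -> RasterLayer:
        """View as a RasterLayer for writing (uint8 on disk)."""
        return RasterLayer(self.grid, self.values, variable_id=variable_id,
                           units="dimensionless")


def build_land_mask(template: RasterLayer) -> MaskLayer:
    """Current-land keep-mask from a present-day template layer.

    1 where the template holds a value (current land), 0 where it is
    NoData (current sea, including once-emerged shelf).
    """
    values = np.where(template.valid_mask, 1.0, 0.0)
    return MaskLayer(template.grid, values, semantics="keep-mask")


def apply_land_mask(layer: RasterLayer, mask: MaskLayer) -> RasterLayer:
    """NoData-out every pixel the keep-mask does not keep.  Idempotent."""
    assert_aligned([layer, mask])
    out = np.where(mask.keep, layer.values, np.nan)
    return layer.with_values(out)


def flag_interglacial_affected(stacks: list[RasterStack],
                               warm_period_ids: list[str],
                               mask: MaskLayer) -> MaskLayer:
    """Flag current-land pixels submerged during any warm period.

    1 where the pixel is land (mask = 1) and NoData in at least one
    warm-period layer of any stack; 0 on other land; NoData off-land.
    The flag annotates — it never removes pixels from the index.
    """
    if not stacks:
        raise ValueError("need at least one stack")
    assert_aligned([s.layers[0] for s in stacks] + [mask])
    known = set()
    for s in stacks:
        known.update(s.period_ids)
    unknown = set(warm_period_ids) - known
    if unknown:
        raise ValueError(f"unknown warm period ids: {sorted(unknown)}")

    submerged = np.zeros(mask.grid.shape, dtype=bool)
    for stack in stacks:
        for layer in stack.layers:
            if layer.period_id in warm_period_ids:
                submerged |= ~layer.valid_mask
    values = np.where(mask.keep,
                      np.where(submerged, 1.0, 0.0),
                      np.nan)
    return MaskLayer(mask.grid, values, semantics="affected-flag")
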