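"""Index composition: normalization, summation, categories, histogram.

The Climate Stability Index for a map set is the per-pixel sum of the
selected variables' normalized dispersion layers, rescaled once more to
[0, 1].  0 marks the most climatically stable pixels, 1 the most
unstable.  Per-variable normalization before the sum is essential:
raw dispersions mix Celsius and millimetres, and precipitation
magnitudes would otherwise dominate the index.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .raster import RasterLayer, assert_aligned


@dataclass
class CSIResult:
    """Final index layer plus the provenance needed to reproduce it."""

    csi: RasterLayer
    provenance: dict = field(default_factory=dict)


@dataclass(frozen=True)
class BreakScheme:
    """Ascending category boundaries over [0, 1].

    ``breaks`` holds the *upper* boundary of each category; the last
    must be 1.  Category i covers (breaks[i-1], breaks[i]], with the
    first category closed at 0.
    """

    breaks: tuple[float, ...]

    def __post_init__(self) -> None:
        b = tuple(float(x) for x in self.breaks)
        object.__setattr__(self, "breaks", b)
        if len(b) < 1:
            raise ValueError("need at least one break")
        if any(b2 <= b1 for b1, b2 in zip(b, b[1:])) or b[0] <= 0:
            raise ValueError("breaks must be strictly ascending in (0, 1]")
        if b[-1] != 1.0:
            raise ValueError("last break must be 1.0")

    @property
    def n_categories(self) -> int:
        return len(self.breaks)

    @classmethod
    def equal_interval(cls, n_categories: int) -> "BreakScheme":
        """n equal-width categories over [0, 1]."""
        if n_categories < 1:
            raise ValueError("n_categories must be >= 1")
        return cls(tuple(np.linspace(0.0, 1.0, n_categories + 1)[1:]))

    @classmethod
    def with_top_break(cls, n_categories: int,
                       top_lower: float) -> "BreakScheme":
        """Equal-width categories below ``top_lower`` plus one top
        category (top_lower, 1].

        Mimics histogram-adjusted ramps where the uppermost category is
        widened to absorb the sparse right tail (e.g. top bin 0.71-1 for
        a past map set, 0.356-1 for a future one).
        """
        if not (0.0 < top_lower < 1.0):
            raise ValueError("top_lower must be in (0, 1)")
        lower = np.linspace(0.0, top_lower, n_categories)[1:]
        return cls(tuple(lower) + (1.0,))


def normalize01(layer: RasterLayer) -> RasterLayer:
    """Min-max rescale the valid pixels to [0, 1]; NoData preserved.

    A constant layer cannot be spread over [0, 1]; it becomes all zeros
    (maximally stable) with a warning.
    """
    valid = layer.valid_mask
    if not valid.any():
        raise ValueError("cannot normalize an all-NoData layer")
    vals = layer.values
    lo = float(np.nanmin(vals))
    hi = float(np.nanmax(vals))
    if hi == lo:
        warnings.warn(f"layer {layer.variable_id!r} is constant; "
                      f"normalized output set to 0 everywhere",
                      stacklevel=2)
        out = np.where(valid, 0.0, np.nan)
    else:
        out = (vals.astype(np.float64) - lo) / (hi - lo)
        out = np.where(valid, out, np.nan)
    return layer.with_values(out)


def compose_csi(sd_layers: Mapping[str, RasterLayer],
                kept: Sequence[str]) -> CSIResult:
    """Sum the kept normalized dispersion layers and rescale to [0, 1].

    NoData propagation is strict: a pixel missing in any kept layer is
    NoData in the index, because a partial sum over fewer variables is
    not comparable across pixels.
    """
    if not kept:
        raise ValueError("kept variable list is empty")
    missing = [k for k in kept if k not in sd_layers]
    if missing:
        raise KeyError(f"kept variables without a layer: {missing}")
    layers = [sd_layers[k] for k in kept]
    assert_aligned(layers)
    total = np.sum([l.values.astype(np.float64) for l in layers], axis=0)
    summed = RasterLayer(layers[0].grid, total, variable_id="csi",
                         units="dimensionless")
    csi = normalize01(summed)
    return CSIResult(csi=csi, provenance={"kept": list(kept)})


def categorize(csi: RasterLayer, scheme: BreakScheme) -> RasterLayer:
    """Map index values to integer categories 1..n via half-open bins
    (lower-exclusive, upper-inclusive; first bin closed at 0)."""
    vals = csi.values
    valid = csi.valid_mask
    v = vals[valid]
    if v.size and (v.min() < 0 or v.max() > 1):
        raise ValueError("index values must lie in [0, 1]")
    cat = np.searchsorted(np.asarray(scheme.breaks, dtype=np.float32),
                          vals, side="left") + 1
    out = np.where(valid, cat.astype(np.float64), np.nan)
    return RasterLayer(csi.grid, out, variable_id="category",
                       units="dimensionless")


def histogram(layer: RasterLayer, n_bins: int) -> pd.DataFrame:
    """Equal-width histogram of the valid values over [0, 1].

    Returns a frame with columns ``bin_lower``, ``bin_upper``,
    ``count``; empty bins appear with count 0 and counts sum to the
    number of valid pixels.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if layer.n_valid == 0:
        raise ValueError("histogram of an all-NoData layer")
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    counts, _ = np.histogram(layer.valid_values(), bins=edges)
    return pd.DataFrame({"bin_lower": edges[:-1], "bin_upper": edges[1:],
                         "count": counts})
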