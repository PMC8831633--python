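"""Robustness validation: pairwise Pearson comparison of index maps.

The index involves three methodological choices — dispersion statistic
(SD vs range), ensemble reducer (mean vs median) and collinearity
threshold (0.7 / 0.8 / 0.9).  The validation harness recomputes the
index for every combination, correlates each relevant pair of maps over
their jointly valid pixels, and reports a three-category matrix:

* ``SD vs range``     — past map set, per threshold;
* ``mean vs median``  — future map sets, per SSP and threshold;
* ``threshold (r)``   — all threshold pairs within one configuration.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConstantLayerError, InsufficientPixelsError
from .raster import RasterLayer, assert_aligned

CATEGORY_SD_RANGE = "SD vs range"
CATEGORY_MEAN_MEDIAN = "mean vs median"
CATEGORY_THRESHOLD = "threshold (r)"


@dataclass
class ValidationMatrix:
    """Rows of (category, pair label, r) plus the configs compared."""

    rows: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        expected = ["category", "pair", "r"]
        if list(self.rows.columns[:3]) != expected:
            raise ValueError(f"rows must have columns {expected}")
        r = self.rows["r"].to_numpy()
        if np.any((r < -1 - 1e-12) | (r > 1 + 1e-12)):
            raise ValueError("correlation values must lie in [-1, 1]")

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False)

    def to_json(self) -> str:
        import json
        return json.dumps({"rows": self.rows.to_dict(orient="records"),
                           "metadata": self.metadata}, indent=2)


def compare_maps(a: RasterLayer, b: RasterLayer) -> float:
    """Pearson r over the pixels valid in both layers.

    Requires >= 3 jointly valid pixels; a layer constant on the joint
    domain makes r undefined and raises.
    """
    assert_aligned([a, b])
    ok = a.valid_mask & b.valid_mask
    if ok.sum() < 3:
        raise InsufficientPixelsError(
            "need >= 3 jointly valid pixels to correlate maps")
    x = a.values[ok].astype(np.float64)
    y = b.values[ok].astype(np.float64)
    for layer, v in ((a, x), (b, y)):
        if np.ptp(v) == 0:
            raise ConstantLayerError(
                f"layer {layer.variable_id!r} is constant on the jointly "
                f"valid domain")
    return float(np.corrcoef(x, y)[0, 1])


def scatter_sample(a: RasterLayer, b: RasterLayer, n: int,
                   seed: int) -> np.ndarray:
    """(n, 2) array of jointly valid value pairs for external
    scatterplots, drawn without replacement, deterministic per seed."""
    assert_aligned([a, b])
    ok = a.valid_mask & b.valid_mask
    rows, cols = np.nonzero(ok)
    if n > rows.size:
        raise InsufficientPixelsError(
            f"requested {n} pairs but only {rows.size} jointly valid "
            f"pixels exist")
    rng = np.random.default_rng(seed)
    idx = rng.choice(rows.size, size=n, replace=False)
    r, c = rows[idx], cols[idx]
    return np.column_stack([a.values[r, c], b.values[r, c]]).astype(np.float64)


def run_validation(past_csi: dict[tuple[str, float], RasterLayer] | None,
                   future_csi: dict[tuple[str, str, float], RasterLayer] | None = None,
                   *, thresholds: tuple[float, ...] = (0.7, 0.8, 0.9),
                   metadata: dict | None = None) -> ValidationMatrix:
    """Assemble the three-category comparison matrix from precomputed
    index maps.

    Parameters
    ----------
    past_csi : mapping (statistic, threshold) -> index layer
        Statistics are "sd" and/or "range".
    future_csi : mapping (ssp, reducer, threshold) -> index layer
        Reducers are "mean" and/or "median".
    thresholds : thresholds present in the sweep, in ascending order.

    Rows follow the fixed structure: SD-vs-range per threshold, then
    mean-vs-median per SSP and threshold, then every threshold pair
    within each configuration.
    """
    past_csi = past_csi or {}
    future_csi = future_csi or {}
    rows: list[dict] = []

    def add(category: str, label: str, a: RasterLayer,
            b: RasterLayer) -> None:
        rows.append({"category": category, "pair": label,
                     "r": compare_maps(a, b)})

    past_stats = sorted({s for s, _ in past_csi})
    if {"sd", "range"} <= set(past_stats):
        for th in thresholds:
            add(CATEGORY_SD_RANGE,
                f"CSI-past SD th {th} vs. CSI-past range th {th}",
                past_csi[("sd", th)], past_csi[("range", th)])

    ssps = sorted({s for s, _, _ in future_csi})
    reducers_by_ssp = {
        ssp: sorted({r for s, r, _ in future_csi if s == ssp})
        for ssp in ssps}
    for ssp in ssps:
        if {"mean", "median"} <= set(reducers_by_ssp[ssp]):
            for th in thresholds:
                add(CATEGORY_MEAN_MEDIAN,
                    f"CSI-future mean {ssp} th {th} vs. "
                    f"CSI-future median {ssp} th {th}",
                    future_csi[(ssp, "mean", th)],
                    future_csi[(ssp, "median", th)])

    th_pairs = list(itertools.combinations(thresholds, 2))
    for stat in past_stats:
        for t1, t2 in th_pairs:
            add(CATEGORY_THRESHOLD,
                f"CSI-past {stat.upper() if stat == 'sd' else stat} "
                f"th {t1} vs. th {t2}",
                past_csi[(stat, t1)], past_csi[(stat, t2)])
    for ssp in ssps:
        for reducer in reducers_by_ssp[ssp]:
            for t1, t2 in th_pairs:
                add(CATEGORY_THRESHOLD,
                    f"CSI-future {reducer} {ssp} th {t1} vs. th {t2}",
                    future_csi[(ssp, reducer, t1)],
                    future_csi[(ssp, reducer, t2)])

    frame = pd.DataFrame(rows, columns=["category", "pair", "r"])
    return ValidationMatrix(rows=frame, metadata=metadata or {})
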