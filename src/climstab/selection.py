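"""Collinearity-based variable selection.

Bioclimatic variables are heavily redundant (annual mean temperature
tracks the warmest- and coldest-quarter means, precipitation totals
track their wettest-quarter subsets, ...).  Summing redundant layers
would double-count one climatic signal, so before composing the index
we: sample random land pixels, build the pairwise Pearson matrix over
the candidate layers at those points, link any two variables whose
|r| exceeds a threshold, take connected components as "groups of
correlated variables", and keep one randomly chosen representative per
group.  Both random draws are seeded and logged.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import ConstantLayerError, InsufficientPixelsError
from .masking import MaskLayer
from .raster import RasterLayer, assert_aligned


@dataclass(frozen=True)
class SelectionConfig:
    """Settings of the collinearity screen.

    Defaults follow common practice for bioclim pruning: 10,000 sample
    points, Pearson correlation, cut-off |r| > 0.8.  ``use_absolute``
    treats strong negative correlation as equally redundant; set False
    to link on signed r > threshold only.
    """

    n_points: int = 10_000
    method: str = "pearson"
    r_threshold: float = 0.8
    use_absolute: bool = True
    sampling_seed: int = 0
    selection_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.r_threshold < 1.0):
            raise ValueError("r_threshold must be in (0, 1)")
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.method != "pearson":
            raise ValueError("only Pearson correlation is supported")


@dataclass
class SelectionResult:
    """Everything needed to audit / replay one selection run."""

    sampled_points: np.ndarray          # (n, 2) array of (row, col)
    corr_matrix: pd.DataFrame           # symmetric, diagonal 1
    groups: list[list[str]]             # partition of the variable ids
    kept: list[str]
    config: SelectionConfig

    def to_json(self) -> str:
        payload = {
            "sampled_points": self.sampled_points.tolist(),
            "variables": list(self.corr_matrix.columns),
            "corr_matrix": self.corr_matrix.to_numpy().tolist(),
            "groups": self.groups,
            "kept": self.kept,
            "config": dataclasses.asdict(self.config),
        }
        return json.dumps(payload, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "SelectionResult":
        d = json.loads(text)
        corr = pd.DataFrame(np.asarray(d["corr_matrix"]),
                            index=d["variables"], columns=d["variables"])
        return cls(sampled_points=np.asarray(d["sampled_points"], dtype=int),
                   corr_matrix=corr, groups=d["groups"], kept=d["kept"],
                   config=SelectionConfig(**d["config"]))


def sample_points(mask: MaskLayer, n_points: int,
                  seed: int) -> np.ndarray:
    """``n_points`` distinct pixel coordinates drawn uniformly without
    replacement from mask=1 pixels.  Deterministic given ``seed``.

    Raises :class:`InsufficientPixelsError` rather than silently
    shrinking the sample.
    """
    rows, cols = np.nonzero(mask.keep)
    n_valid = rows.size
    if n_valid < n_points:
        raise InsufficientPixelsError(
            f"requested {n_points} sample points but the mask has only "
            f"{n_valid} valid pixels")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n_valid, size=n_points, replace=False)
    return np.column_stack([rows[idx], cols[idx]])


def correlation_matrix(layers: list[RasterLayer],
                       points: np.ndarray) -> pd.DataFrame:
    """Pairwise Pearson matrix of the layers at the sampled points.

    Point pairs where either layer is NoData are dropped pairwise.  A
    layer constant at its evaluated points makes r undefined and raises
    :class:`ConstantLayerError` naming the layer.
    """
    if len(layers) < 2:
        raise ValueError("need >= 2 layers for a correlation matrix")
    assert_aligned(layers)
    names = [l.variable_id for l in layers]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate variable ids: {names}")
    pts = np.asarray(points, dtype=int)
    samples = np.stack([l.values[pts[:, 0], pts[:, 1]] for l in layers])

    n = len(layers)
    corr = np.eye(n)
    for i in range(n):
        for j in range(i + 1, n):
            x, y = samples[i], samples[j]
            ok = ~(np.isnan(x) | np.isnan(y))
            if ok.sum() < 2:
                raise InsufficientPixelsError(
                    f"fewer than 2 jointly valid points for "
                    f"{names[i]} vs {names[j]}")
            xv, yv = x[ok].astype(np.float64), y[ok].astype(np.float64)
            for name, v in ((names[i], xv), (names[j], yv)):
                if np.ptp(v) == 0:
                    raise ConstantLayerError(
                        f"layer {name!r} is constant at the sampled "
                        f"points; Pearson r is undefined")
            r = np.corrcoef(xv, yv)[0, 1]
            corr[i, j] = corr[j, i] = r
    return pd.DataFrame(corr, index=names, columns=names)


def correlated_groups(corr: pd.DataFrame, r_threshold: float,
                      use_absolute: bool = True) -> list[list[str]]:
    """Partition variables into connected components of the exceedance
    graph (edge iff |r| > threshold, or signed r with
    ``use_absolute=False``).

    Components are the minimal closure of pairwise exceedance and do
    not depend on variable order.  Groups come back sorted by first
    member, members sorted within each group.
    """
    names = list(corr.columns)
    r = corr.to_numpy(dtype=float)
    strength = np.abs(r) if use_absolute else r
    adj = strength > r_threshold
    np.fill_diagonal(adj, False)
    n_comp, labels = connected_components(csr_matrix(adj), directed=False)
    groups = [[] for _ in range(n_comp)]
    for name, lab in zip(names, labels):
        groups[lab].append(name)
    groups = [sorted(g, key=names.index) for g in groups]
    return sorted(groups, key=lambda g: names.index(g[0]))


def select_variables(groups: list[list[str]], seed: int) -> list[str]:
    """One uniformly random representative per group, deterministic
    given ``seed``.  Singleton groups are kept verbatim."""
    if not groups:
        raise ValueError("empty partition")
    rng = np.random.default_rng(seed)
    return [group[int(rng.integers(len(group)))] for group in groups]


def select_uncorrelated(layers: list[RasterLayer], mask: MaskLayer,
                        config: SelectionConfig) -> SelectionResult:
    """Full screen: sample, correlate, group, pick representatives."""
    points = sample_points(mask, config.n_points, config.sampling_seed)
    corr = correlation_matrix(layers, points)
    groups = correlated_groups(corr, config.r_threshold,
                               config.use_absolute)
    kept = select_variables(groups, config.selection_seed)
    return SelectionResult(sampled_points=points, corr_matrix=corr,
                           groups=groups, kept=kept, config=config)
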