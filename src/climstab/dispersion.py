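"""Per-pixel temporal dispersion and GCM ensemble reduction.

The stability signal of the index is the amount of per-pixel variation a
bioclimatic variable shows across time periods.  Two dispersion
statistics are supported: the sample standard deviation (the default)
and the range (max minus min).  For future map sets, each variable x
period is first collapsed across its available general circulation
models with a per-pixel median (or mean).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .raster import EnsembleCube, RasterLayer, RasterStack


@dataclass(frozen=True)
class DispersionConfig:
    """How temporal dispersion is computed.

    Parameters
    ----------
    statistic : {"sd", "range"}
        Sample standard deviation (denominator n-1) or max-min range.
    min_valid : int
        Minimum number of non-NoData periods a pixel needs; pixels with
        fewer become NoData.  At least 2 — dispersion of a single value
        is meaningless and, for once-emerged shelf pixels, badly biased.
    """

    statistic: str = "sd"
    min_valid: int = 2

    def __post_init__(self) -> None:
        if self.statistic not in ("sd", "range"):
            raise ValueError(f"statistic must be 'sd' or 'range', got "
                             f"{self.statistic!r}")
        if self.min_valid < 2:
            raise ValueError("min_valid must be >= 2")


@dataclass(frozen=True)
class EnsembleConfig:
    """How the GCM ensemble is collapsed per pixel.

    ``median`` is the headline choice; ``mean`` exists for the
    robustness comparison.  Either way only available members enter —
    a model absent for an SSP x period is skipped, never imputed.
    """

    reducer: str = "median"

    def __post_init__(self) -> None:
        if self.reducer not in ("median", "mean"):
            raise ValueError(f"reducer must be 'median' or 'mean', got "
                             f"{self.reducer!r}")


def _masked_reduce(cube: np.ndarray, func, min_valid: int) -> np.ndarray:
    """Apply a nan-aware reducer along axis 0, blanking pixels with
    fewer than ``min_valid`` finite entries."""
    cube = np.asarray(cube, dtype=np.float64)   # float32 accumulation drifts
    n_valid = np.sum(~np.isnan(cube), axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        out = func(cube)
    out = np.asarray(out, dtype=np.float32)
    out[n_valid < min_valid] = np.nan
    return out


def pixelwise_sd(stack: RasterStack,
                 config: DispersionConfig = DispersionConfig()) -> RasterLayer:
    """Sample standard deviation of each pixel across the stack's periods.

    Pixels with fewer than ``config.min_valid`` valid periods are NoData.
    """
    if len(stack) < 2:
        raise ValueError("dispersion needs a stack of >= 2 layers")
    cube = stack.as_array()
    out = _masked_reduce(cube, lambda c: np.nanstd(c, axis=0, ddof=1),
                         config.min_valid)
    return RasterLayer(stack.grid, out, variable_id="sd",
                       period_id=_span(stack), units=stack.layers[0].units)


def pixelwise_range(stack: RasterStack,
                    config: DispersionConfig = DispersionConfig()
                    ) -> RasterLayer:
    """Per-pixel max minus min across the stack's periods."""
    if len(stack) < 2:
        raise ValueError("dispersion needs a stack of >= 2 layers")
    cube = stack.as_array()
    out = _masked_reduce(
        cube, lambda c: np.nanmax(c, axis=0) - np.nanmin(c, axis=0),
        config.min_valid)
    return RasterLayer(stack.grid, out, variable_id="range",
                       period_id=_span(stack), units=stack.layers[0].units)


def pixelwise_dispersion(stack: RasterStack,
                         config: DispersionConfig) -> RasterLayer:
    """Dispatch on ``config.statistic``."""
    if config.statistic == "sd":
        return pixelwise_sd(stack, config)
    return pixelwise_range(stack, config)


def ensemble_reduce(cube: EnsembleCube,
                    config: EnsembleConfig = EnsembleConfig()
                    ) -> RasterLayer:
    """Collapse an ensemble cube to one layer per pixel.

    A pixel is NoData only where no available member has a value; with a
    partial ensemble the median/mean runs over whatever members are
    valid there.
    """
    arr = cube.as_array()
    func = np.nanmedian if config.reducer == "median" else np.nanmean
    out = _masked_reduce(arr, lambda c: func(c, axis=0), min_valid=1)
    member = next(iter(cube.members.values()))
    return RasterLayer(cube.grid, out, variable_id=cube.variable_id,
                       period_id=cube.period_id, units=member.units)


def _span(stack: RasterStack) -> str:
    p = stack.period_ids
    return f"{p[0]}..{p[-1]}" if len(p) > 1 else p[0]
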