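"""Core raster data model: grid, layer, stack, ensemble cube, catalog.

All layers in a workflow must live on one shared geographic grid; nothing
here resamples or reprojects.  Grids that differ — in shape, transform
(beyond 1e-9 degrees), CRS tag or NoData sentinel — are an error, because
silent resampling would corrupt every per-pixel statistic downstream.

NoData convention: in memory, value layers are float arrays with ``NaN``
marking NoData; the sentinel stored in :class:`Grid` is only used on disk.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import GridAlignmentError

#: Disk sentinel used when synthesizing layers: a -3.4e38-class float,
#: far outside any plausible temperature or precipitation value, stored
#: float32-exact so it round-trips through the GDAL_NODATA ASCII tag.
DEFAULT_NODATA = float(np.float32(-3.3e38))

#: Transform comparison tolerance, in degrees.  Grids from one product
#: family are expected to be bit-identical; anything looser hides bugs.
TRANSFORM_ATOL = 1e-9


@dataclass(frozen=True)
class Grid:
    """The shared spatial frame every layer must match.

    ``transform`` follows the GDAL geotransform convention
    ``(origin_x, pixel_width, row_rot, origin_y, col_rot, pixel_height)``
    with ``pixel_height`` negative for north-up rasters.  Units are
    degrees (geographic CRS assumed).
    """

    n_rows: int
    n_cols: int
    transform: tuple[float, float, float, float, float, float]
    crs_tag: str = "EPSG:4326"
    nodata_value: float = DEFAULT_NODATA

    def __post_init__(self) -> None:
        if self.n_rows <= 0 or self.n_cols <= 0:
            raise ValueError(f"grid shape must be positive, got "
                             f"{self.n_rows}x{self.n_cols}")
        if len(self.transform) != 6:
            raise ValueError("transform must have 6 elements")
        if self.transform[1] == 0 or self.transform[5] == 0:
            raise ValueError("pixel width and height must be nonzero")
        object.__setattr__(self, "transform",
                           tuple(float(t) for t in self.transform))

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @classmethod
    def regular(cls, n_rows: int, n_cols: int, *,
                origin: tuple[float, float] = (-180.0, 90.0),
                resolution: float = 2.5 / 60.0,
                crs_tag: str = "EPSG:4326",
                nodata_value: float = DEFAULT_NODATA) -> "Grid":
        """North-up axis-aligned grid with square pixels.

        The default resolution is 2.5 arc-min, the grain of typical
        global bioclim distributions.
        """
        ox, oy = origin
        return cls(n_rows, n_cols,
                   (ox, resolution, 0.0, oy, 0.0, -resolution),
                   crs_tag=crs_tag, nodata_value=nodata_value)

    def differing_field(self, other: "Grid") -> str | None:
        """Name of the first field where ``other`` deviates, or None."""
        if self.shape != other.shape:
            return "shape"
        t0 = np.asarray(self.transform)
        t1 = np.asarray(other.transform)
        if np.any(np.abs(t0 - t1) > TRANSFORM_ATOL):
            return "transform"
        if self.crs_tag != other.crs_tag:
            return "crs_tag"
        a, b = self.nodata_value, other.nodata_value
        if not (a == b or (np.isnan(a) and np.isnan(b))):
            return "nodata_value"
        return None

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Grid):
            return NotImplemented
        return self.differing_field(other) is None

    def __hash__(self) -> int:
        return hash((self.n_rows, self.n_cols, self.crs_tag))


@dataclass
class RasterLayer:
    """One variable's field at one time period.

    ``values`` is a float array of ``grid`` shape with NaN at NoData
    cells; NoData is excluded from every statistic in the package.
    """

    grid: Grid
    values: np.ndarray
    variable_id: str
    period_id: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.shape != self.grid.shape:
            raise ValueError(
                f"values shape {self.values.shape} does not match grid "
                f"shape {self.grid.shape}")

    @property
    def valid_mask(self) -> np.ndarray:
        """Boolean array, True where the pixel holds a value."""
        return ~np.isnan(self.values)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_values(self) -> np.ndarray:
        """1-D array of the valid pixel values."""
        return self.values[self.valid_mask]

    def with_values(self, values: np.ndarray, *,
                    variable_id: str | None = None,
                    period_id: str | None = None,
                    units: str | None = None) -> "RasterLayer":
        """Copy of this layer with new pixel values (same grid)."""
        return RasterLayer(
            self.grid, values,
            variable_id=self.variable_id if variable_id is None else variable_id,
            period_id=self.period_id if period_id is None else period_id,
            units=self.units if units is None else units)


@dataclass
class RasterStack:
    """Ordered time series of one variable: >=2 layers, unique periods,
    all on one grid (enforced at construction)."""

    grid: Grid
    layers: list[RasterLayer]

    def __post_init__(self) -> None:
        if not self.layers:
            raise ValueError("stack needs at least one layer")
        assert_aligned([l for l in self.layers], reference_grid=self.grid)
        periods = [l.period_id for l in self.layers]
        if len(set(periods)) != len(periods):
            raise ValueError(f"duplicate period ids in stack: {periods}")
        var_ids = {l.variable_id for l in self.layers}
        if len(var_ids) != 1:
            raise ValueError(f"stack mixes variables: {sorted(var_ids)}")

    @classmethod
    def from_layers(cls, layers: Sequence[RasterLayer]) -> "RasterStack":
        return cls(layers[0].grid, list(layers))

    @property
    def variable_id(self) -> str:
        return self.layers[0].variable_id

    @property
    def period_ids(self) -> list[str]:
        return [l.period_id for l in self.layers]

    def __len__(self) -> int:
        return len(self.layers)

    def layer(self, period_id: str) -> RasterLayer:
        for l in self.layers:
            if l.period_id == period_id:
                return l
        raise KeyError(f"period {period_id!r} not in stack "
                       f"({self.period_ids})")

    def as_array(self) -> np.ndarray:
        """(n_periods, n_rows, n_cols) float array, NaN at NoData."""
        return np.stack([l.values for l in self.layers])


@dataclass
class EnsembleCube:
    """GCM ensemble for one variable at one future period.

    ``members`` maps GCM name to layer for *available* members only;
    ``availability`` records every roster GCM, so absent models are
    visible (and skipped, never imputed).
    """

    grid: Grid
    variable_id: str
    period_id: str
    members: dict[str, RasterLayer]
    availability: dict[str, bool] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(
                f"cube {self.variable_id}/{self.period_id} has no "
                f"available members")
        for name in self.members:
            self.availability.setdefault(name, True)
        for name, avail in self.availability.items():
            if avail and name not in self.members:
                raise ValueError(f"GCM {name!r} marked available but has "
                                 f"no layer")
            if not avail and name in self.members:
                raise ValueError(f"GCM {name!r} marked absent but a layer "
                                 f"was supplied")
        assert_aligned(list(self.members.values()),
                       reference_grid=self.grid)

    @property
    def available_members(self) -> list[str]:
        return sorted(self.members)

    @property
    def n_available(self) -> int:
        return len(self.members)

    def as_array(self) -> np.ndarray:
        """(n_available, n_rows, n_cols) array in sorted member order."""
        return np.stack([self.members[m].values
                         for m in self.available_members])


@dataclass
class VariableCatalog:
    """Which bioclim variables exist at which periods for a map set.

    The catalog drives behavior: a variable missing from some periods is
    excluded from index calculation for that map set, never silently
    filled in.
    """

    map_set: str
    periods: list[str]
    entries: dict[str, list[str]]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.map_set not in ("past", "future"):
            raise ValueError(f"map_set must be 'past' or 'future', got "
                             f"{self.map_set!r}")
        for var, pers in self.entries.items():
            unknown = set(pers) - set(self.periods)
            if unknown:
                raise ValueError(f"{var}: unknown periods {sorted(unknown)}")

    def fully_available(self) -> list[str]:
        """Variables present in every period (usable for the index)."""
        full = set(self.periods)
        return sorted((v for v, p in self.entries.items()
                       if set(p) == full),
                      key=_bio_sort_key)

    def partially_absent(self) -> list[str]:
        full = set(self.periods)
        return sorted((v for v, p in self.entries.items()
                       if set(p) != full),
                      key=_bio_sort_key)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "VariableCatalog":
        return cls(**json.loads(text))


def _bio_sort_key(var: str):
    """bio2 before bio10; non-bio names sort after, alphabetically."""
    if var.startswith("bio") and var[3:].isdigit():
        return (0, int(var[3:]), var)
    return (1, 0, var)


def assert_aligned(layers: Iterable[RasterLayer | "MaskLayerLike"],
                   reference_grid: Grid | None = None) -> None:
    """Verify all layers share one grid; raise naming the first offender.

    Every multi-layer operation in the package calls this before
    touching pixels.
    """
    layers = list(layers)
    if not layers:
        raise ValueError("assert_aligned needs at least one layer")
    ref = reference_grid if reference_grid is not None else layers[0].grid
    for i, layer in enumerate(layers):
        bad = ref.differing_field(layer.grid)
        if bad is not None:
            name = getattr(layer, "variable_id", "?")
            period = getattr(layer, "period_id", "")
            label = f"{name}/{period}" if period else name
            raise GridAlignmentError(
                f"layer {i} ({label}) is misaligned: field {bad!r} "
                f"differs from the reference grid")


class MaskLayerLike:  # pragma: no cover - typing aid only
    grid: Grid
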