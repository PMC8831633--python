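"""Synthetic raster worlds with known statistical structure.

Real inputs for a stability index are global bioclim grids: one layer
per variable x time period (x GCM for future scenarios).  This module
fabricates worlds of the same shape whose properties are *planted* and
therefore checkable:

* spatially autocorrelated fields (smoothing-kernel filtered white
  noise) — real climatologies are smooth, and the SD-vs-range
  robustness check depends on that;
* controllable inter-variable correlation: variables in a declared
  block share a latent amplitude field, mixed with independent noise at
  an analytically derived ratio, so their dispersion maps correlate at
  a known target |r|;
* temporal drift plus per-period noise;
* sea-level NoData patterns: shelf pixels valid only in glacial
  (low-sea-level) periods, and low-lying land pixels missing in warm
  (high-sea-level) periods;
* a GCM roster with per-SSP x period availability gaps.

Worlds are bit-identical under a fixed master seed; every derived
per-purpose seed is logged in the truth record.

The fields are Gaussian, so "precipitation" can dip below zero; the
index only consumes dispersions, which are unaffected.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .geotiff import write_geotiff
from .raster import (EnsembleCube, Grid, RasterLayer, RasterStack,
                     VariableCatalog, _bio_sort_key)

#: Units of the standard bioclim variables.
VARIABLE_UNITS = {
    **{f"bio{i}": "degC" for i in (1, 2, 4, 5, 6, 7, 8, 9, 10, 11)},
    "bio3": "dimensionless", "bio15": "dimensionless",
    **{f"bio{i}": "mm" for i in (12, 13, 14, 16, 17, 18, 19)},
}

ALL_VARIABLES = tuple(f"bio{i}" for i in range(1, 20))

#: Past map set: twelve time slices, Pliocene analogue (T1) to the
#: Anthropocene (T12).  Low-sea-level (glacial) and high-sea-level
#: (warm) slices mirror the structure of paleoclimate archives.
PAST_PERIODS = tuple(f"T{i}" for i in range(1, 13))
WARM_PERIODS = ("T2", "T4", "T10")
GLACIAL_PERIODS = ("T1", "T3", "T5", "T6", "T7", "T8", "T9")

#: Five early-epoch variables missing from the oldest paleo slices.
PAST_ABSENT = {v: ("T1", "T2", "T3")
               for v in ("bio2", "bio3", "bio5", "bio6", "bio7")}

FUTURE_PERIODS = ("1970-2000", "2021-2040", "2041-2060", "2061-2080",
                  "2081-2100")
PRESENT_PERIOD = FUTURE_PERIODS[0]

GCM_ROSTER = ("BCC-CSM2-MR", "CNRM-CM6-1", "CNRM-ESM2-1", "CanESM5",
              "GFDL-ESM4", "IPSL-CM6A-LR", "MIROC-ES2L", "MIROC6",
              "MRI-ESM2-0")
SSPS = ("SSP1-2.6", "SSP2-4.5", "SSP3-7.0", "SSP5-8.5")

#: (ssp, period) -> GCMs without published output there.
GCM_UNAVAILABLE = {
    ("SSP2-4.5", "2021-2040"): ("GFDL-ESM4", "IPSL-CM6A-LR"),
    ("SSP5-8.5", "2021-2040"): ("GFDL-ESM4", "MRI-ESM2-0"),
    ("SSP2-4.5", "2041-2060"): ("GFDL-ESM4",),
    ("SSP5-8.5", "2041-2060"): ("GFDL-ESM4",),
    ("SSP2-4.5", "2061-2080"): ("GFDL-ESM4",),
    ("SSP5-8.5", "2061-2080"): ("GFDL-ESM4",),
    ("SSP2-4.5", "2081-2100"): ("GFDL-ESM4",),
    ("SSP5-8.5", "2081-2100"): ("GFDL-ESM4",),
}

# per-unit field parameters: (mean offset, mean spread, dispersion amp)
_UNIT_PARAMS = {"degC": (12.0, 6.0, 2.0),
                "mm": (900.0, 350.0, 120.0),
                "dimensionless": (40.0, 12.0, 6.0)}


@dataclass(frozen=True)
class WorldSpec:
    """Declarative description of a synthetic world.

    ``correlation_blocks`` lists (members, target |r|): the dispersion
    maps of block members will correlate pairwise at roughly the target
    (shared-latent construction, exact in expectation).  Fractions are
    of all grid pixels.
    """

    map_set: str = "past"
    n_rows: int = 80
    n_cols: int = 120
    variables: tuple[str, ...] = ALL_VARIABLES
    periods: tuple[str, ...] = ()
    correlation_blocks: tuple[tuple[tuple[str, ...], float], ...] = (
        (("bio1", "bio10", "bio11"), 0.95),
        (("bio12", "bio13", "bio16"), 0.95),
    )
    absent: dict = field(default_factory=dict)
    warm_period_ids: tuple[str, ...] = WARM_PERIODS
    glacial_period_ids: tuple[str, ...] = GLACIAL_PERIODS
    land_fraction: float = 0.65
    glacial_only_fraction: float = 0.05
    warm_submerged_fraction: float = 0.04
    temporal_amplitude: float = 1.0
    drift_amplitude: float = 0.5
    noise_sd: float = 0.1
    gcm_noise_sd: float = 0.05
    smoothing_sigma: float = 3.0
    gcms: tuple[str, ...] = GCM_ROSTER
    ssps: tuple[str, ...] = SSPS
    gcm_unavailable: dict = field(default_factory=lambda: dict(GCM_UNAVAILABLE))
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.map_set not in ("past", "future"):
            raise ValueError("map_set must be 'past' or 'future'")
        if not self.periods:
            default = PAST_PERIODS if self.map_set == "past" else FUTURE_PERIODS
            object.__setattr__(self, "periods", default)
        if not self.absent and self.map_set == "past":
            object.__setattr__(self, "absent",
                               {k: v for k, v in PAST_ABSENT.items()
                                if k in self.variables})
        seen: set[str] = set()
        for members, r in self.correlation_blocks:
            if not members:
                raise ValueError("empty correlation block")
            if not (0.0 < r < 1.0):
                raise ValueError(f"block target |r| must be in (0,1), "
                                 f"got {r}")
            overlap = seen & set(members)
            if overlap:
                raise ValueError(f"correlation blocks overlap: "
                                 f"{sorted(overlap)}")
            unknown = set(members) - set(self.variables)
            if unknown:
                raise ValueError(f"block members not in variables: "
                                 f"{sorted(unknown)}")
            seen |= set(members)
        if not (0 < self.land_fraction < 1):
            raise ValueError("land_fraction must be in (0, 1)")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["gcm_unavailable"] = {"|".join(k): list(v)
                                for k, v in self.gcm_unavailable.items()}
        return json.dumps(d, indent=2, default=list)

    @classmethod
    def from_json(cls, text: str) -> "WorldSpec":
        d = json.loads(text)
        d["variables"] = tuple(d["variables"])
        d["periods"] = tuple(d["periods"])
        d["correlation_blocks"] = tuple(
            (tuple(m), float(r)) for m, r in d["correlation_blocks"])
        for key in ("warm_period_ids", "glacial_period_ids", "gcms",
                    "ssps"):
            d[key] = tuple(d[key])
        d["absent"] = {k: tuple(v) for k, v in d["absent"].items()}
        d["gcm_unavailable"] = {
            tuple(k.split("|")) if isinstance(k, str) else tuple(k): tuple(v)
            for k, v in d["gcm_unavailable"].items()}
        return cls(**d)


@dataclass
class SyntheticWorld:
    """A generated world: inputs for one map set plus the truth record."""

    spec: WorldSpec
    grid: Grid
    template: RasterLayer
    catalog: VariableCatalog
    stacks: dict[str, RasterStack] = field(default_factory=dict)
    present: dict[str, RasterLayer] = field(default_factory=dict)
    cubes: dict = field(default_factory=dict)   # ssp -> var -> period -> cube
    truth: dict = field(default_factory=dict)

    def write(self, directory: str | Path) -> None:
        """Materialize the world as a GeoTIFF tree plus JSON sidecars.

        Layout: ``<var>_<period>.tif`` for past stacks and present
        layers, ``<var>_<period>_<gcm>.tif`` for ensemble members,
        ``template.tif``, ``catalog.json``, ``worldspec.json``,
        ``truth.json``.
        """
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        write_geotiff(self.template, directory / "template.tif")
        for var, stack in self.stacks.items():
            for layer in stack.layers:
                write_geotiff(layer, directory / f"{var}_{layer.period_id}.tif")
        for var, layer in self.present.items():
            write_geotiff(layer, directory / f"{var}_{layer.period_id}.tif")
        for ssp, by_var in self.cubes.items():
            for var, by_period in by_var.items():
                for period, cube in by_period.items():
                    for gcm, layer in cube.members.items():
                        write_geotiff(
                            layer,
                            directory / f"{var}_{period}_{gcm}.tif")
        if self.cubes:
            availability = {}
            for ssp, by_var in self.cubes.items():
                first_var = next(iter(by_var))
                availability[ssp] = {
                    period: cube.available_members
                    for period, cube in by_var[first_var].items()}
            (directory / "availability.json").write_text(
                json.dumps(availability, indent=2))
        (directory / "catalog.json").write_text(self.catalog.to_json())
        (directory / "worldspec.json").write_text(self.spec.to_json())
        truth = {k: v for k, v in self.truth.items()
                 if k not in ("amplitude_fields", "elevation")}
        (directory / "truth.json").write_text(
            json.dumps(truth, indent=2, default=list))


class _SeedLog:
    """Named, logged seeds derived from one master seed."""

    def __init__(self, master_seed: int) -> None:
        self._root = np.random.SeedSequence(master_seed)
        self.log: dict[str, int] = {}

    def rng(self, name: str) -> np.random.Generator:
        child = self._root.spawn(1)[0]
        seed = int(child.generate_state(1)[0])
        self.log[name] = seed
        return np.random.default_rng(seed)


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Standardized low-pass-filtered white noise (wrap-around edges)."""
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="wrap")
    return (f - f.mean()) / f.std()


def make_catalog(spec: WorldSpec) -> VariableCatalog:
    """Variable availability per period, honoring ``spec.absent``."""
    entries = {
        var: [p for p in spec.periods
              if p not in spec.absent.get(var, ())]
        for var in spec.variables}
    units = {var: VARIABLE_UNITS.get(var, "dimensionless")
             for var in spec.variables}
    return VariableCatalog(map_set=spec.map_set,
                           periods=list(spec.periods),
                           entries=entries, units=units)


def make_world(spec: WorldSpec) -> SyntheticWorld:
    """Generate the world: template, stacks (past) or present layers
    plus ensemble cubes (future), catalog and truth record."""
    shape = (spec.n_rows, spec.n_cols)
    grid = Grid.regular(*shape, origin=(-60.0, 30.0), resolution=0.05)
    seeds = _SeedLog(spec.master_seed)
    sigma = spec.smoothing_sigma

    # --- geography -------------------------------------------------------
    elevation = _smooth_field(seeds.rng("elevation"), shape, sigma)
    t_land = float(np.quantile(elevation, 1.0 - spec.land_fraction))
    land = elevation >= t_land
    if spec.map_set == "past" and spec.glacial_only_fraction > 0:
        t_glacial = float(np.quantile(
            elevation, 1.0 - spec.land_fraction - spec.glacial_only_fraction))
        glacial_band = (elevation >= t_glacial) & ~land
    else:
        glacial_band = np.zeros(shape, dtype=bool)
    if spec.map_set == "past" and spec.warm_submerged_fraction > 0:
        t_warm = float(np.quantile(
            elevation, 1.0 - spec.land_fraction + spec.warm_submerged_fraction))
        warm_band = land & (elevation < t_warm)
    else:
        warm_band = np.zeros(shape, dtype=bool)

    template = RasterLayer(
        grid, np.where(land, elevation, np.nan),
        variable_id="template", period_id=spec.periods[-1])

    # --- latent block fields --------------------------------------------
    block_latent: dict[str, np.ndarray] = {}
    block_target: dict[str, float] = {}
    for bi, (members, r) in enumerate(spec.correlation_blocks):
        latent = _smooth_field(seeds.rng(f"block:{bi}"), shape, sigma)
        for var in members:
            block_latent[var] = latent
            block_target[var] = r

    catalog = make_catalog(spec)
    included = catalog.fully_available()

    # --- per-variable structure -----------------------------------------
    amplitude: dict[str, np.ndarray] = {}
    mean_field: dict[str, np.ndarray] = {}
    profiles: dict[str, np.ndarray] = {}
    n_periods = len(spec.periods)
    lin = (np.arange(n_periods) / max(n_periods - 1, 1)) - 0.5
    for var in spec.variables:
        rng = seeds.rng(f"field:{var}")
        own = _smooth_field(rng, shape, sigma)
        if var in block_latent:
            r = block_target[var]
            g = np.sqrt(r) * block_latent[var] + np.sqrt(1.0 - r) * own
        else:
            g = own
        offset, spread, amp = _UNIT_PARAMS[
            VARIABLE_UNITS.get(var, "dimensionless")]
        amplitude[var] = amp * np.clip(1.0 + 0.35 * g, 0.1, None)
        mean_field[var] = offset + spread * _smooth_field(rng, shape, sigma)
        z = rng.standard_normal(n_periods)
        z = (z - z.mean()) / z.std()
        profiles[var] = (spec.temporal_amplitude * z
                         + spec.drift_amplitude * lin)

    def base_values(var: str, t: int,
                    noise_rng: np.random.Generator) -> np.ndarray:
        noise = spec.noise_sd * _smooth_field(noise_rng, shape, sigma)
        return (mean_field[var]
                + amplitude[var] * (profiles[var][t] + noise))

    world = SyntheticWorld(spec=spec, grid=grid, template=template,
                           catalog=catalog)

    if spec.map_set == "past":
        valid_by_period = {}
        for p in spec.periods:
            valid = land.copy()
            if p in spec.warm_period_ids:
                valid &= ~warm_band
            if p in spec.glacial_period_ids:
                valid |= glacial_band
            valid_by_period[p] = valid
        for var in included:
            rng = seeds.rng(f"noise:{var}")
            layers = []
            for t, p in enumerate(spec.periods):
                vals = base_values(var, t, rng)
                vals = np.where(valid_by_period[p], vals, np.nan)
                layers.append(RasterLayer(
                    grid, vals, variable_id=var, period_id=p,
                    units=VARIABLE_UNITS.get(var, "dimensionless")))
            world.stacks[var] = RasterStack.from_layers(layers)
    else:
        future_windows = [p for p in spec.periods if p != PRESENT_PERIOD]
        for var in included:
            rng = seeds.rng(f"noise:{var}")
            bases = {p: base_values(var, t, rng)
                     for t, p in enumerate(spec.periods)}
            present_vals = np.where(land, bases[PRESENT_PERIOD], np.nan)
            world.present[var] = RasterLayer(
                grid, present_vals, variable_id=var,
                period_id=PRESENT_PERIOD,
                units=VARIABLE_UNITS.get(var, "dimensionless"))
            for ssp in spec.ssps:
                by_var = world.cubes.setdefault(ssp, {})
                by_period = by_var.setdefault(var, {})
                gcm_rng = seeds.rng(f"gcm:{ssp}:{var}")
                for p in future_windows:
                    na = set(spec.gcm_unavailable.get((ssp, p), ()))
                    members = {}
                    availability = {}
                    for gcm in spec.gcms:
                        availability[gcm] = gcm not in na
                        # burn one field per roster slot so availability
                        # gaps do not shift later members' noise
                        noise = spec.gcm_noise_sd * _smooth_field(
                            gcm_rng, shape, sigma)
                        if gcm in na:
                            continue
                        vals = np.where(land,
                                        bases[p] + amplitude[var] * noise,
                                        np.nan)
                        members[gcm] = RasterLayer(
                            grid, vals, variable_id=var, period_id=p,
                            units=VARIABLE_UNITS.get(var, "dimensionless"))
                    by_period[p] = EnsembleCube(
                        grid, variable_id=var, period_id=p,
                        members=members, availability=availability)

    world.truth = {
        "seeds": seeds.log,
        "included_variables": included,
        "expected_groups": _expected_groups(spec, included),
        "n_land": int(land.sum()),
        "n_glacial_only": int(glacial_band.sum()),
        "n_warm_submerged": int(warm_band.sum()),
        "elevation": elevation,
        "amplitude_fields": amplitude,
    }
    return world


def _expected_groups(spec: WorldSpec,
                     included: list[str]) -> list[list[str]]:
    """Planted partition over the included variables, ordered the way
    ``correlated_groups`` orders its output for bio-sorted layers."""
    order = {v: i for i, v in
             enumerate(sorted(included, key=_bio_sort_key))}
    in_block: set[str] = set()
    groups = []
    for members, _ in spec.correlation_blocks:
        present = sorted((m for m in members if m in order),
                         key=order.get)
        if len(present) >= 2:
            groups.append(present)
            in_block |= set(present)
        elif present:            # a lone survivor is a singleton
            groups.append(present)
            in_block |= set(present)
    for var in sorted(set(included) - in_block, key=_bio_sort_key):
        groups.append([var])
    return sorted(groups, key=lambda g: order[g[0]])
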