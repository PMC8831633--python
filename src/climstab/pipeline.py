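"""End-to-end workflows: past and future map sets, plus the sweep.

Two orchestration levels live here.  The in-memory functions
(:func:`compute_past_csi`, :func:`compute_future_csi`,
:func:`validation_sweep`) take raster objects and return results; the
disk-level :func:`run_pipeline` wraps them with file layout, preflight
checks, Data-Records-style output naming and a JSON run manifest that
suffices to reproduce the run bit-for-bit.

Past workflow order: per-variable temporal dispersion -> current-land
mask -> per-variable [0,1] normalization -> collinearity selection ->
summation and final normalization.  The future workflow first collapses
each variable x period ensemble across its available GCMs, prepends the
present-day layer, then follows the same chain.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .compose import CSIResult, compose_csi, histogram, normalize01
from .dispersion import (DispersionConfig, EnsembleConfig,
                         ensemble_reduce, pixelwise_dispersion)
from .errors import PreflightError
from .geotiff import read_geotiff, write_geotiff
from .masking import (MaskLayer, apply_land_mask, build_land_mask,
                      flag_interglacial_affected)
from .raster import (EnsembleCube, RasterLayer, RasterStack,
                     VariableCatalog, _bio_sort_key)
from .selection import SelectionConfig, SelectionResult, select_uncorrelated
from .synthetic import PRESENT_PERIOD, WARM_PERIODS
from .validation import ValidationMatrix, run_validation

log = logging.getLogger("climstab.pipeline")


@dataclass
class MapSetResult:
    """Outcome of one workflow run on one map set."""

    csi: CSIResult
    selection: SelectionResult
    sd_raw: dict[str, RasterLayer]
    sd_norm: dict[str, RasterLayer]
    land_mask: MaskLayer
    interglacial_flag: MaskLayer | None = None
    member_counts: dict = field(default_factory=dict)


def _sorted_vars(d) -> list[str]:
    return sorted(d, key=_bio_sort_key)


def compute_past_csi(stacks: dict[str, RasterStack],
                     template: RasterLayer, *,
                     statistic: str = "sd",
                     r_threshold: float = 0.8,
                     n_points: int = 10_000,
                     sampling_seed: int = 0,
                     selection_seed: int = 0,
                     min_valid: int = 2,
                     warm_period_ids: tuple[str, ...] = WARM_PERIODS,
                     ) -> MapSetResult:
    """Past map set: dispersion across the time slices of each variable,
    masked to current land, normalized, pruned for collinearity and
    summed into the index."""
    disp_cfg = DispersionConfig(statistic=statistic, min_valid=min_valid)
    land_mask = build_land_mask(template)

    sd_raw: dict[str, RasterLayer] = {}
    sd_norm: dict[str, RasterLayer] = {}
    for var in _sorted_vars(stacks):
        disp = pixelwise_dispersion(stacks[var], disp_cfg)
        masked = apply_land_mask(disp, land_mask)
        masked.variable_id = var      # keep the source variable visible
        sd_raw[var] = masked
        sd_norm[var] = normalize01(masked)

    known_periods = set()
    for s in stacks.values():
        known_periods.update(s.period_ids)
    warm = tuple(p for p in warm_period_ids if p in known_periods)
    flag = flag_interglacial_affected(list(stacks.values()), list(warm),
                                      land_mask) if warm else None

    sel_cfg = SelectionConfig(n_points=n_points, r_threshold=r_threshold,
                              sampling_seed=sampling_seed,
                              selection_seed=selection_seed)
    layers = [sd_norm[v] for v in _sorted_vars(sd_norm)]
    selection = select_uncorrelated(layers, land_mask, sel_cfg)

    result = compose_csi(sd_norm, selection.kept)
    result.provenance.update({
        "map_set": "past", "statistic": statistic,
        "r_threshold": r_threshold,
        "sampling_seed": sampling_seed,
        "selection_seed": selection_seed,
        "groups": selection.groups,
    })
    return MapSetResult(csi=result, selection=selection, sd_raw=sd_raw,
                        sd_norm=sd_norm, land_mask=land_mask,
                        interglacial_flag=flag)


def reduce_ensembles(cubes: dict[str, dict[str, EnsembleCube]],
                     present: dict[str, RasterLayer],
                     reducer: str = "median",
                     period_order: list[str] | None = None,
                     ) -> tuple[dict[str, RasterStack], dict]:
    """Collapse every variable x period cube, prepend the present
    layer, and return per-variable time stacks plus member counts."""
    ens_cfg = EnsembleConfig(reducer=reducer)
    stacks: dict[str, RasterStack] = {}
    member_counts: dict[str, dict[str, int]] = {}
    for var in _sorted_vars(cubes):
        by_period = cubes[var]
        order = period_order or sorted(by_period)
        layers = [present[var]]
        counts = {}
        for period in order:
            cube = by_period[period]
            layers.append(ensemble_reduce(cube, ens_cfg))
            counts[period] = cube.n_available
        stacks[var] = RasterStack.from_layers(layers)
        member_counts[var] = counts
    return stacks, member_counts


def compute_future_csi(cubes: dict[str, dict[str, EnsembleCube]],
                       present: dict[str, RasterLayer],
                       template: RasterLayer, *,
                       reducer: str = "median",
                       statistic: str = "sd",
                       r_threshold: float = 0.8,
                       n_points: int = 10_000,
                       sampling_seed: int = 0,
                       selection_seed: int = 0,
                       min_valid: int = 2,
                       period_order: list[str] | None = None,
                       ) -> MapSetResult:
    """Future map set for one SSP: ensemble reduction per variable x
    period, then the same dispersion/normalize/select/sum chain."""
    stacks, member_counts = reduce_ensembles(cubes, present, reducer,
                                             period_order)
    result = compute_past_csi(stacks, template, statistic=statistic,
                              r_threshold=r_threshold, n_points=n_points,
                              sampling_seed=sampling_seed,
                              selection_seed=selection_seed,
                              min_valid=min_valid, warm_period_ids=())
    result.member_counts = member_counts
    result.csi.provenance.update({"map_set": "future", "reducer": reducer})
    return result


def validation_sweep(past_world=None, future_world=None, *,
                     statistics: tuple[str, ...] = ("sd", "range"),
                     reducers: tuple[str, ...] = ("median", "mean"),
                     thresholds: tuple[float, ...] = (0.7, 0.8, 0.9),
                     ssps: tuple[str, ...] | None = None,
                     n_points: int = 10_000,
                     sampling_seed: int = 0,
                     selection_seed: int = 0,
                     min_valid: int = 2) -> ValidationMatrix:
    """Compute the index for every sweep cell (shared seeds throughout)
    and assemble the three-category robustness matrix."""
    past_csi = {}
    if past_world is not None:
        for stat in statistics:
            for th in thresholds:
                res = compute_past_csi(
                    past_world.stacks, past_world.template,
                    statistic=stat, r_threshold=th, n_points=n_points,
                    sampling_seed=sampling_seed,
                    selection_seed=selection_seed, min_valid=min_valid,
                    warm_period_ids=past_world.spec.warm_period_ids)
                past_csi[(stat, th)] = res.csi.csi
                log.info("past CSI done: statistic=%s threshold=%s",
                         stat, th)

    future_csi = {}
    if future_world is not None:
        sweep_ssps = ssps or tuple(future_world.cubes)
        order = [p for p in future_world.spec.periods
                 if p != PRESENT_PERIOD]
        for ssp in sweep_ssps:
            for reducer in reducers:
                stacks, _ = reduce_ensembles(
                    future_world.cubes[ssp], future_world.present,
                    reducer, order)
                for th in thresholds:
                    res = compute_past_csi(
                        stacks, future_world.template, statistic="sd",
                        r_threshold=th, n_points=n_points,
                        sampling_seed=sampling_seed,
                        selection_seed=selection_seed,
                        min_valid=min_valid, warm_period_ids=())
                    future_csi[(ssp, reducer, th)] = res.csi.csi
                    log.info("future CSI done: ssp=%s reducer=%s "
                             "threshold=%s", ssp, reducer, th)

    meta = {"statistics": list(statistics), "reducers": list(reducers),
            "thresholds": list(thresholds),
            "n_points": n_points, "sampling_seed": sampling_seed,
            "selection_seed": selection_seed}
    return run_validation(past_csi, future_csi, thresholds=thresholds,
                          metadata=meta)


# --------------------------------------------------------------------------
# disk-level runner
# --------------------------------------------------------------------------

@dataclass
class RunConfig:
    """One reproducible pipeline run over a GeoTIFF input tree.

    ``map_set`` is ``"past"`` or ``"future:<SSP>"``.  The input
    directory must contain ``catalog.json`` plus layers named
    ``<var>_<period>.tif`` (and ``<var>_<period>_<gcm>.tif`` with an
    ``availability.json`` for future runs) and a ``template.tif``.
    """

    map_set: str
    input_dir: str
    output_dir: str
    statistic: str = "sd"
    reducer: str = "median"
    r_threshold: float = 0.8
    n_points: int = 10_000
    sampling_seed: int = 0
    selection_seed: int = 0
    min_valid: int = 2
    warm_period_ids: tuple[str, ...] = WARM_PERIODS
    template_file: str = "template.tif"

    def __post_init__(self) -> None:
        self.warm_period_ids = tuple(self.warm_period_ids)
        if not (self.map_set == "past"
                or self.map_set.startswith("future:")):
            raise ValueError("map_set must be 'past' or 'future:<SSP>'")

    @property
    def ssp(self) -> str | None:
        if self.map_set.startswith("future:"):
            return self.map_set.split(":", 1)[1]
        return None


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _preflight(paths: dict[str, Path]) -> dict[str, str]:
    """Verify every referenced input exists before any computation;
    return checksums keyed by logical name."""
    missing = [str(p) for p in paths.values() if not p.is_file()]
    if missing:
        raise PreflightError(
            f"{len(missing)} referenced input file(s) missing, e.g. "
            f"{missing[:5]}")
    return {name: _sha256(p) for name, p in sorted(paths.items())}


def run_pipeline(config: RunConfig) -> MapSetResult:
    """Execute the configured workflow and write the output file set.

    Outputs (past): ``sd_past_<bio>.tif`` (raw dispersion, masked),
    ``sd_past_<bio>_norm.tif``, ``csi_past.tif``,
    ``intergl_affected.tif`` (flag, 1 = land submerged in a warm
    period), ``lgm_del_mask.tif`` (keep-mask, 1 = current land),
    ``csi_past_histogram.csv``, ``selection.json``,
    ``corr_matrix.csv``, ``manifest.json``.  Future runs write the
    ``sd_future_<SSP>_<bio>.tif`` / ``csi_future_<SSP>.tif`` analogues.
    """
    in_dir = Path(config.input_dir)
    out_dir = Path(config.output_dir)
    catalog_path = in_dir / "catalog.json"
    if not catalog_path.is_file():
        raise PreflightError(f"missing catalog: {catalog_path}")
    catalog = VariableCatalog.from_json(catalog_path.read_text())
    included = catalog.fully_available()
    if not included:
        raise PreflightError("catalog lists no fully available variables")

    paths: dict[str, Path] = {"template": in_dir / config.template_file}
    availability = None
    if config.ssp is None:
        for var in included:
            for p in catalog.periods:
                paths[f"{var}/{p}"] = in_dir / f"{var}_{p}.tif"
    else:
        avail_path = in_dir / "availability.json"
        if not avail_path.is_file():
            raise PreflightError(f"missing availability table: {avail_path}")
        availability = json.loads(avail_path.read_text())
        if config.ssp not in availability:
            raise PreflightError(f"SSP {config.ssp!r} not in availability "
                                 f"table")
        for var in included:
            paths[f"{var}/{PRESENT_PERIOD}"] = (
                in_dir / f"{var}_{PRESENT_PERIOD}.tif")
            for p in catalog.periods:
                if p == PRESENT_PERIOD:
                    continue
                for gcm in availability[config.ssp].get(p, []):
                    paths[f"{var}/{p}/{gcm}"] = (
                        in_dir / f"{var}_{p}_{gcm}.tif")
    checksums = _preflight(paths)
    log.info("preflight passed: %d input files", len(paths))

    template = read_geotiff(paths["template"])
    template.variable_id = "template"

    common = dict(statistic=config.statistic,
                  r_threshold=config.r_threshold,
                  n_points=config.n_points,
                  sampling_seed=config.sampling_seed,
                  selection_seed=config.selection_seed,
                  min_valid=config.min_valid)
    if config.ssp is None:
        stacks = {}
        for var in included:
            layers = []
            for p in catalog.periods:
                layer = read_geotiff(paths[f"{var}/{p}"])
                layer.variable_id, layer.period_id = var, p
                layers.append(layer)
            stacks[var] = RasterStack.from_layers(layers)
        result = compute_past_csi(stacks, template,
                                  warm_period_ids=config.warm_period_ids,
                                  **common)
    else:
        present = {}
        cubes: dict[str, dict[str, EnsembleCube]] = {}
        order = [p for p in catalog.periods if p != PRESENT_PERIOD]
        for var in included:
            layer = read_geotiff(paths[f"{var}/{PRESENT_PERIOD}"])
            layer.variable_id, layer.period_id = var, PRESENT_PERIOD
            present[var] = layer
            cubes[var] = {}
            for p in order:
                gcms = availability[config.ssp].get(p, [])
                members = {}
                for gcm in gcms:
                    m = read_geotiff(paths[f"{var}/{p}/{gcm}"])
                    m.variable_id, m.period_id = var, p
                    members[gcm] = m
                cubes[var][p] = EnsembleCube(
                    members[gcms[0]].grid, variable_id=var, period_id=p,
                    members=members)
        result = compute_future_csi(cubes, present, template,
                                    reducer=config.reducer,
                                    period_order=order, **common)

    out_dir.mkdir(parents=True, exist_ok=True)
    outputs = _write_outputs(result, config, out_dir)
    manifest = {
        "package": "climstab",
        "config": dataclasses.asdict(config),
        "input_checksums": checksums,
        "kept": result.selection.kept,
        "groups": result.selection.groups,
        "member_counts": result.member_counts,
        "outputs": outputs,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                      default=list))
    log.info("run complete: %d output files in %s", len(outputs) + 1,
             out_dir)
    return result


def _write_outputs(result: MapSetResult, config: RunConfig,
                   out_dir: Path) -> list[str]:
    ssp = config.ssp
    sd_stem = "sd_past_{var}" if ssp is None else f"sd_future_{ssp}_{{var}}"
    csi_name = "csi_past.tif" if ssp is None else f"csi_future_{ssp}.tif"
    outputs = []

    def emit(name: str) -> Path:
        outputs.append(name)
        return out_dir / name

    for var in _sorted_vars(result.sd_raw):
        write_geotiff(result.sd_raw[var],
                      emit(sd_stem.format(var=var) + ".tif"))
        write_geotiff(result.sd_norm[var],
                      emit(sd_stem.format(var=var) + "_norm.tif"))
    write_geotiff(result.csi.csi, emit(csi_name))
    if result.interglacial_flag is not None:
        write_geotiff(result.interglacial_flag.as_layer("intergl_affected"),
                      emit("intergl_affected.tif"), dtype="uint8")
    if ssp is None:
        write_geotiff(result.land_mask.as_layer("lgm_del_mask"),
                      emit("lgm_del_mask.tif"), dtype="uint8")
    hist = histogram(result.csi.csi, 64)
    hist.to_csv(emit(csi_name.replace(".tif", "_histogram.csv")),
                index=False)
    emit("selection.json")
    (out_dir / "selection.json").write_text(result.selection.to_json())
    emit("corr_matrix.csv")
    result.selection.corr_matrix.to_csv(out_dir / "corr_matrix.csv")
    return outputs


def run_from_manifest(manifest_path: str | Path,
                      output_dir: str | Path | None = None) -> MapSetResult:
    """Replay a run from its manifest (optionally into a new directory)."""
    manifest = json.loads(Path(manifest_path).read_text())
    cfg_dict = dict(manifest["config"])
    if output_dir is not None:
        cfg_dict["output_dir"] = str(output_dir)
    return run_pipeline(RunConfig(**cfg_dict))
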