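"""End-to-end orchestration: simulate -> prep -> fit-hsm -> connect ->
evaluate -> tiers, as a seeded, logged, artifact-producing run.

Every stage persists its outputs under the run directory and the manifest
records a content hash per artifact, so identical configs yield identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from corridorscope import ahp as ahp_mod
from corridorscope import maxent as mx
from corridorscope.circuit import cumulative_current
from corridorscope.evaluate import evaluation_matrix, identify_patches, per_individual_capture, tier_map
from corridorscope.landscape import Landscape, LandscapeParams, gen_landscape, gen_surveys
from corridorscope.lcm import corridor_surface, cost_distance
from corridorscope.migration import (
    WindowParams,
    classify_long_distance,
    detect_seasonal_window,
    pool_migration_points,
    tracks_to_csv,
)
from corridorscope.raster import GridSpec, resample, write_raster
from corridorscope.telemetry import TelemetryParams, simulate_tracks

__all__ = ["RunConfig", "ConfigError", "validate_config", "load_config", "run_pipeline", "STAGES"]

log = logging.getLogger("corridorscope")

STAGES = ("simulate", "prep", "fit-hsm", "connect", "evaluate", "tiers")

SEASONS = ("spring", "fall")


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class HSMConfig:
    beta: float = 0.5
    background_size: int = 10_000
    test_frac: float = 0.25
    n_experts_spring: int = 11
    n_experts_fall: int = 12
    survey_noise_sd: float = 0.25


@dataclass(frozen=True)
class ConnectivityConfig:
    neighborhood: int = 8
    circuit_aggregation: int = 3  # 30 m -> 90 m analogue
    basis: str = "area_percentile"
    hint_halfwidth_m: float = 9000.0
    min_patch_cells: int = 4


@dataclass(frozen=True)
class RunConfig:
    seed: int
    landscape: LandscapeParams = field(default_factory=LandscapeParams)
    telemetry: TelemetryParams = field(default_factory=TelemetryParams)
    hsm: HSMConfig = field(default_factory=HSMConfig)
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    thresholds: tuple[float, ...] = (1, 5, 10, 15, 20)
    window: WindowParams = field(default_factory=WindowParams)

    def __post_init__(self) -> None:
        for p in self.thresholds:
            if not 0 < p < 100:
                raise ConfigError(f"threshold {p} outside (0, 100)")


_SECTION_KEYS = {
    "landscape": {
        "nrows", "ncols", "cellsize", "landcover_props", "n_wells", "n_water_bodies",
        "n_roads", "n_parcels_x", "n_parcels_y", "ndvi_corr_length", "patch_radius_m",
    },
    "telemetry": {f.name for f in TelemetryParams.__dataclass_fields__.values()} - {"seed"},
    "hsm": {f.name for f in HSMConfig.__dataclass_fields__.values()},
    "connectivity": {f.name for f in ConnectivityConfig.__dataclass_fields__.values()},
    "window": {"k", "floor_m", "min_days"},
}


def validate_config(raw: dict) -> RunConfig:
    """Schema-check a raw mapping: unknown keys rejected, defaults injected."""
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(raw) - ({"seed", "thresholds"} | set(_SECTION_KEYS))
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in raw:
        raise ConfigError("config must set an explicit seed")
    seed = int(raw["seed"])
    sections: dict[str, dict] = {}
    for name, allowed in _SECTION_KEYS.items():
        sub = raw.get(name, {}) or {}
        bad = set(sub) - allowed
        if bad:
            raise ConfigError(f"unknown keys in {name}: {sorted(bad)}")
        sections[name] = dict(sub)
    ls = sections["landscape"]
    nrows = int(ls.pop("nrows", 120))
    ncols = int(ls.pop("ncols", 120))
    cellsize = float(ls.pop("cellsize", 750.0))
    spec = GridSpec(nrows, ncols, cellsize, origin_y=nrows * cellsize)
    try:
        landscape = LandscapeParams(spec=spec, seed=seed, **ls)
        telemetry = TelemetryParams(seed=seed + 1, **sections["telemetry"])
        config = RunConfig(
            seed=seed,
            landscape=landscape,
            telemetry=telemetry,
            hsm=HSMConfig(**sections["hsm"]),
            connectivity=ConnectivityConfig(**sections["connectivity"]),
            thresholds=tuple(raw.get("thresholds", (1, 5, 10, 15, 20))),
            window=WindowParams(**sections["window"]),
        )
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc
    log.info("validated config: seed=%s grid=%dx%d@%gm thresholds=%s",
             seed, nrows, ncols, cellsize, config.thresholds)
    return config


def load_config(path: str | Path) -> RunConfig:
    return validate_config(yaml.safe_load(Path(path).read_text()) or {})


def _hint_box(center, half):
    return (center[0] - half, center[1] - half, center[0] + half, center[1] + half)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class RunState:
    """In-memory artifacts threaded through the stages."""

    config: RunConfig
    out: Path
    landscape: Landscape | None = None
    tracks: list | None = None
    truth: object | None = None
    season_points: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    suitability: dict = field(default_factory=dict)  # (season, hsm) -> layer
    resistance: dict = field(default_factory=dict)
    models: dict = field(default_factory=dict)
    patches: dict = field(default_factory=dict)
    surfaces: dict = field(default_factory=dict)
    currents: dict = field(default_factory=dict)
    records: pd.DataFrame | None = None
    masks: dict = field(default_factory=dict)
    artifacts: list[Path] = field(default_factory=list)

    def emit(self, path: Path) -> None:
        self.artifacts.append(path)


def _stage_simulate(state: RunState) -> None:
    cfg = state.config
    state.landscape = gen_landscape(cfg.landscape)
    state.tracks, state.truth = simulate_tracks(state.landscape, cfg.telemetry)
    out = state.out / "simulate"
    out.mkdir(parents=True, exist_ok=True)
    for season in SEASONS:
        for role, layer in state.landscape.stacks[season].layers.items():
            if season == "fall" and role != "ndvi":
                continue  # non-NDVI layers are shared across seasons
            state.emit(write_raster(layer, out / f"{season}_{role}.asc"))
    state.emit(state.landscape.fences.to_geojson(out / "fences.geojson"))
    state.emit(tracks_to_csv(state.tracks, out / "tracks.csv"))
    surveys = []
    for season, n in (("spring", cfg.hsm.n_experts_spring), ("fall", cfg.hsm.n_experts_fall)):
        surveys.extend(
            gen_surveys(state.landscape.truths[season], n, season, seed=cfg.seed + 2, noise_sd=cfg.hsm.survey_noise_sd)
        )
    state.emit(ahp_mod.save_surveys(surveys, out / "surveys.yaml"))


def _stage_prep(state: RunState) -> None:
    cfg = state.config
    out = state.out / "prep"
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for season in SEASONS:
        windows = {}
        for track in state.tracks:
            w = detect_seasonal_window(track, season, cfg.window)
            if w is None:
                continue
            if classify_long_distance(track, w, params=cfg.window) == "migrant":
                windows[track.individual] = w
                rows.append(
                    {
                        "individual": track.individual,
                        "season": season,
                        "start_day": str(w.start_day),
                        "end_day": str(w.end_day),
                    }
                )
        state.windows[season] = windows
        pooled = pool_migration_points(state.tracks, season, windows, params=cfg.window)
        state.season_points[season] = pooled
        state.emit(pooled.to_csv(out / f"points_{season}.csv"))
        log.info("prep: %s migrants=%d pooled=%d", season, len(windows), len(pooled))
    pd.DataFrame(rows).to_csv(out / "windows.csv", index=False)
    state.emit(out / "windows.csv")


def _stage_fit_hsm(state: RunState) -> None:
    cfg = state.config
    out = state.out / "hsm"
    out.mkdir(parents=True, exist_ok=True)
    surveys = ahp_mod.load_surveys(state.out / "simulate" / "surveys.yaml")
    diagnostics = {}
    for season in SEASONS:
        stack = state.landscape.stacks[season]
        pooled = state.season_points[season]
        feats = mx.build_features(stack)
        train, test = mx.split_points(pooled, cfg.hsm.test_frac, seed=cfg.seed + 3)
        model = mx.fit_maxent(
            feats,
            mx.presence_rows(feats, train),
            beta=cfg.hsm.beta,
            seed=cfg.seed + 4,
            background_size=cfg.hsm.background_size,
        )
        state.models[(season, "maxent")] = model
        suit = mx.predict(model, feats, "logistic")
        raw = mx.predict(model, feats, "raw")
        state.suitability[(season, "maxent")] = suit
        state.resistance[(season, "maxent")] = mx.suitability_to_resistance(raw, "maxent")
        test_rows = mx.presence_rows(feats, test, dedupe=False)
        cells = feats.cells
        auc = mx.auc_presence_background(
            suit.values[cells[test_rows, 0], cells[test_rows, 1]],
            suit.values[cells[model.background_rows, 0], cells[model.background_rows, 1]],
        )
        contrib = mx.variable_contributions(model)
        diagnostics[season] = {
            "auc_test": auc,
            "n_train": len(train),
            "n_test": len(test),
            "contributions": contrib,
        }
        log.info("fit-hsm: %s maxent auc=%.3f top=%s", season, auc, max(contrib, key=contrib.get))
        (out / f"maxent_{season}.json").write_text(json.dumps(model.to_dict(), indent=1))
        state.emit(out / f"maxent_{season}.json")

        season_surveys = [s for s in surveys if s.season == season]
        weights = ahp_mod.weights_from_surveys(season_surveys)
        suit_ahp = ahp_mod.ahp_suitability(stack, weights)
        state.suitability[(season, "ahp")] = suit_ahp
        state.resistance[(season, "ahp")] = ahp_mod.invert_rescale(suit_ahp)
        (out / f"ahp_{season}.json").write_text(
            json.dumps(
                {
                    "variable_weights": weights.variable_weights,
                    "contributions_percent": weights.contributions_percent(),
                    "category_scores": {k: {str(c): s for c, s in v.items()} for k, v in weights.category_scores.items()},
                    "diagnostics": weights.diagnostics,
                    "n_experts": weights.n_experts,
                },
                indent=1,
            )
        )
        state.emit(out / f"ahp_{season}.json")
        for hsm in ("maxent", "ahp"):
            state.emit(write_raster(state.suitability[(season, hsm)], out / f"suitability_{season}_{hsm}.asc"))
            state.emit(write_raster(state.resistance[(season, hsm)], out / f"resistance_{season}_{hsm}.asc"))
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=1))
    state.emit(out / "diagnostics.json")


def _aggregate_regions(cells, factor):
    seen = []
    got = set()
    for r, c in cells:
        rc = (r // factor, c // factor)
        if rc not in got:
            got.add(rc)
            seen.append(rc)
    return seen


def _stage_connect(state: RunState) -> None:
    cfg = state.config
    conn = cfg.connectivity
    out = state.out / "connect"
    out.mkdir(parents=True, exist_ok=True)
    land = state.landscape
    half = conn.hint_halfwidth_m
    for season in SEASONS:
        for hsm in ("maxent", "ahp"):
            suit = state.suitability[(season, hsm)]
            res = state.resistance[(season, hsm)]
            patches = identify_patches(
                suit,
                state.season_points[season],
                _hint_box(land.source_center, half),
                [_hint_box(c, half) for c in land.dest_centers],
                min_cells=conn.min_patch_cells,
            )
            state.patches[(season, hsm)] = patches
            src_cells = patches.source_cells()
            dst_cells = [c for d in patches.destination_cells() for c in d]
            if season == "fall":  # migration reverses: northern patches feed the winter range
                src_cells, dst_cells = dst_cells, src_cells
            cd_src = cost_distance(res, src_cells, conn.neighborhood)
            cd_dst = cost_distance(res, dst_cells, conn.neighborhood)
            state.surfaces[(season, hsm)] = corridor_surface(cd_src, cd_dst)

            factor = conn.circuit_aggregation
            res_c = resample(res, factor, "mean") if factor > 1 else res
            regions = [patches.source_cells()] + patches.destination_cells()
            taken: set = set()
            agg_regions = []
            for reg in regions:
                agg = [rc for rc in _aggregate_regions(reg, factor) if rc not in taken]
                taken.update(agg)
                agg_regions.append(agg)
            pairs = [(0, k) for k in range(1, len(agg_regions))]
            if season == "fall":
                pairs = [(k, 0) for k in range(1, len(agg_regions))]
            state.currents[(season, hsm)] = cumulative_current(res_c, agg_regions, pairs, conn.neighborhood)

            state.emit(write_raster(state.surfaces[(season, hsm)].copy_with(
                np.where(np.isfinite(state.surfaces[(season, hsm)].values),
                         state.surfaces[(season, hsm)].values, -9999.0)),
                out / f"corridor_{season}_{hsm}_lcm.asc"))
            state.emit(write_raster(state.currents[(season, hsm)], out / f"current_{season}_{hsm}.asc"))
            state.emit(write_raster(patches.labels, out / f"patches_{season}_{hsm}.asc"))
            log.info(
                "connect: %s/%s source=%d cells, %d destinations, threshold=%.3f",
                season, hsm, len(src_cells), len(patches.destinations), patches.threshold,
            )


def _stage_evaluate(state: RunState) -> None:
    cfg = state.config
    out = state.out / "evaluate"
    out.mkdir(parents=True, exist_ok=True)
    df, masks = evaluation_matrix(
        state.surfaces,
        state.currents,
        state.season_points,
        thresholds=cfg.thresholds,
        basis=cfg.connectivity.basis,
        tracks=state.tracks,
        windows=state.windows,
    )
    state.records = df
    state.masks = masks
    df.to_csv(out / "evaluation.csv", index=False)
    state.emit(out / "evaluation.csv")
    per_ind = []
    for (season, hsm, method, p), mask in masks.items():
        sub = per_individual_capture(mask, state.tracks, state.windows[season])
        sub["hsm"], sub["method"], sub["threshold"] = hsm, method, p
        per_ind.append(sub)
    pd.concat(per_ind, ignore_index=True).to_csv(out / "per_individual.csv", index=False)
    state.emit(out / "per_individual.csv")


def _stage_tiers(state: RunState) -> None:
    out = state.out / "tiers"
    out.mkdir(parents=True, exist_ok=True)
    needed = {}
    for season in SEASONS:
        for p in (1, 5, 10):
            key = (season, "maxent", "lcm", float(p))
            alt = (season, "maxent", "lcm", p)
            mask = state.masks.get(key, state.masks.get(alt))
            if mask is None:
                raise ValueError(f"missing maxent-lcm corridor {season} {p}% for tier map")
            needed[(season, p)] = mask
    tiers = tier_map(needed)
    state.emit(write_raster(tiers, out / "tiers.asc"))
    legend = "0 none\n1 tier1 (union of seasonal 1% corridors)\n2 tier2 (intersection of 5%)\n3 tier3 (intersection of 10%)\n"
    (out / "legend.txt").write_text(legend)
    state.emit(out / "legend.txt")


_STAGE_FN = {
    "simulate": _stage_simulate,
    "prep": _stage_prep,
    "fit-hsm": _stage_fit_hsm,
    "connect": _stage_connect,
    "evaluate": _stage_evaluate,
    "tiers": _stage_tiers,
}


def run_pipeline(config: RunConfig, out_dir: str | Path, through: str = "tiers") -> dict:
    """Run the stages in order up to ``through`` and write the manifest."""
    if through not in STAGES:
        raise ConfigError(f"unknown stage {through!r}")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    state = RunState(config, out)
    for stage in STAGES[: STAGES.index(through) + 1]:
        log.info("stage %s starting", stage)
        try:
            _STAGE_FN[stage](state)
        except Exception as exc:
            raise RuntimeError(f"stage {stage!r} failed: {exc}") from exc
    manifest = {
        "seed": config.seed,
        "through": through,
        "thresholds": list(config.thresholds),
        "artifacts": {str(p.relative_to(out)): _sha256(p) for p in sorted(set(state.artifacts))},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
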