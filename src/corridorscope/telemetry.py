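"""Synthetic migratory telemetry over a generated landscape.

A collared population of residents and long-distance migrants is simulated
as a suitability-biased correlated walk.  Migrants drift toward a seasonal
destination during a known migration window while keeping migratory-scale
daily movement (~7 km/day of path versus ~4.8 km/day for ordinary ranging),
so window-detection and classification recovery tests have ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from corridorscope.landscape import Landscape
from corridorscope.migration import Track
from corridorscope.raster import RasterLayer

__all__ = ["TelemetryParams", "TelemetryTruth", "simulate_tracks"]


@dataclass(frozen=True)
class TelemetryParams:
    n_individuals: int = 42
    n_spring_migrants: int = 17
    n_fall_migrants: int = 18
    fixes_per_day: int = 6
    n_days: int = 365
    start_date: str = "2008-01-01"
    resident_step_m: float = 780.0
    migrant_step_m: float = 1170.0
    step_noise_sd: float = 0.05  # lognormal sd on step lengths
    spring_start_doy: int = 79  # ~Mar 20
    spring_duration_days: int = 50
    fall_start_doy: int = 288  # ~Oct 15
    fall_duration_days: int = 32
    start_jitter_days: int = 2
    home_sd_m: float = 1200.0
    suitability_gain: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.n_spring_migrants <= self.n_individuals):
            raise ValueError("spring migrant count out of range")
        if not (0 <= self.n_fall_migrants <= self.n_individuals):
            raise ValueError("fall migrant count out of range")


@dataclass
class TelemetryTruth:
    """Ground truth recorded by the simulator, per individual."""

    spring_migrants: set[str]
    fall_migrants: set[str]
    windows: dict[tuple[str, str], tuple[np.datetime64, np.datetime64]]  # (id, season) -> (start, end) days
    destinations: dict[str, tuple[float, float]] = field(default_factory=dict)


def _cone_half_angle(drift_ratio: float) -> float:
    """Half-angle a of a uniform heading cone with E[cos] = sin(a)/a = drift_ratio."""
    rho = float(np.clip(drift_ratio, 1e-3, 0.999))
    return brentq(lambda a: np.sin(a) / a - rho, 1e-6, np.pi - 1e-9)


def _suitability_at(layer: RasterLayer, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    r, c = layer.spec.index_of(x, y)
    return layer.values[r, c]


def simulate_tracks(landscape: Landscape, params: TelemetryParams = TelemetryParams()) -> tuple[list[Track], TelemetryTruth]:
    rng = np.random.default_rng(params.seed)
    suit = {season: landscape.truths[season].suitability(landscape.stacks[season]) for season in ("spring", "fall")}
    spec = landscape.params.spec
    xmin, ymin, xmax, ymax = spec.extent
    margin = spec.cellsize
    source = np.array(landscape.source_center)
    dests = [np.array(d) for d in landscape.dest_centers]
    radius = landscape.params.patch_radius_m

    n = params.n_individuals
    n_both = min(params.n_spring_migrants, params.n_fall_migrants)
    spring_ids = {f"P{i:02d}" for i in range(params.n_spring_migrants)}
    fall_ids = {f"P{i:02d}" for i in range(params.n_fall_migrants)}
    # individuals beyond the overlap migrate in only one season; fall-only
    # migrants summer in the north and are collared there
    fall_only = fall_ids - spring_ids

    n_fixes = params.n_days * params.fixes_per_day
    t0 = np.datetime64(params.start_date)
    dt_s = int(round(86400 / params.fixes_per_day))
    times = t0.astype("datetime64[s]") + np.arange(n_fixes) * np.timedelta64(dt_s, "s")
    fix_days = times.astype("datetime64[D]")
    day_index = ((fix_days - fix_days[0]) / np.timedelta64(1, "D")).astype(int)
    months = fix_days.astype("datetime64[M]").astype(int) % 12 + 1
    spring_half = months <= 7

    daily_path = params.migrant_step_m * params.fixes_per_day

    tracks: list[Track] = []
    truth = TelemetryTruth(set(), set(), {}, {})
    for i in range(n):
        ind = f"P{i:02d}"
        r = np.random.default_rng(rng.integers(0, 2**63))
        dest = dests[i % len(dests)]
        if ind in fall_only:
            home = dest + r.normal(0, params.home_sd_m, 2)
        else:
            home = source + r.normal(0, params.home_sd_m, 2)
        truth.destinations[ind] = (float(dest[0]), float(dest[1]))

        legs: list[tuple[int, int, np.ndarray]] = []  # (start_day, end_day_exclusive, target)
        if ind in spring_ids and ind not in fall_only:
            s = params.spring_start_doy + int(r.integers(-params.start_jitter_days, params.start_jitter_days + 1))
            legs.append((s, s + params.spring_duration_days, dest))
            truth.spring_migrants.add(ind)
            truth.windows[(ind, "spring")] = (
                fix_days[0] + np.timedelta64(s, "D"),
                fix_days[0] + np.timedelta64(s + params.spring_duration_days - 1, "D"),
            )
        if ind in fall_ids:
            s = params.fall_start_doy + int(r.integers(-params.start_jitter_days, params.start_jitter_days + 1))
            legs.append((s, s + params.fall_duration_days, source))
            truth.fall_migrants.add(ind)
            truth.windows[(ind, "fall")] = (
                fix_days[0] + np.timedelta64(s, "D"),
                fix_days[0] + np.timedelta64(s + params.fall_duration_days - 1, "D"),
            )

        xs = np.empty(n_fixes)
        ys = np.empty(n_fixes)
        pos = home.copy()
        anchor = home.copy()
        offsets = np.linspace(-1.0, 1.0, 9)
        for k in range(n_fixes):
            day = day_index[k]
            leg = next((lg for lg in legs if lg[0] <= day < lg[1]), None)
            slayer = suit["spring" if spring_half[k] else "fall"]
            if leg is not None:
                target = leg[2]
                to_go = np.hypot(*(target - pos))
                days_left = max(leg[1] - day, 1)
                step = params.migrant_step_m * np.exp(r.normal(0, params.step_noise_sd))
                if to_go <= radius:
                    # stopover at the destination: keep migratory turnover locally
                    anchor = target
                    heading = r.uniform(0, 2 * np.pi)
                    cand = pos + step * np.column_stack([np.cos([heading]), np.sin([heading])])[0]
                    if np.hypot(*(cand - target)) > radius:
                        heading = np.arctan2(*(target - pos)[::-1]) + r.normal(0, 0.5)
                    new = pos + step * np.array([np.cos(heading), np.sin(heading)])
                else:
                    rho = to_go / (days_left * daily_path)
                    alpha = _cone_half_angle(min(rho * 1.15, 0.98))
                    bearing = np.arctan2(target[1] - pos[1], target[0] - pos[0])
                    headings = bearing + alpha * offsets
                    cx = pos[0] + step * np.cos(headings)
                    cy = pos[1] + step * np.sin(headings)
                    svals = _suitability_at(slayer, np.clip(cx, xmin + margin, xmax - margin), np.clip(cy, ymin + margin, ymax - margin))
                    w = np.exp(params.suitability_gain * svals)
                    pick = r.choice(len(headings), p=w / w.sum())
                    new = np.array([cx[pick], cy[pick]])
                    anchor = new
            else:
                step = params.resident_step_m * np.exp(r.normal(0, params.step_noise_sd))
                if np.hypot(*(pos - anchor)) > 2.5 * params.home_sd_m:
                    heading = np.arctan2(anchor[1] - pos[1], anchor[0] - pos[0]) + r.normal(0, 0.6)
                else:
                    heading = r.uniform(0, 2 * np.pi)
                new = pos + step * np.array([np.cos(heading), np.sin(heading)])
            pos = np.array(
                [np.clip(new[0], xmin + margin, xmax - margin), np.clip(new[1], ymin + margin, ymax - margin)]
            )
            xs[k] = pos[0]
            ys[k] = pos[1]
        tracks.append(Track(ind, xs, ys, times.copy()))
    return tracks, truth
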