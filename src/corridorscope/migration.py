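"""Track preparation: daily displacements, migration-window detection,
migrant/resident classification, and pooled seasonal presence points.

The study-design rule of thumb is codified here as an explicit, reproducible
threshold: a migration window is the longest contiguous run of calendar days
whose daily movement exceeds ``max(k * median_daily, floor_m)``.  The
defaults (k = 1.25, floor 5 km) separate migratory days (~7 km of movement)
from ordinary ranging (~4.8 km).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from corridorscope.pointset import PointSet

__all__ = [
    "SEASON_MONTHS",
    "Track",
    "MigrationWindow",
    "WindowParams",
    "daily_displacements",
    "detect_migration_window",
    "detect_seasonal_window",
    "classify_long_distance",
    "pool_migration_points",
    "tracks_to_csv",
    "tracks_from_csv",
]

#: default seasonal period calendars (month numbers)
SEASON_MONTHS: dict[str, tuple[int, ...]] = {
    "spring": (3, 4, 5, 6),
    "fall": (10, 11, 12),
}


@dataclass
class Track:
    """Time-stamped fixes for one individual."""

    individual: str
    x: np.ndarray
    y: np.ndarray
    t: np.ndarray  # datetime64

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.t = np.asarray(self.t, dtype="datetime64[s]")
        n = len(self.x)
        if not (len(self.y) == len(self.t) == n):
            raise ValueError("x, y, t must have equal length")
        if n < 2:
            raise ValueError("a track needs at least two fixes")
        if np.any(np.diff(self.t).astype("timedelta64[s]").astype(np.int64) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.x)

    def days(self) -> np.ndarray:
        return self.t.astype("datetime64[D]")


@dataclass
class MigrationWindow:
    """A contiguous run of migratory days for one individual and season."""

    individual: str
    season: str
    start_idx: int  # first fix index inside the window
    end_idx: int  # last fix index inside the window (inclusive)
    start_day: np.datetime64
    end_day: np.datetime64

    def __post_init__(self) -> None:
        if self.start_idx >= self.end_idx:
            raise ValueError("window must span more than one fix")


@dataclass(frozen=True)
class WindowParams:
    k: float = 1.25
    floor_m: float = 5000.0
    min_days: int = 7  # series shorter than this cannot support detection


def daily_displacements(track: Track) -> pd.Series:
    """Per-calendar-day movement: the sum of successive step lengths whose
    starting fix falls on that day.  Days with fewer than two fixes are NaN."""
    days = pd.to_datetime(track.days())
    if days.nunique() < 2:
        raise ValueError("track must span at least two calendar days")
    steps = np.hypot(np.diff(track.x), np.diff(track.y))
    sums = pd.Series(steps).groupby(days[:-1].values).sum()
    counts = pd.Series(np.ones(len(days))).groupby(days.values).size()
    full_index = pd.date_range(days.min(), days.max(), freq="D")
    out = sums.reindex(full_index)
    out[(counts.reindex(full_index).fillna(0) < 2).values] = np.nan
    return out


def detect_migration_window(series: pd.Series, params: WindowParams = WindowParams()) -> tuple[np.datetime64, np.datetime64] | None:
    """Longest contiguous run of days whose displacement exceeds the threshold.

    Returns ``(start_day, end_day)`` inclusive, or None when no day exceeds
    the threshold.  Ties go to the earliest run.
    """
    vals = series.to_numpy(dtype=float)
    if np.sum(~np.isnan(vals)) < params.min_days:
        raise ValueError(f"need at least {params.min_days} non-missing days")
    theta = max(params.k * np.nanmedian(vals), params.floor_m)
    above = np.where(np.isnan(vals), False, vals > theta)
    if not above.any():
        return None
    best_start = best_len = 0
    run_start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    idx = np.asarray(series.index.values, dtype="datetime64[D]")
    return idx[best_start], idx[best_start + best_len - 1]


def detect_seasonal_window(
    track: Track, season: str, params: WindowParams = WindowParams()
) -> MigrationWindow | None:
    """Detect the migration window within one seasonal calendar period."""
    months = SEASON_MONTHS[season]
    series = daily_displacements(track)
    idx = pd.DatetimeIndex(series.index)
    sub = series[idx.month.isin(months)]
    if sub.empty or np.sum(~np.isnan(sub.to_numpy(dtype=float))) < params.min_days:
        return None
    found = detect_migration_window(sub, params)
    if found is None:
        return None
    start_day, end_day = found
    days = track.days()
    inside = (days >= start_day) & (days <= end_day)
    fix_idx = np.flatnonzero(inside)
    if len(fix_idx) < 2:
        return None
    return MigrationWindow(track.individual, season, int(fix_idx[0]), int(fix_idx[-1]), start_day, end_day)


def classify_long_distance(
    track: Track,
    window: MigrationWindow | None = None,
    cutoff_km: float = 50.0,
    params: WindowParams = WindowParams(),
    range_days: int = 45,
) -> str:
    """Label a track ``migrant`` or ``resident``.

    Migrant iff the planar distance between the pre-window and post-window
    seasonal-range centroids strictly exceeds the cutoff.  Centroids are
    taken over the ``range_days`` days adjacent to the window so that a
    different season's migration cannot contaminate the range estimate.
    When no window is supplied the whole-series window is detected first; no
    detectable window means resident.
    """
    if window is None:
        series = daily_displacements(track)
        found = detect_migration_window(series, params)
        if found is None:
            return "resident"
        start_day, end_day = found
    else:
        start_day, end_day = window.start_day, window.end_day
    days = track.days()
    lookback = start_day - np.timedelta64(range_days, "D")
    lookahead = end_day + np.timedelta64(range_days, "D")
    pre = (days < start_day) & (days >= lookback)
    post = (days > end_day) & (days <= lookahead)
    if not pre.any() or not post.any():
        raise ValueError("track does not cover both sides of the migration window")
    dx = track.x[post].mean() - track.x[pre].mean()
    dy = track.y[post].mean() - track.y[pre].mean()
    return "migrant" if np.hypot(dx, dy) > cutoff_km * 1000.0 else "resident"


def pool_migration_points(
    tracks: list[Track],
    season: str,
    windows: dict[str, MigrationWindow] | None = None,
    cutoff_km: float = 50.0,
    params: WindowParams = WindowParams(),
) -> PointSet:
    """Union of within-window fixes of every migrant for one season
    (stopover fixes included by design)."""
    sets: list[PointSet] = []
    for track in tracks:
        window = windows.get(track.individual) if windows is not None else detect_seasonal_window(track, season, params)
        if window is None:
            continue
        try:
            label = classify_long_distance(track, window, cutoff_km, params)
        except ValueError:
            continue
        if label != "migrant":
            continue
        sl = slice(window.start_idx, window.end_idx + 1)
        sets.append(
            PointSet(
                track.x[sl],
                track.y[sl],
                ids=np.full(window.end_idx + 1 - window.start_idx, track.individual, dtype=object),
                t=track.t[sl],
            )
        )
    if not sets:
        raise ValueError(f"no migrant fixes pooled for season {season!r}")
    return PointSet.concat(sets)


# ---------------------------------------------------------------------------
# CSV round-trip
# ---------------------------------------------------------------------------

def tracks_to_csv(tracks: list[Track], path: str | Path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame({"id": t.individual, "x": t.x, "y": t.y, "t": pd.to_datetime(t.t)}) for t in tracks
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def tracks_from_csv(path: str | Path) -> list[Track]:
    df = pd.read_csv(path, parse_dates=["t"])
    tracks = []
    for ind, grp in df.groupby("id", sort=True):
        grp = grp.sort_values("t")
        tracks.append(Track(str(ind), grp["x"].to_numpy(), grp["y"].to_numpy(), grp["t"].to_numpy()))
    return tracks
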