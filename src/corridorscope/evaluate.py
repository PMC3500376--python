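"""Patch identification, capture-rate evaluation over the factorial design,
and the tiered priority-area overlay.

The evaluation statistic pair is (percent of pooled migration fixes inside a
corridor mask, percent of valid study-area cells inside it); the study-area
denominator is always the valid mask of the analysis grid and is logged with
every record.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import label

from corridorscope.lcm import CorridorMask, slice_corridor
from corridorscope.circuit import slice_current
from corridorscope.migration import MigrationWindow, Track
from corridorscope.pointset import PointSet
from corridorscope.raster import RasterLayer

__all__ = [
    "PatchSet",
    "TIER_CODES",
    "equal_sens_spec_threshold",
    "identify_patches",
    "capture_stats",
    "per_individual_capture",
    "evaluation_matrix",
    "tier_map",
]

TIER_CODES = {"none": 0, "tier1": 1, "tier2": 2, "tier3": 3}

_EIGHT = np.ones((3, 3), dtype=int)


@dataclass
class PatchSet:
    """Connected components of good habitat with seasonal roles."""

    labels: RasterLayer  # categorical component labels, 0 = background
    source: int
    destinations: list[int]
    threshold: float

    def __post_init__(self) -> None:
        if self.source in self.destinations:
            raise ValueError("source patch cannot also be a destination")

    def cells(self, patch_label: int) -> list[tuple[int, int]]:
        return [tuple(rc) for rc in np.argwhere(self.labels.values == patch_label)]

    def source_cells(self) -> list[tuple[int, int]]:
        return self.cells(self.source)

    def destination_cells(self) -> list[list[tuple[int, int]]]:
        return [self.cells(d) for d in self.destinations]


def equal_sens_spec_threshold(presence_scores, background_scores) -> float:
    """Threshold minimizing |sensitivity - specificity|; ties take the lower t.

    Sensitivity: fraction of presences scoring >= t; specificity: fraction of
    background scoring < t.  Candidates are the sorted unique scores.
    """
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if len(p) == 0 or len(b) == 0:
        raise ValueError("both score sets must be non-empty")
    candidates = np.unique(np.r_[p, b])
    best_t, best_gap = None, np.inf
    for t in candidates:
        sens = np.mean(p >= t)
        spec = np.mean(b < t)
        gap = abs(sens - spec)
        if gap < best_gap - 1e-12:
            best_gap, best_t = gap, t
    return float(best_t)


def _box_cells(spec, box) -> np.ndarray:
    """Grid cells whose centre falls inside a (xmin, ymin, xmax, ymax) box."""
    xmin, ymin, xmax, ymax = box
    xs, ys = spec.cell_centers()
    return (xs >= xmin) & (xs <= xmax) & (ys >= ymin) & (ys <= ymax)


def identify_patches(
    suitability: RasterLayer,
    presence: PointSet,
    source_hint: tuple[float, float, float, float],
    dest_hints: list[tuple[float, float, float, float]],
    background_scores: np.ndarray | None = None,
    min_cells: int = 4,
    protected_mask: np.ndarray | None = None,
) -> PatchSet:
    """Patches of good habitat anchored on the hint areas.

    Good habitat is thresholded at equal sensitivity/specificity; each patch
    is the dominant 8-connected component of good habitat *within* its hint
    box (the source hint is the collaring area; destination hints are
    high-density seeds, e.g. a protected area).  Destinations are ranked by
    within-patch presence density."""
    spec = suitability.spec
    pr, pc = spec.index_of(presence.x, presence.y)
    presence_scores = suitability.values[pr, pc]
    if background_scores is None:
        background_scores = suitability.values[suitability.mask]
    t = equal_sens_spec_threshold(presence_scores, background_scores)
    good = (suitability.values >= t) & suitability.mask
    if protected_mask is not None:
        good |= np.asarray(protected_mask, dtype=bool) & suitability.mask
    if not good.any():
        raise ValueError("no cell reaches the suitability threshold")
    presence_grid = np.zeros(spec.shape, dtype=np.int64)
    np.add.at(presence_grid, (pr, pc), 1)

    out = np.zeros(spec.shape, dtype=np.int64)

    def carve_patch(box, name, patch_label):
        inside = good & _box_cells(spec, box) & (out == 0)
        comps, n = label(inside, structure=_EIGHT)
        sizes = np.bincount(comps.ravel(), minlength=n + 1)
        sizes[0] = 0
        candidates = np.flatnonzero(sizes >= min_cells)
        if len(candidates) == 0:
            raise ValueError(f"hint {name} overlaps no habitat component of >= {min_cells} cells")
        pts = np.bincount(comps.ravel(), weights=presence_grid.ravel(), minlength=n + 1)
        density = pts[candidates] / sizes[candidates]
        order = np.lexsort((-sizes[candidates], -density))
        chosen = candidates[order[0]]
        out[comps == chosen] = patch_label
        return float(density[order[0]])

    carve_patch(source_hint, "source", 1)
    densities = []
    for i, hint in enumerate(dest_hints):
        densities.append((carve_patch(hint, f"destination[{i}]", 2 + i), 2 + i))
    dests = [lab for _, lab in sorted(densities, key=lambda d: -d[0])]
    layer = RasterLayer(spec, out, "categorical", suitability.mask.copy())
    return PatchSet(layer, 1, dests, t)


def capture_stats(mask: CorridorMask | np.ndarray, points: PointSet, valid_mask: np.ndarray, spec=None) -> tuple[float, float]:
    """(percent of fixes inside the mask, percent of valid cells inside it)."""
    if isinstance(mask, CorridorMask):
        spec = mask.layer.spec
        cells = mask.cells
    else:
        if spec is None:
            raise ValueError("spec required when passing a bare mask array")
        cells = np.asarray(mask, dtype=bool)
    if len(points) == 0:
        raise ValueError("no points to evaluate")
    r, c = spec.index_of(points.x, points.y)
    pct_points = 100.0 * np.mean(cells[r, c])
    pct_area = 100.0 * cells.sum() / np.asarray(valid_mask, dtype=bool).sum()
    return float(pct_points), float(pct_area)


def per_individual_capture(
    mask: CorridorMask,
    tracks: list[Track],
    windows: dict[str, MigrationWindow],
) -> pd.DataFrame:
    """Per-individual fraction of window fixes inside the mask, with a
    fully-contained flag."""
    spec = mask.layer.spec
    cells = mask.cells
    rows = []
    for track in tracks:
        window = windows.get(track.individual)
        if window is None:
            continue
        sl = slice(window.start_idx, window.end_idx + 1)
        r, c = spec.index_of(track.x[sl], track.y[sl])
        inside = cells[r, c]
        frac = float(np.mean(inside))
        rows.append(
            {
                "individual": track.individual,
                "season": window.season,
                "n_fixes": int(inside.size),
                "fraction_inside": frac,
                "fully_contained": bool(frac == 1.0),
            }
        )
    return pd.DataFrame(rows)


def evaluation_matrix(
    surfaces: dict[tuple[str, str], RasterLayer],
    currents: dict[tuple[str, str], RasterLayer],
    season_points: dict[str, PointSet],
    thresholds=(1, 5, 10, 15, 20),
    basis: str = "area_percentile",
    tracks: list[Track] | None = None,
    windows: dict[str, dict[str, MigrationWindow]] | None = None,
) -> tuple[pd.DataFrame, dict[tuple[str, str, str, float], CorridorMask]]:
    """Every (season x HSM x method x threshold) evaluation record.

    ``surfaces`` maps (season, hsm) to the summed cost-distance corridor
    surface; ``currents`` maps (season, hsm) to the cumulative current map.
    Returns the records plus the sliced masks keyed by the full combination.
    """
    records = []
    masks: dict[tuple[str, str, str, float], CorridorMask] = {}
    seasons = sorted({k[0] for k in surfaces})
    hsms = sorted({k[1] for k in surfaces})
    for season in seasons:
        points = season_points[season]
        for hsm in hsms:
            for method in ("lcm", "circuit"):
                for p in thresholds:
                    if method == "lcm":
                        surface = surfaces[(season, hsm)]
                        mask = slice_corridor(surface, p, basis, season=season, hsm=hsm)
                    else:
                        mask, _ = slice_current(currents[(season, hsm)], p, season=season, hsm=hsm)
                    masks[(season, hsm, method, p)] = mask
                    pct_points, pct_area = capture_stats(mask, points, mask.layer.mask)
                    rec = {
                        "season": season,
                        "hsm": hsm,
                        "method": method,
                        "threshold": p,
                        "pct_points": pct_points,
                        "pct_area": pct_area,
                        "denominator_cells": int(mask.layer.mask.sum()),
                    }
                    if tracks is not None and windows is not None:
                        per_ind = per_individual_capture(mask, tracks, windows[season])
                        rec["mean_individual_pct"] = float(100 * per_ind["fraction_inside"].mean())
                        rec["n_fully_contained"] = int(per_ind["fully_contained"].sum())
                    records.append(rec)
    df = pd.DataFrame(records)
    return df, masks


def tier_map(corridors: dict[tuple[str, float], CorridorMask]) -> RasterLayer:
    """Tiered priority overlay from the seasonal 1/5/10% corridors.

    Tier 1 = union of the seasonal 1% corridors; tier 2 = intersection of the
    5% corridors; tier 3 = intersection of the 10% corridors.  Each cell is
    coded with the best (lowest-numbered) tier it attains.
    """
    needed = [(s, p) for s in ("spring", "fall") for p in (1, 5, 10)]
    missing = [k for k in needed if k not in corridors]
    if missing:
        raise ValueError(f"missing corridors for tier map: {missing}")
    g = {k: corridors[k].cells for k in needed}
    tier1 = g[("spring", 1)] | g[("fall", 1)]
    tier2 = g[("spring", 5)] & g[("fall", 5)]
    tier3 = g[("spring", 10)] & g[("fall", 10)]
    ref = corridors[("spring", 1)].layer
    out = np.zeros(ref.spec.shape, dtype=np.int64)
    out[tier3] = TIER_CODES["tier3"]
    out[tier2] = TIER_CODES["tier2"]
    out[tier1] = TIER_CODES["tier1"]
    return RasterLayer(ref.spec, out, "categorical", ref.mask.copy())
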