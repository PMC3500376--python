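"""Synthetic prairie landscapes: covariate stacks, parcels, roads, modeled
fences, fence ground truth, and a known true-suitability surface.

Every generator is fully deterministic under its seed.  The true suitability
surface is produced by the exact weighted-linear-combination scoring path of
the AHP engine, so downstream recovery tests are well-posed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import shapely
from scipy.ndimage import gaussian_filter, uniform_filter
from shapely.geometry import LineString

from corridorscope.ahp import weighted_suitability
from corridorscope.pointset import PointSet
from corridorscope.raster import (
    COVARIATE_ROLES,
    CovariateStack,
    GridSpec,
    RasterLayer,
    distance_to_features,
)

__all__ = [
    "LANDCOVER_CODES",
    "TOPO_CODES",
    "LandscapeParams",
    "LineSet",
    "FenceRules",
    "TruthModel",
    "Landscape",
    "default_truth_weights",
    "default_category_scores",
    "gen_parcels_and_roads",
    "model_fences",
    "rasterize_lines",
    "fence_accuracy",
    "gen_fence_truth",
    "gen_covariates",
    "gen_landscape",
]

LANDCOVER_CODES = {
    "water": 1,
    "development": 2,
    "grassland": 3,
    "wetlands": 4,
    "agriculture": 5,
    "pasture": 6,
}

TOPO_CODES = {"canyon": 1, "flat": 2, "steep": 3, "ridge": 4}

#: landcover classes ordered along the generating field (wet to dry-developed)
_CLASS_ORDER = ("water", "wetlands", "grassland", "pasture", "agriculture", "development")

_OWNERSHIP_CLASSES = ("private", "federal", "state")


@dataclass(frozen=True)
class LandscapeParams:
    """Knobs for the synthetic prairie generator."""

    spec: GridSpec = field(default_factory=lambda: GridSpec(120, 120, 750.0, origin_x=0.0, origin_y=90_000.0))
    landcover_props: dict[str, float] = field(
        default_factory=lambda: {
            "grassland": 0.56,
            "agriculture": 0.26,
            "pasture": 0.09,
            "wetlands": 0.04,
            "water": 0.03,
            "development": 0.02,
        }
    )
    n_wells: int = 40
    n_water_bodies: int = 25
    n_roads: int = 3
    n_parcels_x: int = 6
    n_parcels_y: int = 6
    ndvi_corr_length: float = 8.0  # cells
    patch_radius_m: float = 6000.0
    patch_centers: tuple[tuple[float, float], ...] | None = None  # source first, then destinations
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.landcover_props.values())
        if any(not 0 <= p <= 1 for p in self.landcover_props.values()) or total > 1 + 1e-9:
            raise ValueError("landcover proportions must lie in [0,1] and sum to at most 1")
        if self.n_wells < 1 or self.n_water_bodies < 1:
            raise ValueError("feature counts must be at least 1 (distance layers need features)")
        if self.spec.nrows * self.spec.ncols < 100:
            raise ValueError("grid too small to place the requested features")

    def resolved_patch_centers(self) -> tuple[tuple[float, float], ...]:
        if self.patch_centers is not None:
            return self.patch_centers
        xmin, ymin, xmax, ymax = self.spec.extent
        w, h = xmax - xmin, ymax - ymin
        source = (xmin + 0.50 * w, ymin + 0.12 * h)
        dests = (
            (xmin + 0.20 * w, ymin + 0.88 * h),
            (xmin + 0.50 * w, ymin + 0.88 * h),
            (xmin + 0.80 * w, ymin + 0.88 * h),
        )
        return (source,) + dests


@dataclass
class LineSet:
    """Polylines in map coordinates with per-line attributes."""

    lines: list[LineString]
    attrs: list[dict]

    def __post_init__(self) -> None:
        if len(self.lines) != len(self.attrs):
            raise ValueError("lines and attrs length mismatch")
        for ln in self.lines:
            if ln.length == 0:
                raise ValueError("degenerate zero-length polyline")

    def __len__(self) -> int:
        return len(self.lines)

    def union(self) -> shapely.Geometry | None:
        if not self.lines:
            return None
        return shapely.union_all(self.lines)

    def total_length(self) -> float:
        return float(sum(ln.length for ln in self.lines))

    def to_geojson(self, path: str | Path) -> Path:
        path = Path(path)
        features = [
            {
                "type": "Feature",
                "geometry": {"type": "LineString", "coordinates": [list(c) for c in ln.coords]},
                "properties": attrs,
            }
            for ln, attrs in zip(self.lines, self.attrs)
        ]
        path.write_text(json.dumps({"type": "FeatureCollection", "features": features}, indent=1))
        return path

    @classmethod
    def from_geojson(cls, path: str | Path) -> "LineSet":
        raw = json.loads(Path(path).read_text())
        lines, attrs = [], []
        for feat in raw["features"]:
            lines.append(LineString(feat["geometry"]["coordinates"]))
            attrs.append(feat.get("properties") or {})
        return cls(lines, attrs)


@dataclass(frozen=True)
class FenceRules:
    """Which boundary classes carry fences."""

    parcel_boundaries: bool = True  # only between distinct ownership classes
    road_one_side: bool = True  # fences modeled on a single side of maintained roads
    road_setback_m: float = 15.0


@dataclass
class TruthModel:
    """Generator-side preference model: the synthetic ground truth."""

    weights: dict[str, float]
    category_scores: dict[str, dict[int, float]]
    season: str = "spring"

    def __post_init__(self) -> None:
        total = sum(self.weights.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"truth weights must sum to 1 (got {total})")

    def suitability(self, stack: CovariateStack) -> RasterLayer:
        """True suitability through the shared weighted-combination scoring path."""
        return weighted_suitability(stack, self.weights, self.category_scores)


@dataclass
class Landscape:
    """Everything the downstream pipeline needs from one synthetic landscape."""

    params: LandscapeParams
    stacks: dict[str, CovariateStack]  # season -> stack
    truths: dict[str, TruthModel]
    parcels: LineSet
    roads: LineSet
    fences: LineSet
    source_center: tuple[float, float]
    dest_centers: tuple[tuple[float, float], ...]


def default_truth_weights(season: str) -> dict[str, float]:
    if season == "spring":
        return {
            "ndvi": 0.40,
            "landcover": 0.18,
            "dist_water": 0.12,
            "dist_roads": 0.10,
            "fence": 0.08,
            "topo_position": 0.07,
            "dist_wells": 0.05,
        }
    if season == "fall":
        return {
            "dist_water": 0.38,
            "ndvi": 0.20,
            "landcover": 0.17,
            "dist_roads": 0.09,
            "fence": 0.07,
            "topo_position": 0.05,
            "dist_wells": 0.04,
        }
    raise ValueError(f"unknown season {season!r}")


def default_category_scores(season: str) -> dict[str, dict[int, float]]:
    ndvi = {0: 0.1, 1: 0.4, 2: 0.7, 3: 1.0}
    if season == "fall":
        # lower greenness still acceptable in fall
        ndvi = {0: 0.3, 1: 0.6, 2: 1.0, 3: 0.8}
    return {
        "dist_wells": {0: 0.2, 1: 0.6, 2: 1.0},
        "dist_water": {0: 1.0, 1: 0.6, 2: 0.2},
        "dist_roads": {0: 0.3, 1: 0.7, 2: 1.0},
        "ndvi": ndvi,
        "fence": {0: 1.0, 1: 0.3},
        "landcover": {1: 0.05, 2: 0.1, 3: 1.0, 4: 0.5, 5: 0.45, 6: 0.75},
        "topo_position": {1: 0.3, 2: 1.0, 3: 0.2, 4: 0.5},
    }


def _saaty_snap(v: float) -> float:
    """Snap a weight ratio onto the discrete 1-9 judgment scale."""
    if v >= 1.0:
        return float(min(round(v), 9) or 1)
    return 1.0 / _saaty_snap(1.0 / v)


def gen_surveys(truth: TruthModel, n_experts: int, season: str, seed: int = 0, noise_sd: float = 0.25):
    """Synthetic expert surveys: pairwise judgments derived from the truth
    model's weight ratios with multiplicative lognormal noise, snapped to the
    1-9 scale.  Emulates the consumed (never administered) survey inputs."""
    from corridorscope.ahp import CATEGORY_CODES, PairwiseMatrix, Survey

    rng = np.random.default_rng(seed)
    var_labels = tuple(COVARIATE_ROLES)
    w = np.array([truth.weights[v] for v in var_labels])
    surveys = []
    for e in range(n_experts):
        def noisy_matrix(values, labels):
            n = len(values)
            m = np.eye(n)
            for i in range(n):
                for j in range(i + 1, n):
                    ratio = values[i] / values[j] * np.exp(rng.normal(0, noise_sd))
                    a = _saaty_snap(float(np.clip(ratio, 1 / 9, 9)))
                    m[i, j] = a
                    m[j, i] = 1 / a
            return PairwiseMatrix(m, labels)

        categories = {}
        for var in var_labels:
            codes = CATEGORY_CODES[var]
            scores = np.array([max(truth.category_scores[var][c], 0.05) for c in codes])
            categories[var] = noisy_matrix(scores, tuple(f"{var}:{c}" for c in codes))
        surveys.append(Survey(f"expert{e:02d}", season, noisy_matrix(w, var_labels), categories))
    return surveys


def sample_presences_from_truth(
    suitability: RasterLayer, n: int, seed: int = 0, concentration: float = 6.0
) -> PointSet:
    """Presence points drawn from valid cells with probability proportional
    to exp(concentration * true suitability) — the direct recovery fixture."""
    rng = np.random.default_rng(seed)
    cells = np.argwhere(suitability.mask)
    s = suitability.values[cells[:, 0], cells[:, 1]]
    w = np.exp(concentration * s)
    w /= w.sum()
    pick = rng.choice(len(cells), size=min(n, len(cells)), replace=False, p=w)
    spec = suitability.spec
    x = spec.origin_x + (cells[pick, 1] + 0.5) * spec.cellsize
    y = spec.origin_y - (cells[pick, 0] + 0.5) * spec.cellsize
    return PointSet(x, y)


# ---------------------------------------------------------------------------
# Vector generators
# ---------------------------------------------------------------------------

def gen_parcels_and_roads(params: LandscapeParams) -> tuple[LineSet, LineSet]:
    """Jittered rectangular parcel tessellation plus extent-crossing roads."""
    if params.n_parcels_x < 1 or params.n_parcels_y < 1:
        raise ValueError("need at least one parcel row and column")
    if params.n_roads < 1:
        raise ValueError("need at least one road")
    rng = np.random.default_rng(params.seed)
    spec = params.spec
    xmin, ymin, xmax, ymax = spec.extent
    nx, ny = params.n_parcels_x, params.n_parcels_y
    px, py = (xmax - xmin) / nx, (ymax - ymin) / ny

    # vertex lattice with jittered interior vertices
    vx = np.tile(xmin + np.arange(nx + 1) * px, (ny + 1, 1)).astype(float)
    vy = np.tile(ymin + np.arange(ny + 1)[:, None] * py, (1, nx + 1)).astype(float)
    jitter = 0.2
    jx = rng.uniform(-jitter * px, jitter * px, vx.shape)
    jy = rng.uniform(-jitter * py, jitter * py, vy.shape)
    jx[:, 0] = jx[:, -1] = 0.0
    jy[0, :] = jy[-1, :] = 0.0
    vx += jx
    vy += jy

    ownership = rng.choice(_OWNERSHIP_CLASSES, size=(ny, nx), p=[0.6, 0.25, 0.15])
    lines: list[LineString] = []
    attrs: list[dict] = []
    # internal vertical boundaries: parcel (ix, iy) | (ix+1, iy)
    for iy in range(ny):
        for ix in range(nx - 1):
            ln = LineString(
                [(vx[iy, ix + 1], vy[iy, ix + 1]), (vx[iy + 1, ix + 1], vy[iy + 1, ix + 1])]
            )
            lines.append(ln)
            attrs.append(
                {
                    "parcel_a": iy * nx + ix,
                    "parcel_b": iy * nx + ix + 1,
                    "own_a": str(ownership[iy, ix]),
                    "own_b": str(ownership[iy, ix + 1]),
                }
            )
    # internal horizontal boundaries: parcel (ix, iy) | (ix, iy+1)
    for iy in range(ny - 1):
        for ix in range(nx):
            ln = LineString(
                [(vx[iy + 1, ix], vy[iy + 1, ix]), (vx[iy + 1, ix + 1], vy[iy + 1, ix + 1])]
            )
            lines.append(ln)
            attrs.append(
                {
                    "parcel_a": iy * nx + ix,
                    "parcel_b": (iy + 1) * nx + ix,
                    "own_a": str(ownership[iy, ix]),
                    "own_b": str(ownership[iy + 1, ix]),
                }
            )
    parcels = LineSet(lines, attrs)

    roads_lines: list[LineString] = []
    roads_attrs: list[dict] = []
    for k in range(params.n_roads):
        frac = (k + 1) / (params.n_roads + 1)
        amp = 0.04 * (xmax - xmin) * rng.uniform(0.3, 1.0)
        phase = rng.uniform(0, 2 * np.pi)
        if k % 2 == 0:  # roughly vertical road, touching top and bottom edges
            x0 = xmin + frac * (xmax - xmin)
            ys = np.linspace(ymin, ymax, 40)
            xs = np.clip(x0 + amp * np.sin(2 * np.pi * (ys - ymin) / (ymax - ymin) + phase), xmin, xmax)
        else:  # roughly horizontal
            y0 = ymin + frac * (ymax - ymin)
            xs = np.linspace(xmin, xmax, 40)
            ys = np.clip(y0 + amp * np.sin(2 * np.pi * (xs - xmin) / (xmax - xmin) + phase), ymin, ymax)
        roads_lines.append(LineString(np.column_stack([xs, ys])))
        roads_attrs.append({"road_id": k, "maintained": True})
    roads = LineSet(roads_lines, roads_attrs)
    return parcels, roads


def model_fences(parcels: LineSet, roads: LineSet, rules: FenceRules | None = None) -> LineSet:
    """Fence lines from ownership boundaries and one side of maintained roads,
    dissolved so shared boundaries are emitted once."""
    rules = rules or FenceRules()
    pieces: list[shapely.Geometry] = []
    if rules.parcel_boundaries:
        for ln, attrs in zip(parcels.lines, parcels.attrs):
            own_a, own_b = attrs.get("own_a"), attrs.get("own_b")
            if own_a is None or own_b is None or own_a != own_b:
                pieces.append(ln)
    if rules.road_one_side:
        for ln, attrs in zip(roads.lines, roads.attrs):
            if attrs.get("maintained", True):
                off = shapely.offset_curve(ln, rules.road_setback_m)
                if not off.is_empty:
                    pieces.append(off)
    if not pieces:
        return LineSet([], [])
    dissolved = shapely.union_all(pieces)
    merged = shapely.line_merge(dissolved)
    parts = [g for g in shapely.get_parts(np.atleast_1d(merged)) if g.length > 0]
    return LineSet([LineString(p) for p in parts], [{"source": "dissolved"} for _ in parts])


def rasterize_lines(lines: LineSet, spec: GridSpec) -> RasterLayer:
    """Binary layer marking cells whose centre lies within cellsize/2 of a line."""
    out = np.zeros(spec.shape, dtype=np.int64)
    geom = lines.union()
    if geom is not None:
        xs, ys = spec.cell_centers()
        pts = shapely.points(xs.ravel(), ys.ravel())
        shapely.prepare(geom)
        hit = shapely.dwithin(geom, pts, spec.cellsize / 2.0)
        out = hit.reshape(spec.shape).astype(np.int64)
    return RasterLayer(spec, out, "binary")


def fence_accuracy(modeled: LineSet, truth_points: PointSet, buffer_m: float = 15.0) -> float:
    """Fraction of ground-truth points whose buffer disk meets a modeled line."""
    if buffer_m <= 0:
        raise ValueError("buffer must be positive")
    if len(truth_points) == 0:
        raise ValueError("empty ground-truth point set")
    geom = modeled.union()
    if geom is None:
        return 0.0
    pts = shapely.points(truth_points.x, truth_points.y)
    shapely.prepare(geom)
    return float(np.mean(shapely.dwithin(geom, pts, buffer_m)))


def gen_fence_truth(
    fences: LineSet,
    n: int = 1788,
    displacement_sd: float = 2.0,
    contamination: float = 0.0,
    seed: int = 0,
    extent: tuple[float, float, float, float] | None = None,
) -> PointSet:
    """Ground-truth fence points: on-line samples jittered by isotropic noise,
    plus a contamination fraction placed uniformly (unmapped fences)."""
    if n < 1:
        raise ValueError("need at least one truth point")
    rng = np.random.default_rng(seed)
    n_contam = int(round(contamination * n))
    n_on = n - n_contam
    lengths = np.array([ln.length for ln in fences.lines])
    if n_on > 0 and (len(lengths) == 0 or lengths.sum() == 0):
        raise ValueError("cannot sample truth points from an empty fence set")
    xs, ys = [], []
    if n_on > 0:
        cum = np.cumsum(lengths)
        d = rng.uniform(0, cum[-1], n_on)
        idx = np.searchsorted(cum, d)
        for i, di in zip(idx, d):
            offset = di - (cum[i] - lengths[i])
            p = fences.lines[i].interpolate(offset)
            xs.append(p.x)
            ys.append(p.y)
        xs = list(np.array(xs) + rng.normal(0, displacement_sd, n_on))
        ys = list(np.array(ys) + rng.normal(0, displacement_sd, n_on))
    if n_contam > 0:
        if extent is None:
            bx = shapely.bounds(fences.union())
            extent = (bx[0], bx[1], bx[2], bx[3])
        xmin, ymin, xmax, ymax = extent
        xs.extend(rng.uniform(xmin, xmax, n_contam))
        ys.extend(rng.uniform(ymin, ymax, n_contam))
    return PointSet(np.array(xs), np.array(ys))


# ---------------------------------------------------------------------------
# Raster generators
# ---------------------------------------------------------------------------

def _rescale01(arr: np.ndarray) -> np.ndarray:
    lo, hi = arr.min(), arr.max()
    if hi == lo:
        raise ValueError("cannot rescale a constant field")
    return (arr - lo) / (hi - lo)


def _patch_bump(spec: GridSpec, centers: Sequence[tuple[float, float]], radius_m: float) -> np.ndarray:
    xs, ys = spec.cell_centers()
    bump = np.zeros(spec.shape)
    for cx, cy in centers:
        d2 = (xs - cx) ** 2 + (ys - cy) ** 2
        bump = np.maximum(bump, np.exp(-d2 / (2 * radius_m**2)))
    return bump


def _landcover(spec: GridSpec, props: dict[str, float], rng: np.random.Generator) -> RasterLayer:
    fieldv = gaussian_filter(rng.standard_normal(spec.shape), sigma=4.0)
    order = [c for c in _CLASS_ORDER if props.get(c, 0) > 0]
    fracs = np.array([props[c] for c in order], dtype=float)
    leftover = 1.0 - fracs.sum()
    if leftover > 1e-9:  # remainder goes to grassland
        fracs[order.index("grassland")] += leftover
    cum = np.cumsum(fracs)[:-1]
    thresholds = np.quantile(fieldv, cum)
    codes_arr = np.digitize(fieldv, thresholds)
    codes = np.array([LANDCOVER_CODES[c] for c in order])[codes_arr]
    return RasterLayer(spec, codes, "categorical")


def _topo(spec: GridSpec, rng: np.random.Generator) -> RasterLayer:
    elev = gaussian_filter(rng.standard_normal(spec.shape), sigma=6.0)
    tpi = elev - uniform_filter(elev, size=15)
    gy, gx = np.gradient(elev, spec.cellsize)
    slope = np.hypot(gx, gy)
    t = 1.2 * tpi.std()
    out = np.full(spec.shape, TOPO_CODES["flat"], dtype=np.int64)
    out[slope > np.quantile(slope, 0.85)] = TOPO_CODES["steep"]
    out[tpi < -t] = TOPO_CODES["canyon"]
    out[tpi > t] = TOPO_CODES["ridge"]
    return RasterLayer(spec, out, "categorical")


def _scatter_cells(
    spec: GridSpec, n: int, rng: np.random.Generator, near: tuple[float, float] | None = None, sd_m: float = 0.0
) -> list[tuple[int, int]]:
    if near is not None:
        x = rng.normal(near[0], sd_m, n)
        y = rng.normal(near[1], sd_m, n)
        r, c = spec.index_of(x, y)
        return list({(int(a), int(b)) for a, b in zip(r, c)})
    r = rng.integers(0, spec.nrows, n)
    c = rng.integers(0, spec.ncols, n)
    return list({(int(a), int(b)) for a, b in zip(r, c)})


def gen_covariates(params: LandscapeParams, season: str = "spring") -> CovariateStack:
    """Seven aligned covariate layers for one season."""
    return gen_landscape(params, seasons=(season,)).stacks[season]


def gen_landscape(params: LandscapeParams, seasons: Sequence[str] = ("spring", "fall")) -> Landscape:
    """Full synthetic landscape bundle, shared across seasons except NDVI."""
    spec = params.spec
    centers = params.resolved_patch_centers()
    source, dests = centers[0], centers[1:]
    rng = np.random.default_rng(params.seed)
    # independent substreams so adding seasons never perturbs shared layers
    r_lc, r_topo, r_ndvi, r_wells, r_water = rng.spawn(5)

    parcels, roads = gen_parcels_and_roads(params)
    fences = model_fences(parcels, roads)
    fence_layer = rasterize_lines(fences, spec)

    landcover = _landcover(spec, params.landcover_props, r_lc)
    topo = _topo(spec, r_topo)

    well_cells = _scatter_cells(spec, params.n_wells, r_wells, near=source, sd_m=3 * params.patch_radius_m)
    dist_wells = distance_to_features(spec, well_cells)

    # one pond near every patch centre plus random water bodies elsewhere
    pond_cells = [spec.index_of(np.array([cx]), np.array([cy])) for cx, cy in centers]
    water_cells = [(int(r[0]), int(c[0])) for r, c in pond_cells]
    extra = max(params.n_water_bodies - len(water_cells), 0)
    water_cells += _scatter_cells(spec, extra, r_water)
    dist_water = distance_to_features(spec, water_cells)

    road_layer = rasterize_lines(roads, spec)
    road_cells = [tuple(rc) for rc in np.argwhere(road_layer.values == 1)]
    dist_roads = distance_to_features(spec, road_cells)

    ndvi_base = _rescale01(gaussian_filter(r_ndvi.standard_normal(spec.shape), sigma=params.ndvi_corr_length))
    bump = _patch_bump(spec, centers, params.patch_radius_m)

    stacks: dict[str, CovariateStack] = {}
    truths: dict[str, TruthModel] = {}
    for season in seasons:
        boost = 0.5 if season == "spring" else 0.35
        ndvi = np.clip(0.05 + 0.5 * ndvi_base + boost * bump, 0.0, 1.0)
        stack = CovariateStack(
            {
                "dist_wells": dist_wells,
                "dist_water": dist_water,
                "dist_roads": dist_roads,
                "ndvi": RasterLayer(spec, ndvi, "continuous"),
                "fence": fence_layer,
                "landcover": landcover,
                "topo_position": topo,
            }
        )
        stacks[season] = stack
        truths[season] = TruthModel(default_truth_weights(season), default_category_scores(season), season)
    return Landscape(params, stacks, truths, parcels, roads, fences, source, tuple(dests))
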