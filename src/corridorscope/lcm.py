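"""Least-cost connectivity: cost-distance accumulation, corridor surfaces,
least-cost paths, and percentile corridor slicing.

The grid graph follows the de facto GIS convention: 8-neighborhood, edge
weight = mean of the two endpoint costs times the centre-to-centre distance
(cellsize, or cellsize * sqrt(2) on diagonals).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from corridorscope.ahp import R_MIN
from corridorscope.raster import RasterLayer

__all__ = [
    "CorridorMask",
    "UNREACHABLE",
    "build_cost_graph",
    "cost_distance",
    "corridor_surface",
    "least_cost_path",
    "slice_corridor",
]

UNREACHABLE = np.inf

_OFFSETS = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


@dataclass
class CorridorMask:
    """Binary corridor selection with full provenance."""

    layer: RasterLayer
    season: str
    hsm: str
    method: str
    threshold: float
    basis: str = "area_percentile"

    def __post_init__(self) -> None:
        if self.layer.kind != "binary":
            raise ValueError("corridor mask must be a binary layer")
        if self.hsm not in ("maxent", "ahp", "truth"):
            raise ValueError(f"unknown hsm {self.hsm!r}")
        if self.method not in ("lcm", "circuit"):
            raise ValueError(f"unknown method {self.method!r}")

    @property
    def cells(self) -> np.ndarray:
        return self.layer.values.astype(bool) & self.layer.mask

    def area_fraction(self) -> float:
        return float(self.cells.sum() / self.layer.mask.sum())


def _node_ids(mask: np.ndarray) -> np.ndarray:
    ids = np.full(mask.shape, -1, dtype=np.int64)
    ids[mask] = np.arange(mask.sum())
    return ids


def build_cost_graph(cost: RasterLayer, neighborhood: int = 8):
    """Sparse symmetric graph over valid cells.

    Returns (ids, csr_matrix) where ids maps grid cells to node indices.
    """
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    vals = cost.values
    mask = cost.mask
    if np.any(vals[mask] < R_MIN - 1e-12):
        raise ValueError(f"costs must be at least {R_MIN}")
    ids = _node_ids(mask)
    n = int(mask.sum())
    cs = cost.spec.cellsize
    rows_l, cols_l, data_l = [], [], []
    # each undirected edge is emitted once via forward offsets, then mirrored
    for dr, dc in [(0, 1), (1, -1), (1, 0), (1, 1)] if neighborhood == 8 else [(0, 1), (1, 0)]:
        a = np.zeros(mask.shape, dtype=bool)
        r0, r1 = max(0, -dr), min(mask.shape[0], mask.shape[0] - dr)
        c0, c1 = max(0, -dc), min(mask.shape[1], mask.shape[1] - dc)
        a[r0:r1, c0:c1] = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        src = ids[a]
        rr, cc = np.nonzero(a)
        dst = ids[rr + dr, cc + dc]
        d = cs * (np.sqrt(2.0) if dr and dc else 1.0)
        w = 0.5 * (vals[rr, cc] + vals[rr + dr, cc + dc]) * d
        rows_l.append(src)
        cols_l.append(dst)
        data_l.append(w)
    src = np.concatenate(rows_l) if rows_l else np.array([], dtype=np.int64)
    dst = np.concatenate(cols_l) if cols_l else np.array([], dtype=np.int64)
    w = np.concatenate(data_l) if data_l else np.array([])
    graph = coo_matrix(
        (np.r_[w, w], (np.r_[src, dst], np.r_[dst, src])), shape=(n, n)
    ).tocsr()
    return ids, graph


def _cells_to_nodes(ids: np.ndarray, cells) -> np.ndarray:
    cells = np.asarray(list(cells), dtype=np.int64).reshape(-1, 2)
    nodes = ids[cells[:, 0], cells[:, 1]]
    if np.any(nodes < 0):
        raise ValueError("source cells fall outside the valid mask")
    return nodes


def cost_distance(cost: RasterLayer, sources, neighborhood: int = 8) -> RasterLayer:
    """Minimal accumulated edge weight from any source cell to every cell.

    Unreachable cells carry +inf and are masked out.
    """
    ids, graph = build_cost_graph(cost, neighborhood)
    nodes = _cells_to_nodes(ids, sources)
    if len(nodes) == 0:
        raise ValueError("empty source set")
    dist = dijkstra(graph, directed=False, indices=nodes, min_only=True)
    out = np.full(cost.spec.shape, UNREACHABLE)
    out[cost.mask] = dist
    mask = cost.mask & np.isfinite(out)
    out[~mask] = UNREACHABLE
    return RasterLayer(cost.spec, out, "continuous", mask)


def corridor_surface(cd_source: RasterLayer, cd_dest: RasterLayer) -> RasterLayer:
    """Cellwise sum of the two accumulation surfaces; its minimum equals the
    source-to-destination least-cost-path cost."""
    if cd_source.spec.shape != cd_dest.spec.shape:
        raise ValueError("grid mismatch between accumulation surfaces")
    mask = cd_source.mask & cd_dest.mask
    vals = np.where(mask, cd_source.values + cd_dest.values, UNREACHABLE)
    return RasterLayer(cd_source.spec, vals, "continuous", mask)


def least_cost_path(
    cost: RasterLayer, source_cells, dest_cells, neighborhood: int = 8
) -> tuple[list[tuple[int, int]], float]:
    """Optimal path from the source set to the destination set.

    The path is backtracked from the cheapest destination cell; among equal
    predecessors the smallest (row, col) wins, making ties deterministic.
    """
    cd = cost_distance(cost, source_cells, neighborhood)
    dest = np.asarray(list(dest_cells), dtype=np.int64).reshape(-1, 2)
    dvals = cd.values[dest[:, 0], dest[:, 1]]
    if not np.isfinite(dvals).any():
        raise ValueError("destination unreachable from source set")
    best = int(np.argmin(dvals))
    total = float(dvals[best])
    cur = (int(dest[best, 0]), int(dest[best, 1]))
    sources = {tuple(map(int, c)) for c in np.asarray(list(source_cells)).reshape(-1, 2)}
    cs = cost.spec.cellsize
    path = [cur]
    offsets = _OFFSETS if neighborhood == 8 else [(-1, 0), (0, -1), (0, 1), (1, 0)]
    guard = cost.spec.nrows * cost.spec.ncols + 1
    for _ in range(guard):
        if cur in sources or cd.values[cur] == 0.0:
            break
        candidates = []
        for dr, dc in offsets:
            r, c = cur[0] + dr, cur[1] + dc
            if not (0 <= r < cost.spec.nrows and 0 <= c < cost.spec.ncols) or not cd.mask[r, c]:
                continue
            d = cs * (np.sqrt(2.0) if dr and dc else 1.0)
            w = 0.5 * (cost.values[cur] + cost.values[r, c]) * d
            if abs(cd.values[r, c] + w - cd.values[cur]) <= 1e-9 * max(1.0, cd.values[cur]):
                candidates.append((r, c))
        if not candidates:
            raise RuntimeError("backtracking failed; inconsistent cost-distance surface")
        cur = min(candidates)
        path.append(cur)
    path.reverse()
    return path, total


def slice_corridor(
    surface: RasterLayer,
    p: float,
    basis: str = "area_percentile",
    *,
    season: str = "na",
    hsm: str = "maxent",
    method: str = "lcm",
) -> CorridorMask:
    """Select the most traversable p percent of the surface.

    ``area_percentile``: cells at or below the p-th percentile of valid
    values (ties included, so the mask is the minimal superset covering at
    least p% of valid cells).  ``value_range``: cells at or below
    min + (p/100)(max - min).
    """
    if not 0 < p <= 100:
        raise ValueError("p must lie in (0, 100]")
    vals = surface.values[surface.mask]
    if np.ptp(vals) == 0:
        raise ValueError("cannot slice a constant surface")
    if basis == "area_percentile":
        k = max(int(np.ceil(p / 100.0 * len(vals))), 1)
        threshold = np.partition(vals, k - 1)[k - 1]
    elif basis == "value_range":
        threshold = vals.min() + (p / 100.0) * (vals.max() - vals.min())
    else:
        raise ValueError(f"unknown slicing basis {basis!r}")
    sel = (surface.values <= threshold) & surface.mask
    layer = RasterLayer(surface.spec, sel.astype(np.int64), "binary", surface.mask.copy())
    return CorridorMask(layer, season, hsm, method, p, basis)
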