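"""Circuit-theory connectivity: conductance network, focal-region
contraction, voltage/current solves, effective resistance and current maps.

Edge conductance is 1 / (mean endpoint resistance * centre distance) — the
same edge rule as the least-cost graph, so both engines see one landscape.
Focal regions are contracted to supernodes (zero internal resistance).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix, csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.sparse.linalg import spsolve

from corridorscope.ahp import R_MIN
from corridorscope.lcm import CorridorMask
from corridorscope.raster import RasterLayer

__all__ = [
    "CircuitNetwork",
    "CircuitSolution",
    "build_network",
    "solve_pair",
    "current_map",
    "cumulative_current",
    "slice_current",
    "patches_connected",
]

_OFFSETS_8 = [(0, 1), (1, -1), (1, 0), (1, 1)]
_OFFSETS_4 = [(0, 1), (1, 0)]


@dataclass
class CircuitNetwork:
    """Conductance graph over valid cells with focal supernodes 0..k-1."""

    node_of: np.ndarray  # grid -> node id, -1 outside mask
    n_nodes: int
    focal_nodes: list[int]
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_g: np.ndarray
    component: np.ndarray  # component label per node
    spec: object
    mask: np.ndarray
    region_cells: list[np.ndarray]

    def laplacian(self) -> csr_matrix:
        n = self.n_nodes
        i = np.r_[self.edge_src, self.edge_dst]
        j = np.r_[self.edge_dst, self.edge_src]
        g = np.r_[self.edge_g, self.edge_g]
        a = coo_matrix((g, (i, j)), shape=(n, n)).tocsr()
        d = np.asarray(a.sum(axis=1)).ravel()
        return csr_matrix(coo_matrix((d, (np.arange(n), np.arange(n))), shape=(n, n))) - a

    def same_component(self, a: int, b: int) -> bool:
        return self.component[a] == self.component[b]


@dataclass
class CircuitSolution:
    voltages: np.ndarray
    edge_currents: np.ndarray  # aligned with network edge arrays, signed src->dst
    r_eff: float
    src: int
    dst: int
    injected: float = 1.0


def build_network(
    resistance: RasterLayer, focal_regions: list, neighborhood: int = 8
) -> CircuitNetwork:
    """Contract each focal region to a supernode and wire the rest of the grid."""
    if neighborhood not in (4, 8):
        raise ValueError("neighborhood must be 4 or 8")
    vals = resistance.values
    mask = resistance.mask
    if np.any(vals[mask] < R_MIN - 1e-12):
        raise ValueError(f"resistance must be at least {R_MIN}")
    regions = [np.asarray(list(r), dtype=np.int64).reshape(-1, 2) for r in focal_regions]
    seen = set()
    for k, cells in enumerate(regions):
        for r, c in cells:
            if not (0 <= r < mask.shape[0] and 0 <= c < mask.shape[1]) or not mask[r, c]:
                raise ValueError(f"focal region {k} extends outside the valid mask")
            if (r, c) in seen:
                raise ValueError("focal regions must be disjoint")
            seen.add((r, c))
    node_of = np.full(mask.shape, -1, dtype=np.int64)
    for k, cells in enumerate(regions):
        node_of[cells[:, 0], cells[:, 1]] = k
    free = mask & (node_of == -1)
    n_free = int(free.sum())
    node_of[free] = len(regions) + np.arange(n_free)
    n_nodes = len(regions) + n_free

    cs = resistance.spec.cellsize
    src_l, dst_l, g_l = [], [], []
    offsets = _OFFSETS_8 if neighborhood == 8 else _OFFSETS_4
    for dr, dc in offsets:
        a = np.zeros(mask.shape, dtype=bool)
        r0, r1 = max(0, -dr), min(mask.shape[0], mask.shape[0] - dr)
        c0, c1 = max(0, -dc), min(mask.shape[1], mask.shape[1] - dc)
        a[r0:r1, c0:c1] = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        rr, cc = np.nonzero(a)
        u = node_of[rr, cc]
        v = node_of[rr + dr, cc + dc]
        d = cs * (np.sqrt(2.0) if dr and dc else 1.0)
        g = 1.0 / (0.5 * (vals[rr, cc] + vals[rr + dr, cc + dc]) * d)
        keep = u != v  # edges internal to a supernode vanish
        src_l.append(u[keep])
        dst_l.append(v[keep])
        g_l.append(g[keep])
    src = np.concatenate(src_l)
    dst = np.concatenate(dst_l)
    g = np.concatenate(g_l)
    # merge parallel edges created by contraction (conductances add)
    lo = np.minimum(src, dst)
    hi = np.maximum(src, dst)
    key = lo * n_nodes + hi
    order = np.argsort(key, kind="stable")
    key, lo, hi, g = key[order], lo[order], hi[order], g[order]
    uniq, start = np.unique(key, return_index=True)
    g_merged = np.add.reduceat(g, start)
    src, dst = lo[start], hi[start]

    adj = coo_matrix(
        (np.r_[g_merged, g_merged], (np.r_[src, dst], np.r_[dst, src])), shape=(n_nodes, n_nodes)
    ).tocsr()
    _, comp = connected_components(adj, directed=False)
    return CircuitNetwork(
        node_of, n_nodes, list(range(len(regions))), src, dst, g_merged, comp, resistance.spec, mask, regions
    )


def solve_pair(network: CircuitNetwork, src: int, dst: int) -> CircuitSolution:
    """Ground the destination supernode, inject unit current at the source,
    and solve the reduced Laplacian system."""
    if src == dst:
        raise ValueError("source and destination must differ")
    s, d = network.focal_nodes[src], network.focal_nodes[dst]
    if not network.same_component(s, d):
        raise ValueError("focal pair lies in different components (infinite resistance)")
    lap = network.laplacian().tolil()
    keep = np.ones(network.n_nodes, dtype=bool)
    keep[d] = False
    reduced = lap[np.ix_(keep, keep)].tocsr()
    rhs = np.zeros(network.n_nodes)
    rhs[s] = 1.0
    v_red = spsolve(reduced, rhs[keep])
    voltages = np.zeros(network.n_nodes)
    voltages[keep] = v_red
    currents = network.edge_g * (voltages[network.edge_src] - voltages[network.edge_dst])
    return CircuitSolution(voltages, currents, float(voltages[s]), s, d)


def kirchhoff_violation(network: CircuitNetwork, solution: CircuitSolution) -> float:
    """Max |net current| over non-focal nodes (should vanish)."""
    net = np.zeros(network.n_nodes)
    np.subtract.at(net, network.edge_src, solution.edge_currents)
    np.add.at(net, network.edge_dst, solution.edge_currents)
    net[solution.src] += solution.injected
    net[solution.dst] -= solution.injected
    return float(np.max(np.abs(net)))


def current_map(network: CircuitNetwork, solution: CircuitSolution) -> RasterLayer:
    """Per-cell current: half the absolute current over incident edges;
    the focal pair's cells carry the injected current."""
    flow = np.zeros(network.n_nodes)
    np.add.at(flow, network.edge_src, np.abs(solution.edge_currents))
    np.add.at(flow, network.edge_dst, np.abs(solution.edge_currents))
    flow *= 0.5
    flow[solution.src] = solution.injected
    flow[solution.dst] = solution.injected
    out = np.zeros(network.mask.shape)
    valid = network.node_of >= 0
    out[valid] = flow[network.node_of[valid]]
    return RasterLayer(network.spec, out, "continuous", network.mask.copy())


def cumulative_current(
    resistance: RasterLayer,
    focal_regions: list,
    pairs: list[tuple[int, int]],
    neighborhood: int = 8,
) -> RasterLayer:
    """Sum of pairwise current maps over the requested ordered pairs."""
    if len(focal_regions) < 2:
        raise ValueError("need at least two focal regions")
    network = build_network(resistance, focal_regions, neighborhood)
    total = np.zeros(resistance.spec.shape)
    for a, b in pairs:
        cm = current_map(network, solve_pair(network, a, b))
        total += cm.values
    return RasterLayer(resistance.spec, total, "continuous", resistance.mask.copy())


def slice_current(
    current: RasterLayer,
    p: float,
    focal_regions: list | None = None,
    *,
    season: str = "na",
    hsm: str = "maxent",
) -> tuple[CorridorMask, bool | None]:
    """Select the highest-current p percent of valid cells.

    Returns the mask plus a diagnostic: whether the first two focal regions
    are connected through the mask (None when no regions are given).
    """
    if not 0 < p <= 100:
        raise ValueError("p must lie in (0, 100]")
    vals = current.values[current.mask]
    if np.ptp(vals) == 0:
        raise ValueError("cannot slice a constant current map")
    k = max(int(np.ceil(p / 100.0 * len(vals))), 1)
    threshold = np.partition(vals, len(vals) - k)[len(vals) - k]
    sel = (current.values >= threshold) & current.mask
    layer = RasterLayer(current.spec, sel.astype(np.int64), "binary", current.mask.copy())
    mask_obj = CorridorMask(layer, season, hsm, "circuit", p)
    connected = None
    if focal_regions is not None and len(focal_regions) >= 2:
        connected = patches_connected(sel, focal_regions[0], focal_regions[1])
    return mask_obj, connected


def patches_connected(sel: np.ndarray, region_a, region_b) -> bool:
    """Whether the two cell regions touch one 8-connected component of ``sel``."""
    from scipy.ndimage import label

    lab, _ = label(sel, structure=np.ones((3, 3)))
    a = np.asarray(list(region_a), dtype=np.int64).reshape(-1, 2)
    b = np.asarray(list(region_b), dtype=np.int64).reshape(-1, 2)
    la = set(lab[a[:, 0], a[:, 1]]) - {0}
    lb = set(lab[b[:, 0], b[:, 1]]) - {0}
    return bool(la & lb)
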