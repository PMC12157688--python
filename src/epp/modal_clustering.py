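"""Modal clustering of a density grid and construction of the cluster graph.

Grid points are visited in descending order of density down to a noise
floor.  A point none of whose 4-neighbors is classified founds a new
cluster (it is a local maximum); a point whose classified 4-neighbors span
two or more clusters becomes a boundary point; otherwise it joins its
neighbors' cluster.  As each point is classified, seven of its eight
neighbors are marked contiguous (one diagonal omitted on a counter modulo
4, keeping the growth radially symmetric).  Points below the floor are then
classified outward in contiguity layers, attaching them to the nearest
significant cluster.  The boundary points are chained into edges, giving a
plane graph whose faces are clusters and whose vertices are the meeting
points of three or more clusters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import WidenSignal

log = logging.getLogger("epp")

__all__ = ["ClusterLabeling", "ClusterEdge", "ClusterGraph", "noise_floor",
           "modal_cluster", "build_cluster_graph", "resolve_face_grid",
           "assign_events", "BOUNDARY", "UNCLASSIFIED"]

UNCLASSIFIED = 0
BOUNDARY = -1

MAX_CLUSTERS = 12
MAX_EDGES = 32


def noise_floor(density: np.ndarray, weights: np.ndarray, W: float,
                sigma: float = 3.0) -> float:
    """Lowest density at which a kernel-spot-sized window holds > sigma^2 events.

    A window of round((4W (G-1))^2) grid points (the +/-2W spot of the
    current kernel) slides along the grid points sorted ascending by
    density; the threshold is the highest density inside the first window
    whose summed weights exceed sigma^2 (9 events at sigma = 3).  Returns
    +inf when no window qualifies: no cluster may be founded.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    G = density.shape[0]
    L = int(round((4.0 * W * (G - 1)) ** 2))
    L = max(L, 1)
    flat_d = density.ravel()
    flat_w = weights.ravel()
    if flat_w.sum() <= sigma * sigma or L > flat_d.size:
        return np.inf
    order = np.argsort(flat_d, kind="stable")
    w_sorted = flat_w[order]
    sums = np.convolve(w_sorted, np.ones(L), mode="valid")
    hits = np.flatnonzero(sums > sigma * sigma)
    if hits.size == 0:
        return np.inf
    return float(flat_d[order[hits[0] + L - 1]])


@dataclass
class ClusterLabeling:
    """Complete partition of the grid into clusters and boundary points."""

    labels: np.ndarray              # int grid: >=1 cluster id, -1 boundary
    modes: dict                     # cluster id -> ((row, col), density)
    noise_floor: float
    n_clusters: int


# neighbor offsets as (drow, dcol); diagonals cycled for the modulo-4 omission
_N4 = ((-1, 0), (1, 0), (0, -1), (0, 1))
_DIAG = ((-1, 1), (1, 1), (1, -1), (-1, -1))


def modal_cluster(density: np.ndarray, floor: float,
                  max_clusters: int = MAX_CLUSTERS) -> ClusterLabeling:
    """Descending-density sweep assigning every grid point to a cluster or
    boundary.  Raises WidenSignal when more than ``max_clusters`` modes are
    founded (the caller doubles W and restarts from the weights).
    """
    G = density.shape[0]
    flat_d = density.ravel()
    labels = np.zeros(G * G, dtype=np.int32)
    contiguous = np.zeros(G * G, dtype=bool)
    modes: dict = {}
    n_clusters = 0
    diag_counter = 0

    order = np.argsort(-flat_d, kind="stable")
    above = flat_d >= floor
    main = order[above[order]]

    def classify(p: int, allow_new: bool) -> bool:
        nonlocal n_clusters, diag_counter
        r, c = divmod(p, G)
        first = 0
        distinct2 = False
        saw_boundary = False
        for dr, dc in _N4:
            rr, cc = r + dr, c + dc
            if 0 <= rr < G and 0 <= cc < G:
                lab = labels[rr * G + cc]
                if lab > 0:
                    if first == 0:
                        first = lab
                    elif lab != first:
                        distinct2 = True
                elif lab == BOUNDARY:
                    saw_boundary = True
        if distinct2:
            labels[p] = BOUNDARY
        elif first:
            labels[p] = first
        elif saw_boundary:
            labels[p] = BOUNDARY
        elif allow_new:
            n_clusters += 1
            if n_clusters > max_clusters:
                raise WidenSignal(f"more than {max_clusters} clusters")
            labels[p] = n_clusters
            modes[n_clusters] = ((r, c), float(flat_d[p]))
        else:
            return False
        omit = _DIAG[diag_counter & 3]
        diag_counter += 1
        for dr, dc in _N4 + _DIAG:
            if (dr, dc) == omit:
                continue
            rr, cc = r + dr, c + dc
            if 0 <= rr < G and 0 <= cc < G:
                contiguous[rr * G + cc] = True
        return True

    for p in main:
        classify(p, allow_new=True)

    if n_clusters == 0:
        return ClusterLabeling(labels.reshape(G, G), modes, floor, 0)

    # below-floor flood: classify contiguity-marked points outward in layers
    while True:
        cand = np.flatnonzero((labels == UNCLASSIFIED) & contiguous)
        if cand.size == 0:
            if not (labels == UNCLASSIFIED).any():
                break
            cand = np.flatnonzero(labels == UNCLASSIFIED)
        cand = cand[np.argsort(-flat_d[cand], kind="stable")]
        progressed = False
        for p in cand:
            if classify(p, allow_new=False):
                progressed = True
        if not progressed:
            # pathological stall: attach by any classified 8-neighbor
            for p in cand:
                r, c = divmod(p, G)
                best = 0
                for dr, dc in _N4 + _DIAG:
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < G and 0 <= cc < G:
                        lab = labels[rr * G + cc]
                        if lab > 0 and (best == 0 or lab < best):
                            best = lab
                if best:
                    labels[p] = best
                    progressed = True
            if not progressed:
                raise WidenSignal("grid flood stalled; pathological labeling")

    return ClusterLabeling(labels.reshape(G, G), modes, floor, n_clusters)


@dataclass
class ClusterEdge:
    """One boundary chain separating exactly two clusters."""

    index: int
    faces: tuple[int, int]
    points: np.ndarray          # (k, 2) ordered (row, col) grid points
    saddle_density: float
    saddle_point: tuple[int, int]


@dataclass
class ClusterGraph:
    """Plane graph: faces are clusters, edges are boundary chains, vertices
    are grid points where three or more clusters meet."""

    faces: list[int]
    edges: list[ClusterEdge]
    vertices: list[tuple[int, int]]
    labels: np.ndarray = field(repr=False)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


def _adjacent_clusters(labels: np.ndarray, r: int, c: int) -> set[int]:
    G = labels.shape[0]
    out = set()
    for dr, dc in _N4 + _DIAG:
        rr, cc = r + dr, c + dc
        if 0 <= rr < G and 0 <= cc < G and labels[rr, cc] > 0:
            out.add(int(labels[rr, cc]))
    return out


def build_cluster_graph(labeling: ClusterLabeling, density: np.ndarray,
                        max_edges: int = MAX_EDGES) -> ClusterGraph:
    """Chain boundary points into edges and assemble the plane graph.

    Boundary points adjacent to a single cluster are absorbed into that
    face; points adjacent to >= 3 clusters become vertices; the remaining
    points, grouped by their separated cluster pair and 8-connectivity,
    form the edges.  Raises WidenSignal for non-chainable boundaries or
    more than ``max_edges`` edges.
    """
    labels = labeling.labels
    G = labels.shape[0]
    boundary = np.argwhere(labels == BOUNDARY)
    pair_points: dict[tuple[int, int], list[tuple[int, int]]] = {}
    vertices: list[tuple[int, int]] = []
    for r, c in boundary:
        adj = _adjacent_clusters(labels, r, c)
        if len(adj) == 0:
            raise WidenSignal("boundary point with no adjacent cluster")
        if len(adj) == 1:
            labels[r, c] = adj.pop()  # spur: absorb into the single face
        elif len(adj) == 2:
            key = tuple(sorted(adj))
            pair_points.setdefault(key, []).append((int(r), int(c)))
        else:
            vertices.append((int(r), int(c)))

    edges: list[ClusterEdge] = []
    for pair, pts in sorted(pair_points.items()):
        for comp in _components(pts):
            chain = _order_chain(comp)
            chain = _attach_vertices(chain, vertices)
            dens = density[chain[:, 0], chain[:, 1]]
            k = int(np.argmax(dens))
            edges.append(ClusterEdge(
                index=len(edges), faces=pair, points=chain,
                saddle_density=float(dens[k]),
                saddle_point=(int(chain[k, 0]), int(chain[k, 1]))))
            if len(edges) > max_edges:
                raise WidenSignal(f"more than {max_edges} edges")
    faces = sorted(labeling.modes.keys())
    return ClusterGraph(faces=faces, edges=edges, vertices=vertices, labels=labels)


def _components(points: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """8-connected components of a point set."""
    remaining = set(points)
    comps = []
    while remaining:
        seed = min(remaining)
        remaining.discard(seed)
        comp = [seed]
        stack = [seed]
        while stack:
            r, c = stack.pop()
            for dr, dc in _N4 + _DIAG:
                q = (r + dr, c + dc)
                if q in remaining:
                    remaining.discard(q)
                    comp.append(q)
                    stack.append(q)
        comps.append(comp)
    return comps


def _order_chain(comp: list[tuple[int, int]]) -> np.ndarray:
    """Order an 8-connected component into a walk (greedy nearest neighbor
    from an endpoint; loops start at the minimal point)."""
    if len(comp) <= 2:
        return np.array(sorted(comp), dtype=np.int64)
    pts = set(comp)
    nbrs = {p: [q for q in ((p[0] + dr, p[1] + dc) for dr, dc in _N4 + _DIAG)
                if q in pts] for p in comp}
    endpoints = sorted(p for p, ns in nbrs.items() if len(ns) <= 1)
    start = endpoints[0] if endpoints else min(comp)
    chain = [start]
    used = {start}
    cur = start
    while len(used) < len(comp):
        cands = [q for q in nbrs[cur] if q not in used]
        if not cands:
            # jump to the nearest unused point (thick boundary patches)
            rest = [q for q in comp if q not in used]
            cands = [min(rest, key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))]
        # prefer orthogonal steps, then lowest coordinates, for determinism
        nxt = min(cands, key=lambda q: (abs(q[0] - cur[0]) + abs(q[1] - cur[1]), q))
        chain.append(nxt)
        used.add(nxt)
        cur = nxt
    return np.array(chain, dtype=np.int64)


def _attach_vertices(chain: np.ndarray, vertices: list[tuple[int, int]]) -> np.ndarray:
    """Extend a chain with any vertex points 8-adjacent to its endpoints."""
    if not vertices:
        return chain
    out = chain
    for endpos, append in ((0, False), (-1, True)):
        r, c = out[endpos]
        near = [v for v in vertices
                if abs(v[0] - r) <= 1 and abs(v[1] - c) <= 1]
        if near:
            v = np.array(min(near), dtype=np.int64)[None, :]
            out = np.vstack([out, v]) if append else np.vstack([v, out])
    return out


def resolve_face_grid(labels: np.ndarray,
                      face_map: dict[int, int] | None = None) -> np.ndarray:
    """Grid of owning cluster per node: boundary nodes take the lowest
    adjacent cluster id (after optional merge mapping)."""
    out = labels.copy()
    if face_map:
        lut = np.zeros(max(face_map) + 2, dtype=np.int32)
        for k, v in face_map.items():
            lut[k] = v
        pos = out > 0
        out[pos] = lut[out[pos]]
    G = out.shape[0]
    while True:
        bd = np.argwhere(out == BOUNDARY)
        if bd.size == 0:
            break
        progressed = False
        for r, c in bd:
            adj = _adjacent_clusters(out, r, c)
            if adj:
                out[r, c] = min(adj)
                progressed = True
        if not progressed:  # isolated boundary blob: arbitrary but fixed
            out[out == BOUNDARY] = min(int(v) for v in np.unique(out) if v > 0)
    return out


def assign_events(x: np.ndarray, y: np.ndarray, face_grid: np.ndarray) -> np.ndarray:
    """Cluster id per event by nearest grid node."""
    G = face_grid.shape[0]
    ix = np.clip(np.rint(np.asarray(x) * (G - 1)).astype(np.int64), 0, G - 1)
    iy = np.clip(np.rint(np.asarray(y) * (G - 1)).astype(np.int64), 0, G - 1)
    return face_grid[iy, ix]
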