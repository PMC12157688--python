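"""Independent brute-force oracles used by the tests.

These deliberately avoid the code paths they check: the convolution oracle
sums Gaussian reflection images directly, the noise-floor oracle slides a
naive window, and the partition oracle enumerates 2-partitions of the face
adjacency graph with networkx.
"""

from __future__ import annotations

import itertools

import networkx as nx
import numpy as np


def reflected_gaussian_smooth(grid: np.ndarray, W: float) -> np.ndarray:
    """Direct separable convolution with a unit-mass Gaussian of SD W under
    reflective boundaries (explicit image sums; no transforms)."""
    G = grid.shape[0]
    h = 1.0 / (G - 1)
    period = 2 * (G - 1)
    pos = np.arange(G)

    def kernel_1d(dist: np.ndarray) -> np.ndarray:
        total = np.zeros_like(dist, dtype=float)
        for m in range(-4, 5):
            u = (dist + m * period) * h
            total += np.exp(-0.5 * (u / W) ** 2)
        return total * h / (np.sqrt(2 * np.pi) * W)

    K = np.zeros((G, G))
    for image in (pos, period - pos):
        K += kernel_1d(np.subtract.outer(pos, image))
    K[:, 0] /= 2.0     # endpoints are their own reflections
    K[:, -1] /= 2.0
    return K @ grid @ K.T


def naive_noise_floor(density: np.ndarray, weights: np.ndarray, W: float,
                      sigma: float = 3.0) -> float:
    """Literal sliding-window reading of the noise-floor rule."""
    G = density.shape[0]
    L = max(int(round((4.0 * W * (G - 1)) ** 2)), 1)
    d = density.ravel()
    w = weights.ravel()
    if w.sum() <= sigma * sigma or L > d.size:
        return np.inf
    order = np.argsort(d, kind="stable")
    for start in range(d.size - L + 1):
        idx = order[start:start + L]
        if w[idx].sum() > sigma * sigma:
            return float(d[idx[-1]])
    return np.inf


def contiguous_two_partitions(graph) -> set[tuple[int, int]]:
    """All (boundary bitset, in-side bitset) pairs whose sides are both
    connected in the face adjacency graph and whose boundary grid points
    form one 8-connected curve.  ``graph`` is a ClusterGraph."""
    faces = sorted(graph.faces)
    adj = nx.MultiGraph()
    adj.add_nodes_from(faces)
    for e in graph.edges:
        adj.add_edge(*e.faces, index=e.index)
    face_bit = {f: i for i, f in enumerate(faces)}
    out = set()
    for r in range(1, len(faces)):
        for combo in itertools.combinations(faces, r):
            S = set(combo)
            T = set(faces) - S
            if not nx.is_connected(adj.subgraph(S)):
                continue
            if not nx.is_connected(adj.subgraph(T)):
                continue
            bedges = [e for e in graph.edges
                      if (e.faces[0] in S) != (e.faces[1] in S)]
            pts = set()
            for e in bedges:
                pts.update(map(tuple, e.points))
            bg = nx.Graph()
            bg.add_nodes_from(pts)
            for (r0, c0) in pts:
                for dr in (-1, 0, 1):
                    for dc in (-1, 0, 1):
                        q = (r0 + dr, c0 + dc)
                        if q != (r0, c0) and q in pts:
                            bg.add_edge((r0, c0), q)
            if not pts or not nx.is_connected(bg):
                continue
            mask = sum(1 << e.index for e in bedges)
            inside = S if min(faces) in S else T
            out.add((mask, sum(1 << face_bit[f] for f in inside)))
    return out


def gaussian_bump_density(centers, sds, amps, grid_size: int = 129) -> np.ndarray:
    """Analytic sum-of-Gaussians density evaluated on the unit grid."""
    xs = np.linspace(0.0, 1.0, grid_size)
    X, Y = np.meshgrid(xs, xs)
    out = np.zeros_like(X)
    for (cx, cy), s, a in zip(centers, sds, amps):
        out += a * np.exp(-((X - cx) ** 2 + (Y - cy) ** 2) / (2 * s * s))
    return out


def random_cluster_graph(seed: int, grid_size: int = 129, max_faces: int = 6):
    """A real cluster graph from a random sum-of-Gaussians density, or None
    when the draw does not yield 2..max_faces clean faces."""
    from epp.errors import WidenSignal
    from epp.modal_clustering import build_cluster_graph, modal_cluster

    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 7))
    centers = rng.uniform(0.15, 0.85, size=(k, 2))
    sds = rng.uniform(0.05, 0.12, size=k)
    amps = rng.uniform(0.5, 2.0, size=k)
    density = gaussian_bump_density(centers, sds, amps, grid_size)
    try:
        labeling = modal_cluster(density, density.max() * 1e-4, max_clusters=8)
        if not 2 <= labeling.n_clusters <= max_faces:
            return None
        return build_cluster_graph(labeling, density), labeling
    except WidenSignal:
        return None


def as_merged(graph, labeling):
    """Wrap an unmerged ClusterGraph in the MergedGraph interface."""
    from epp.dbm_merging import MergedEdge, MergedGraph

    return MergedGraph(
        faces=list(graph.faces),
        edges=[MergedEdge(frozenset([e.index]), e.faces, e.saddle_density,
                          e.saddle_point, [e.points]) for e in graph.edges],
        face_map={f: f for f in graph.faces},
        modes={f: labeling.modes[f] for f in graph.faces})
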