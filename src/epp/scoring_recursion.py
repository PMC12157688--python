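"""Candidate scoring, per-pair analysis and the recursive gating driver.

Each candidate boundary is scored by integrating the density along it,
scaled to the approximate number of events within a strip of +/-W around
the border (lower is better).  In best-balance mode the score is divided
by the balance factor 4P(1-P), where P is the fraction of events on the
"in" side, penalizing lopsided splits.  ``analyze_pair`` runs the whole
weights -> KDE -> noise floor -> modal clustering -> cluster graph -> DBM
-> dual enumeration -> scoring chain for one dimension pair, doubling the
kernel width W and restarting whenever the grid is too complex.
``epp_recurse`` drives qualification and pair analysis per population and
recurses on both sides of the globally best split until no population
supports a further division; the resulting leaves are the algorithmic
phenotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .dbm_merging import dbm_merge
from .errors import ValidationError, WidenSignal
from .graph_simplification import dualize, enumerate_separations
from .io_transforms import EventMatrix
from .kde import GRID_SIZE, compute_weights, kde_dct, kde_variance
from .modal_clustering import (ClusterEdge, assign_events, build_cluster_graph,
                               modal_cluster, noise_floor, resolve_face_grid)
from .qualification import enumerate_pairs, qualify_dimension

log = logging.getLogger("epp")

__all__ = ["EPPConfig", "GateNode", "GatingTree", "score_boundary",
           "apply_balance", "analyze_pair", "epp_recurse", "stitch_chains"]

_W_MAX = 0.5  # beyond this the kernel is essentially flat; give up widening


@dataclass(frozen=True)
class EPPConfig:
    """Tunable parameters of the gating algorithm (all deterministic).

    ``W_init`` defaults to 0.01 of full scale for fluorescence and 0.025
    for mass cytometry when left None.  ``mode`` selects best_separation
    (fewest events near the boundary) or best_balance (the same score
    divided by 4P(1-P)).
    """

    W_init: float | None = None
    grid_size: int = GRID_SIZE
    sigma: float = 3.0
    dbm_z: float = 3.0
    dbm_require_both: bool = True
    kld_threshold_normal: float = 0.04
    kld_threshold_exponential: float = 0.2
    max_clusters: int = 12
    max_edges: int = 32
    mode: str = "best_balance"
    data_mode: str = "fluorescence"
    min_events_abs: int = 0
    min_events_rel: float = 0.0
    min_stop_strict: bool = False
    rdp_tolerance: float = 0.01

    def __post_init__(self) -> None:
        if self.mode not in ("best_separation", "best_balance"):
            raise ValidationError(f"unknown selection mode {self.mode!r}")
        if self.data_mode not in ("fluorescence", "mass"):
            raise ValidationError(f"unknown data mode {self.data_mode!r}")

    @property
    def w_init(self) -> float:
        if self.W_init is not None:
            return self.W_init
        return 0.025 if self.data_mode == "mass" else 0.01


def score_boundary(chains: list[np.ndarray], density: np.ndarray,
                   n: int, W: float) -> float:
    """Estimated events within +/-W of the boundary: n * 2W * integral of
    density along the chains (trapezoid over the ordered grid points)."""
    G = density.shape[0]
    total = 0.0
    for chain in chains:
        if len(chain) < 2:
            continue
        d = density[chain[:, 0], chain[:, 1]]
        seg = np.hypot(np.diff(chain[:, 0]), np.diff(chain[:, 1])) / (G - 1)
        total += float(np.sum(0.5 * (d[:-1] + d[1:]) * seg))
    return n * 2.0 * W * total


def apply_balance(score: float, P: float) -> float:
    """Divide by the balance factor 4P(1-P); identity at P = 0.5."""
    if not 0.0 < P < 1.0:
        raise ValidationError(f"balance fraction P={P} outside (0, 1)")
    return score / (4.0 * P * (1.0 - P))


@dataclass
class PairSplit:
    """Best candidate separation found for one dimension pair."""

    dims: tuple[int, int]
    W: float
    widened: bool
    boundary_edges: int
    chains: list[np.ndarray]
    in_faces: frozenset[int]
    in_events: np.ndarray          # bool per population event
    P: float
    score: float                   # events-near-boundary estimate
    selection_score: float         # balanced in best_balance mode


def analyze_pair(events: EventMatrix, dims: tuple[int, int],
                 cfg: EPPConfig) -> PairSplit | None:
    """Best separation of this population in the (x, y) = dims projection,
    or None when no statistically supported separation exists."""
    i, j = dims
    x = events.values[:, i]
    y = events.values[:, j]
    n = len(x)
    if n <= cfg.sigma ** 2:
        return None
    weights = compute_weights(x, y, cfg.grid_size)
    W = cfg.w_init
    while W <= _W_MAX:
        density = kde_dct(weights, W)
        floor = noise_floor(density, weights, W, cfg.sigma)
        if not np.isfinite(floor):
            W *= 2.0
            continue
        try:
            labeling = modal_cluster(density, floor, cfg.max_clusters)
            if labeling.n_clusters == 0:
                W *= 2.0
                continue
            if labeling.n_clusters == 1:
                return None
            graph = build_cluster_graph(labeling, density, cfg.max_edges)
        except WidenSignal as sig:
            log.debug("dims %s: widening W to %g (%s)", dims, 2 * W, sig)
            W *= 2.0
            continue
        variance = kde_variance(weights, W)
        merged = dbm_merge(graph, labeling, density, variance, n,
                           z=cfg.dbm_z, require_both=cfg.dbm_require_both)
        if merged.n_faces <= 1:
            return None
        face_grid = resolve_face_grid(labeling.labels, merged.face_map)
        ev_face = assign_events(x, y, face_grid)
        edge_by_index = {e.index: e for e in graph.edges}
        dual = dualize(merged)
        best: PairSplit | None = None
        for cand in enumerate_separations(dual):
            in_faces = cand.in_faces(dual.face_bits)
            in_ev = np.isin(ev_face, list(in_faces))
            n_in = int(in_ev.sum())
            if n_in == 0 or n_in == n:
                continue
            P = n_in / n
            chains = [edge_by_index[k].points
                      for k in range(cfg.max_edges)
                      if cand.boundary_edges >> k & 1]
            s = score_boundary(chains, density, n, W)
            sel = apply_balance(s, P) if cfg.mode == "best_balance" else s
            if best is None or sel < best.selection_score:
                best = PairSplit(dims=dims, W=W, widened=W > cfg.w_init,
                                 boundary_edges=cand.boundary_edges,
                                 chains=chains, in_faces=in_faces,
                                 in_events=in_ev, P=P, score=s,
                                 selection_score=sel)
        return best
    return None


# ---------------------------------------------------------------------------
# gating tree

@dataclass
class GateNode:
    """One population in the gating tree.

    Internal nodes carry the split (dimension pair, boundary polyline in
    transformed [0, 1] coordinates, score, balance fraction P) and two
    children; leaves carry an id and a heuristic marker label.
    """

    indices: np.ndarray
    n: int
    dims: tuple[int, int] | None = None
    dim_names: tuple[str, str] | None = None
    polygon: np.ndarray | None = None
    score: float | None = None
    P: float | None = None
    W: float | None = None
    in_child: "GateNode | None" = None
    out_child: "GateNode | None" = None
    leaf_id: int | None = None
    label: str = ""

    @property
    def is_leaf(self) -> bool:
        return self.in_child is None


@dataclass
class GatingTree:
    """Binary tree of gates; the leaves partition the root's events."""

    root: GateNode
    marker_names: list[str]
    phenotyping_dims: np.ndarray

    def leaves(self) -> list[GateNode]:
        out: list[GateNode] = []

        def walk(node: GateNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.in_child)
                walk(node.out_child)

        walk(self.root)
        return out

    def leaf_of_events(self) -> np.ndarray:
        """Leaf id per root event (in root event order)."""
        out = np.empty(self.root.n, dtype=np.int64)
        for leaf in self.leaves():
            out[leaf.indices] = leaf.leaf_id
        return out


def stitch_chains(chains: list[np.ndarray]) -> np.ndarray:
    """Join boundary chains end to end into one polyline (grid coords)."""
    rem = [np.asarray(c) for c in chains if len(c)]
    if not rem:
        return np.zeros((0, 2), dtype=np.int64)
    rem.sort(key=lambda c: (c[0, 0], c[0, 1]))
    poly = list(map(tuple, rem.pop(0)))
    while rem:
        tail = np.array(poly[-1])
        head = np.array(poly[0])
        best_k, best_dist, best_mode = 0, np.inf, "append"
        for k, c in enumerate(rem):
            for mode, dist in (("append", np.abs(c[0] - tail).max()),
                               ("append_rev", np.abs(c[-1] - tail).max()),
                               ("prepend", np.abs(c[-1] - head).max()),
                               ("prepend_rev", np.abs(c[0] - head).max())):
                if dist < best_dist:
                    best_k, best_dist, best_mode = k, dist, mode
        c = rem.pop(best_k)
        if best_mode == "append":
            poly.extend(map(tuple, c))
        elif best_mode == "append_rev":
            poly.extend(map(tuple, c[::-1]))
        elif best_mode == "prepend":
            poly[:0] = list(map(tuple, c))
        else:
            poly[:0] = list(map(tuple, c[::-1]))
    return np.array(poly, dtype=np.int64)


def _qualify_population(values: np.ndarray, dims: np.ndarray,
                        cfg: EPPConfig) -> list:
    thresholds = {"normal": cfg.kld_threshold_normal,
                  "exponential": cfg.kld_threshold_exponential}
    return [qualify_dimension(values[:, d], dimension=int(d),
                              thresholds=thresholds, mode=cfg.data_mode)
            for d in dims]


def epp_recurse(events: EventMatrix, cfg: EPPConfig | None = None) -> GatingTree:
    """Run exhaustive projection pursuit on a transformed, censored event
    matrix and return the gating tree."""
    cfg = cfg or EPPConfig()
    dims = events.phenotyping_dims
    if dims.size < 2:
        raise ValidationError("need at least two phenotyping dimensions")
    root_n = events.n
    G = cfg.grid_size

    def build(indices: np.ndarray, depth: int) -> GateNode:
        node = GateNode(indices=indices, n=len(indices))
        if _too_small(node.n):
            return node
        values = events.values[indices]
        results = _qualify_population(values, dims, cfg)
        pairs = enumerate_pairs(results)
        log.info("population n=%d depth=%d: qualified dims %s, %d pair(s)",
                 node.n, depth,
                 [r.dimension for r in results if r.qualified], len(pairs))
        sub_matrix = EventMatrix(values, list(events.marker_names),
                                 events.phenotyping_mask, events.source_ids[indices])
        best: PairSplit | None = None
        for pair in pairs:
            res = analyze_pair(sub_matrix, pair, cfg)
            if res is not None and (best is None
                                    or res.selection_score < best.selection_score):
                best = res
        if best is None:
            return node
        if cfg.min_stop_strict and (_too_small(int(best.in_events.sum()))
                                    or _too_small(int((~best.in_events).sum()))):
            return node
        i, j = best.dims
        poly = stitch_chains(best.chains).astype(np.float64)
        node.dims = best.dims
        node.dim_names = (events.marker_names[i], events.marker_names[j])
        # chains are (row=y, col=x); polygon is (x, y) on [0, 1]
        node.polygon = np.column_stack([poly[:, 1], poly[:, 0]]) / (G - 1)
        node.score = best.score
        node.P = best.P
        node.W = best.W
        log.info("split n=%d on (%s, %s): score=%.2f P=%.3f W=%g",
                 node.n, node.dim_names[0], node.dim_names[1],
                 best.score, best.P, best.W)
        node.in_child = build(indices[best.in_events], depth + 1)
        node.out_child = build(indices[~best.in_events], depth + 1)
        return node

    def _too_small(n: int) -> bool:
        return n < cfg.min_events_abs or n < cfg.min_events_rel * root_n

    root = build(np.arange(root_n), 0)
    tree = GatingTree(root=root, marker_names=list(events.marker_names),
                      phenotyping_dims=dims)
    _assign_leaf_ids(tree)
    _label_leaves(tree, events)
    return tree


def _assign_leaf_ids(tree: GatingTree) -> None:
    for k, leaf in enumerate(tree.leaves(), start=1):
        leaf.leaf_id = k


def _label_leaves(tree: GatingTree, events: EventMatrix) -> None:
    """Heuristic marker labels: at every ancestor split annotate the 1-2
    phenotyping markers whose means differ most between the siblings, with
    +/- for the side this leaf descends through."""
    dims = tree.phenotyping_dims

    def walk(node: GateNode, trail: list[tuple[str, str]]) -> None:
        if node.is_leaf:
            seen: dict[str, str] = {}
            for name, sign in trail:
                seen[name] = sign  # later (deeper) splits win
            node.label = "".join(f"{k}{v}" for k, v in seen.items())
            return
        mean_in = events.values[node.in_child.indices][:, dims].mean(axis=0)
        mean_out = events.values[node.out_child.indices][:, dims].mean(axis=0)
        diff = mean_in - mean_out
        order = np.argsort(-np.abs(diff))
        chosen = [order[0]]
        if len(order) > 1 and abs(diff[order[1]]) > 0.5 * abs(diff[order[0]]):
            chosen.append(order[1])
        ann_in = [(tree.marker_names[dims[k]], "+" if diff[k] > 0 else "-")
                  for k in chosen]
        ann_out = [(name, "-" if s == "+" else "+") for name, s in ann_in]
        walk(node.in_child, trail + ann_in)
        walk(node.out_child, trail + ann_out)

    walk(tree.root, [])
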