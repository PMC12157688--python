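"""Density-based merging: remove cluster-graph edges without a significant dip.

For each edge the saddle (highest density along the chain) is compared to
the densities at the two modes it separates.  The dip is significant when
both modes exceed the saddle by more than z standard errors, the standard
error coming from the squared-kernel variance pass: Var[f-hat(x)] ~=
V(x)/n^2.  Edges are tested in descending order of saddle density; an
insignificant edge is removed, its two faces merge (the merged mode is the
denser of the two), edges now joining the same face pair are spliced, and
the scan restarts until a fixed point is reached.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .modal_clustering import ClusterGraph, ClusterLabeling

log = logging.getLogger("epp")

__all__ = ["MergedEdge", "MergedGraph", "dbm_merge"]


@dataclass
class MergedEdge:
    """A (possibly spliced) boundary between two merged faces."""

    edge_ids: frozenset[int]        # constituent cluster-graph edge indices
    faces: tuple[int, int]          # merged-face representatives
    saddle_density: float
    saddle_point: tuple[int, int]
    chains: list[np.ndarray]


@dataclass
class MergedGraph:
    """Cluster graph after density-based merging."""

    faces: list[int]                    # surviving face representatives
    edges: list[MergedEdge]
    face_map: dict[int, int]            # original cluster id -> representative
    modes: dict                         # representative -> ((row, col), density)

    @property
    def n_faces(self) -> int:
        return len(self.faces)


def dbm_merge(graph: ClusterGraph, labeling: ClusterLabeling,
              density: np.ndarray, variance_density: np.ndarray,
              n: int, z: float = 3.0,
              require_both: bool = True) -> MergedGraph:
    """Merge statistically unsupported separations; returns the fixed point.

    ``require_both`` demands that both modes clear the dip by z standard
    errors (the conservative reading); set False to accept either.
    A single-face result (no edges) is a valid outcome meaning "no
    separation in this pair".
    """
    if z <= 0:
        raise ValueError("z must be positive")
    parent = {f: f for f in graph.faces}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    modes = {f: labeling.modes[f] for f in graph.faces}
    edges = [MergedEdge(frozenset([e.index]), e.faces, e.saddle_density,
                        e.saddle_point, [e.points]) for e in graph.edges]

    def var_at(pt: tuple[int, int]) -> float:
        return float(variance_density[pt[0], pt[1]]) / (n * n)

    def regroup(items: list[MergedEdge]) -> list[MergedEdge]:
        grouped: dict[tuple[int, int], MergedEdge] = {}
        for e in items:
            a, b = find(e.faces[0]), find(e.faces[1])
            if a == b:
                continue  # became internal to a merged face
            key = (min(a, b), max(a, b))
            if key in grouped:
                g = grouped[key]
                ids = g.edge_ids | e.edge_ids
                if e.saddle_density > g.saddle_density:
                    saddle, spt = e.saddle_density, e.saddle_point
                else:
                    saddle, spt = g.saddle_density, g.saddle_point
                grouped[key] = MergedEdge(ids, key, saddle, spt,
                                          g.chains + e.chains)
            else:
                grouped[key] = MergedEdge(e.edge_ids, key, e.saddle_density,
                                          e.saddle_point, e.chains)
        return sorted(grouped.values(),
                      key=lambda e: min(e.edge_ids))

    while True:
        edges = regroup(edges)
        removed = False
        for e in sorted(edges, key=lambda e: (-e.saddle_density,
                                              min(e.edge_ids))):
            a, b = e.faces
            f_saddle = float(density[e.saddle_point[0], e.saddle_point[1]])
            v_saddle = var_at(e.saddle_point)
            sig = []
            for f in (a, b):
                (pt, f_mode) = modes[f]
                se = math.sqrt(max(var_at(pt) + v_saddle, 0.0))
                t = (f_mode - f_saddle) / se if se > 0 else math.inf
                sig.append(t > z)
            ok = (sig[0] and sig[1]) if require_both else (sig[0] or sig[1])
            if not ok:
                # merge: the denser mode represents the union
                keep = a if modes[a][1] >= modes[b][1] else b
                drop = b if keep == a else a
                parent[drop] = keep
                modes[keep] = max(modes[a], modes[b], key=lambda m: m[1])
                removed = True
                break
        if not removed:
            break

    faces = sorted({find(f) for f in graph.faces})
    face_map = {f: find(f) for f in graph.faces}
    return MergedGraph(faces=faces, edges=regroup(edges), face_map=face_map,
                       modes={f: modes[f] for f in faces})
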