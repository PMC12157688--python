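"""Enumeration of all two-part separation boundaries via the bit-vector dual.

The dual of the cluster graph has a node per face and an edge per boundary.
Removing a dual edge merges its two nodes (the corresponding faces fuse)
and any dual edges now joining the same pair of nodes fuse by bitwise OR
(the corresponding boundaries splice).  Compounding this elementary step
until a single dual edge remains yields exactly the boundaries that are
continuous curves separating two contiguous regions.  Nodes and edges are
bit vectors, so every operation is integer arithmetic.

Enumeration is stack-driven and ordered: a (possibly fused) dual edge may
be removed only when its lowest constituent bit exceeds the lowest bit of
every previously removed edge.  Each candidate then arises from exactly
one removal sequence, so the search is complete and emits no duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass

from .dbm_merging import MergedGraph

__all__ = ["DualGraph", "CandidateSeparation", "dualize",
           "enumerate_separations"]

MAX_EDGE_BITS = 32


@dataclass(frozen=True)
class DualGraph:
    """Abstract dual: face bit per node, cluster-edge bit(s) per edge."""

    face_bits: dict[int, int]            # face id -> bit position
    edges: tuple[tuple[int, int, int], ...]  # (node mask u, node mask v, edge mask)


@dataclass(frozen=True)
class CandidateSeparation:
    """A continuous boundary dividing the faces into two contiguous parts."""

    boundary_edges: int     # bitset of cluster-graph edge indices
    in_mask: int            # bitset of faces on the "in" side
    out_mask: int

    def in_faces(self, face_bits: dict[int, int]) -> frozenset[int]:
        return frozenset(f for f, b in face_bits.items() if self.in_mask >> b & 1)


def dualize(graph: MergedGraph) -> DualGraph:
    """One dual node per face, one dual edge per boundary; parallel duals
    (two faces sharing several boundaries) are fused immediately."""
    face_bits = {f: i for i, f in enumerate(sorted(graph.faces))}
    fused: dict[tuple[int, int], int] = {}
    for e in graph.edges:
        emask = 0
        for i in e.edge_ids:
            if i >= MAX_EDGE_BITS:
                raise ValueError(f"edge index {i} exceeds {MAX_EDGE_BITS}-bit capacity")
            emask |= 1 << i
        u = 1 << face_bits[e.faces[0]]
        v = 1 << face_bits[e.faces[1]]
        key = (min(u, v), max(u, v))
        fused[key] = fused.get(key, 0) | emask
    edges = tuple((u, v, m) for (u, v), m in sorted(fused.items()))
    return DualGraph(face_bits=face_bits, edges=edges)


def _lowbit(x: int) -> int:
    return (x & -x).bit_length() - 1


def enumerate_separations(dual: DualGraph) -> list[CandidateSeparation]:
    """All candidate two-part separations, ordered lexicographically by
    boundary bitset then in-side bitset.  The "in" side is the side
    containing the lowest-numbered face."""
    if not dual.edges:
        return []
    out: list[CandidateSeparation] = []
    stack: list[tuple[tuple[tuple[int, int, int], ...], int]] = [(dual.edges, -1)]
    while stack:
        edges, removed_max = stack.pop()
        if len(edges) == 1:
            u, v, emask = edges[0]
            in_mask, out_mask = (u, v) if u & 1 else (v, u)
            out.append(CandidateSeparation(emask, in_mask, out_mask))
            continue
        for u, v, emask in edges:
            if _lowbit(emask) <= removed_max:
                continue
            merged = u | v
            fused: dict[tuple[int, int], int] = {}
            for uu, vv, mm in edges:
                if mm == emask:
                    continue
                if uu == u or uu == v:
                    uu = merged
                if vv == u or vv == v:
                    vv = merged
                key = (min(uu, vv), max(uu, vv))
                fused[key] = fused.get(key, 0) | mm
            nxt = tuple((a, b, m) for (a, b), m in sorted(fused.items()))
            stack.append((nxt, _lowbit(emask)))
    out.sort(key=lambda c: (c.boundary_edges, c.in_mask))
    return out
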