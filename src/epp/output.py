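"""Serialization: JSON gating tree with simplified polygons, assignment CSV.

The gating tree is written as nested JSON ("epp_tree_v1"): internal nodes
carry the dimension pair, the boundary polyline simplified by the
Ramer-Douglas-Peucker algorithm at a configurable tolerance (1% of scale
by default), the boundary score and the balance fraction P; leaves carry
an integer id, a heuristic label and an event count.  A companion CSV maps
every non-censored event to its leaf id together with the Mahalanobis
distance of the event from the leaf's center over the phenotyping
dimensions.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .io_transforms import EventMatrix
from .scoring_recursion import GateNode, GatingTree

log = logging.getLogger("epp")

__all__ = ["rdp_simplify", "mahalanobis", "tree_to_dict", "write_tree_json",
           "read_tree_json", "AssignmentRecord", "compute_assignments",
           "write_assignments_csv"]


def rdp_simplify(points: np.ndarray, tolerance: float) -> np.ndarray:
    """Ramer-Douglas-Peucker polyline simplification.

    Keeps the endpoints; every dropped point lies within ``tolerance``
    (same units as the coordinates) of the simplified polyline.
    """
    pts = np.asarray(points, dtype=np.float64)
    if len(pts) < 3 or tolerance <= 0:
        return pts.copy()
    keep = np.zeros(len(pts), dtype=bool)
    keep[0] = keep[-1] = True
    stack = [(0, len(pts) - 1)]
    while stack:
        a, b = stack.pop()
        if b - a < 2:
            continue
        seg = pts[b] - pts[a]
        norm = np.hypot(*seg)
        mid = pts[a + 1:b]
        if norm == 0.0:
            dist = np.hypot(*(mid - pts[a]).T)
        else:
            rel = mid - pts[a]
            dist = np.abs(seg[0] * rel[:, 1] - seg[1] * rel[:, 0]) / norm
        k = int(np.argmax(dist))
        if dist[k] > tolerance:
            keep[a + 1 + k] = True
            stack.append((a, a + 1 + k))
            stack.append((a + 1 + k, b))
    return pts[keep]


def mahalanobis(x: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """sqrt((x - mu)^T Sigma^-1 (x - mu)) with ridge-regularized Sigma.

    ``x`` may be a single vector or an (n, d) matrix.  The covariance is
    regularized by 1e-6 * trace/d on the diagonal; if it is still singular
    the diagonal covariance is used (with a warning).
    """
    x = np.atleast_2d(np.asarray(x, dtype=np.float64))
    mean = np.asarray(mean, dtype=np.float64)
    cov = np.asarray(cov, dtype=np.float64)
    d = cov.shape[0]
    ridge = 1e-6 * np.trace(cov) / d
    if ridge <= 0:
        ridge = 1e-12
    delta = x - mean
    try:
        inv = np.linalg.inv(cov + ridge * np.eye(d))
    except np.linalg.LinAlgError:
        log.warning("singular covariance; falling back to diagonal")
        diag = np.maximum(np.diag(cov), ridge)
        inv = np.diag(1.0 / diag)
    q = np.einsum("ij,jk,ik->i", delta, inv, delta)
    out = np.sqrt(np.maximum(q, 0.0))
    return out if len(out) > 1 else out[0] if x.shape[0] == 1 else out


# ---------------------------------------------------------------------------
# gating tree JSON

def _node_to_dict(node: GateNode, tolerance: float) -> dict:
    if node.is_leaf:
        return {"leaf_id": int(node.leaf_id), "label": node.label,
                "n": int(node.n)}
    poly = rdp_simplify(node.polygon, tolerance)
    return {
        "dims": [node.dim_names[0], node.dim_names[1]],
        "polygon": [[float(x), float(y)] for x, y in poly],
        "score": float(node.score),
        "P": float(node.P),
        "W": float(node.W),
        "n": int(node.n),
        "in": _node_to_dict(node.in_child, tolerance),
        "out": _node_to_dict(node.out_child, tolerance),
    }


def tree_to_dict(tree: GatingTree, tolerance: float = 0.01) -> dict:
    return {"version": "epp_tree_v1",
            "markers": list(tree.marker_names),
            "root": _node_to_dict(tree.root, tolerance)}


def write_tree_json(tree: GatingTree, path, tolerance: float = 0.01) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(tree_to_dict(tree, tolerance), fh, indent=1)
        fh.write("\n")


def read_tree_json(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("version") != "epp_tree_v1":
        raise ValidationError(f"{path}: not an epp_tree_v1 document")
    return doc


# ---------------------------------------------------------------------------
# per-event assignments

@dataclass(frozen=True)
class AssignmentRecord:
    event_id: int
    leaf_id: int
    mahalanobis: float


def compute_assignments(tree: GatingTree, events: EventMatrix) -> list[AssignmentRecord]:
    """Leaf id and Mahalanobis distance from the leaf center per event.

    Distances use the phenotyping dimensions; tiny leaves (fewer events
    than dimensions + 1) get distance 0 for lack of a usable covariance.
    """
    dims = tree.phenotyping_dims
    leaf_ids = tree.leaf_of_events()
    dist = np.zeros(events.n)
    for leaf in tree.leaves():
        sub = events.values[leaf.indices][:, dims]
        if len(sub) >= len(dims) + 1:
            cov = np.cov(sub, rowvar=False)
            cov = np.atleast_2d(cov)
            dist[leaf.indices] = np.atleast_1d(
                mahalanobis(sub, sub.mean(axis=0), cov))
    return [AssignmentRecord(int(events.source_ids[k]), int(leaf_ids[k]),
                             float(dist[k]))
            for k in range(events.n)]


def write_assignments_csv(records: list[AssignmentRecord], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("event_id,leaf_id,mahalanobis\n")
        for r in records:
            fh.write(f"{r.event_id},{r.leaf_id},{r.mahalanobis:.6f}\n")
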