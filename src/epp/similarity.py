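"""Comparing two labelings of the same events.

A match table counts shared events between populations of two labelings.
The Jaccard similarity of two event sets is |A n B| / |A u B|; the central
similarity first trims each set to its central fraction (80% by default)
by Mahalanobis distance from the set's own mean, then computes the Jaccard
coefficient restricted to the union of the trimmed cores, discounting
disagreement confined to the outer tails of the distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_transforms import EventMatrix
from .output import mahalanobis

__all__ = ["MatchTable", "match_table", "jaccard", "central_similarity"]


@dataclass
class MatchTable:
    """Shared-event counts between populations of labelings A (rows) and
    B (columns), with marginal totals and dominant-match highlighting."""

    counts: pd.DataFrame

    @property
    def row_totals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def dominant_matches(self) -> pd.Series:
        """For each row population, the column with the largest overlap."""
        return self.counts.idxmax(axis=1)


def match_table(labels_a, labels_b) -> MatchTable:
    """Cross-tabulate two per-event population labelings."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValidationError(
            f"labelings cover different event universes ({a.shape} vs {b.shape})")
    return MatchTable(pd.crosstab(pd.Series(a, name="A"), pd.Series(b, name="B")))


def jaccard(set_a, set_b) -> float:
    """|A n B| / |A u B|; 0 by convention when both sets are empty."""
    A, B = set(set_a), set(set_b)
    union = A | B
    if not union:
        return 0.0
    return len(A & B) / len(union)


def _central_core(ids: np.ndarray, events: EventMatrix, trim: float) -> set:
    dims = events.phenotyping_dims
    pos = {int(s): k for k, s in enumerate(events.source_ids)}
    rows = np.array([pos[int(i)] for i in ids])
    sub = events.values[rows][:, dims]
    cov = np.atleast_2d(np.cov(sub, rowvar=False))
    d = np.atleast_1d(mahalanobis(sub, sub.mean(axis=0), cov))
    keep = math.ceil(trim * len(ids))
    order = np.argsort(d, kind="stable")[:keep]
    return {int(i) for i in ids[order]}


def central_similarity(set_a, set_b, events: EventMatrix,
                       trim: float = 0.8) -> float:
    """Jaccard similarity restricted to the central cores of the two sets.

    Each set is independently trimmed to its central ``trim`` fraction by
    Mahalanobis distance from its own mean (per-set covariance over the
    phenotyping dimensions); the comparison is J(A n C, B n C) with C the
    union of the two cores.
    """
    A = np.asarray(sorted(set(set_a)), dtype=np.int64)
    B = np.asarray(sorted(set(set_b)), dtype=np.int64)
    dims = events.phenotyping_dims
    if len(A) < len(dims) + 2 or len(B) < len(dims) + 2:
        raise ValidationError("each set needs at least dims + 2 events")
    core = _central_core(A, events, trim) | _central_core(B, events, trim)
    return jaccard(set(map(int, A)) & core, set(map(int, B)) & core)
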