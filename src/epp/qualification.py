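"""Dimension qualification by Kullback-Leibler divergence from reference laws.

A dimension whose marginal looks like a single normal (fluorescence) or, in
mass mode, additionally like an exponential of its non-zero values, carries
no separable structure and is omitted.  The divergence of the sample from
the moment-matched reference is estimated from the order statistics by an
m-spacing estimator; dimensions below the thresholds (0.04 normal, 0.2
exponential by default) are unqualified.  Qualified dimensions are paired
exhaustively; when fewer than two qualify the most promising pair by
divergence from normal is still examined.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import ValidationError

log = logging.getLogger("epp")

__all__ = ["QualificationResult", "estimate_kld", "qualify_dimension",
           "enumerate_pairs"]

MIN_EVENTS_FOR_KLD = 20


@dataclass(frozen=True)
class QualificationResult:
    dimension: int
    kld_normal: float
    kld_exponential: float | None
    qualified: bool


def estimate_kld(values: np.ndarray, reference_cdf, m: int | None = None) -> float:
    """m-spacing estimate of KL(sample || reference) from order statistics.

    D-hat = (1/n) sum_i log( ((i_hi - i_lo)/n) / (F(x[i_hi]) - F(x[i_lo])) )
    with i_hi = min(i+m, n-1), i_lo = max(i-m, 0) and m = ceil(sqrt(n)).
    ``values`` must be sorted ascending.  Consistent: tends to 0 when the
    sample is drawn from the reference family.
    """
    x = np.asarray(values, dtype=np.float64)
    n = x.size
    if n < MIN_EVENTS_FOR_KLD:
        raise ValidationError(f"need at least {MIN_EVENTS_FOR_KLD} values, got {n}")
    if m is None:
        m = math.ceil(math.sqrt(n))
    i = np.arange(n)
    hi = np.minimum(i + m, n - 1)
    lo = np.maximum(i - m, 0)
    num = (hi - lo) / n
    F = np.asarray(reference_cdf(x), dtype=np.float64)
    den = np.maximum(F[hi] - F[lo], np.finfo(np.float64).tiny)
    return float(np.mean(np.log(num / den)))


def qualify_dimension(values: np.ndarray, dimension: int = 0,
                      thresholds: dict | None = None,
                      mode: str = "fluorescence") -> QualificationResult:
    """Test one marginal against its moment-matched reference distributions.

    Fluorescence mode tests divergence from N(mean, var); mass mode also
    requires divergence from the exponential fitted to the non-zero values
    (rate = 1 / mean of non-zero values).  Degenerate inputs (too few
    events, zero variance) are unqualified without raising.
    """
    th = {"normal": 0.04, "exponential": 0.2}
    if thresholds:
        th.update(thresholds)
    if mode not in ("fluorescence", "mass"):
        raise ValidationError(f"unknown mode {mode!r}")
    x = np.sort(np.asarray(values, dtype=np.float64))
    n = x.size
    if n < MIN_EVENTS_FOR_KLD:
        log.warning("dimension %d: only %d events, too few to judge; unqualified",
                    dimension, n)
        return QualificationResult(dimension, 0.0, None, False)
    mu = float(np.mean(x))
    sd = float(np.std(x))
    if sd <= 1e-12 * max(1.0, abs(mu)):  # constant dimension
        return QualificationResult(dimension, 0.0, None, False)
    kld_n = estimate_kld(x, stats.norm(loc=mu, scale=sd).cdf)
    kld_e: float | None = None
    if mode == "mass":
        nz = x[x > 0.0]
        if nz.size >= MIN_EVENTS_FOR_KLD and float(np.mean(nz)) > 0.0:
            kld_e = estimate_kld(nz, stats.expon(scale=float(np.mean(nz))).cdf)
        else:
            kld_e = 0.0  # all-zero / near-empty dimension: exponential-like
    qualified = kld_n >= th["normal"]
    if kld_e is not None:
        qualified = qualified and kld_e >= th["exponential"]
    return QualificationResult(dimension, kld_n, kld_e, qualified)


def enumerate_pairs(results: list[QualificationResult]) -> list[tuple[int, int]]:
    """Dimension pairs to examine, ordered ascending by index.

    All C(q, 2) pairs of the q qualified dimensions; if q == 1 the qualified
    dimension is paired with the unqualified one of highest divergence from
    normal; if q == 0 the two highest-divergence dimensions are paired, so
    at least one pair is always tried.  Ties break toward the lower index.
    """
    if len(results) < 2:
        raise ValidationError("need at least two phenotyping dimensions")
    by_dim = sorted(results, key=lambda r: r.dimension)
    qual = [r.dimension for r in by_dim if r.qualified]
    if len(qual) >= 2:
        return [(a, b) for k, a in enumerate(qual) for b in qual[k + 1:]]
    # rank the unqualified by descending kld_normal, lowest index first on ties
    unqual = sorted((r for r in by_dim if not r.qualified),
                    key=lambda r: (-r.kld_normal, r.dimension))
    if len(qual) == 1:
        pair = (qual[0], unqual[0].dimension)
    else:
        pair = (unqual[0].dimension, unqual[1].dimension)
    return [tuple(sorted(pair))]
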