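"""Hypergeometric enrichment and population z-scores.

A motif's "success" is a protein containing at least one match.  With n
positives, p negatives and b background proteins, the motif present in
k_pos positives, q_neg negatives and m_bak background proteins gets two
upper-tail cumulative hypergeometric p-values::

    p_NEG = H(k_pos | n + p,     k_pos + q_neg,         n)
    p_BAK = H(k_pos | n + p + b, k_pos + q_neg + m_bak, n)   (proteome mode)
    p_BAK = H(k_pos | n + b,     k_pos + m_bak,         n)   (background-only mode)

where H(k | N, m, n) = sum_{i=k}^{min(m,n)} C(m,i) C(N-m, n-i) / C(N,n).
All p-values are computed and stored in log10 space: printed significances
reach 1e-21 and beyond, well into underflow territory for naive summation.

Each p-value is then standardized over the population of all motifs
surviving pruning in a run (pooled across masks and lengths): z = (x - mean)
/ sd of x = -log10 p, population standard deviation.  A motif's assigned
score is the weaker (smaller) of its two z-scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

_LN10 = math.log(10.0)


def _logsumexp_list(vals) -> float:
    """Stable log(sum(exp(vals))) for a short python list."""
    vmax = max(vals)
    if math.isinf(vmax):
        return vmax
    return vmax + math.log(sum(math.exp(v - vmax) for v in vals))


class ScoringError(ValueError):
    pass


@lru_cache(maxsize=1 << 20)
def log10_hypergeom_tail(k: int, N: int, m: int, n: int) -> float:
    """log10 of the upper-tail cumulative hypergeometric H(k | N, m, n).

    Stable for any representable parameters: terms are summed in log space
    via log-gamma, and when the tail holds most of the mass the complement
    (lower tail) is summed instead so log(p) near 0 keeps full precision.
    Degenerate cases: k <= max(0, n+m-N) gives 0.0 (p = 1); k > min(m, n)
    gives -inf (p = 0).
    """
    if not (0 <= m <= N and 0 <= n <= N and k >= 0):
        raise ScoringError(f"invalid hypergeometric parameters k={k} N={N} m={m} n={n}")
    lo = max(0, n + m - N)
    hi = min(m, n)
    if k <= lo:
        return 0.0
    if k > hi:
        return -math.inf
    lg = math.lgamma
    base = lg(m + 1) + lg(N - m + 1) - (lg(N + 1) - lg(n + 1) - lg(N - n + 1))
    if hi - lo <= 512:
        logpmf = [
            base - lg(i + 1) - lg(m - i + 1) - lg(n - i + 1) - lg(N - m - n + i + 1)
            for i in range(lo, hi + 1)
        ]
        upper = _logsumexp_list(logpmf[k - lo :])
        if upper > -math.log(2.0):
            lower = _logsumexp_list(logpmf[: k - lo])
            return math.log1p(-math.exp(lower)) / _LN10
        return upper / _LN10
    i = np.arange(lo, hi + 1)
    logpmf = (
        base
        - gammaln(i + 1) - gammaln(m - i + 1)
        - gammaln(n - i + 1) - gammaln(N - m - n + i + 1)
    )
    upper = logsumexp(logpmf[k - lo :])
    if upper > math.log(0.5):
        lower = logsumexp(logpmf[: k - lo])
        return math.log1p(-math.exp(lower)) / _LN10
    return float(upper) / _LN10


def score_motif(counts, partition, background_mode: str = "proteome"):
    """(log10 p_NEG, log10 p_BAK) for one motif's presence counts.

    Either value is None when the corresponding reference set is empty
    (scoring then proceeds on the available reference alone).
    """
    n, p, b = partition.n, partition.p, partition.b
    if n == 0:
        raise ScoringError("empty positives set")
    k, q, mb = counts.k_pos, counts.q_neg, counts.m_bak
    log10_p_neg = log10_hypergeom_tail(k, n + p, k + q, n) if p > 0 else None
    if b > 0:
        if background_mode == "proteome":
            log10_p_bak = log10_hypergeom_tail(k, n + p + b, k + q + mb, n)
        elif background_mode == "background_only":
            log10_p_bak = log10_hypergeom_tail(k, n + b, k + mb, n)
        else:
            raise ScoringError(f"unknown background mode {background_mode!r}")
    else:
        log10_p_bak = None
    if log10_p_neg is None and log10_p_bak is None:
        raise ScoringError("both reference sets empty; nothing to score against")
    return log10_p_neg, log10_p_bak


def zscore_population(log10_ps) -> np.ndarray:
    """Standardize x = -log10 p over its population (population sd).

    A degenerate population (sd = 0, e.g. a single motif) maps to all-zero
    z-scores rather than NaN.
    """
    x = -np.asarray(log10_ps, dtype=float)
    if x.size == 0:
        raise ScoringError("empty p-value population")
    sd = float(np.std(x))
    if sd == 0.0 or not np.isfinite(sd):
        return np.zeros_like(x)
    return (x - float(np.mean(x))) / sd


@dataclass
class ScoredMotif:
    """A motif with its counts, log10 p-values, z-scores and assigned score."""

    motif: object
    counts: object
    log10_p_neg: float | None
    log10_p_bak: float | None
    z_neg: float | None = None
    z_bak: float | None = None
    z: float | None = None
    family: str | None = None  # seed lineage (degeneration bookkeeping)

    def sort_key(self):
        # rank: z descending, then stronger p_NEG, then motif text
        pn = self.log10_p_neg if self.log10_p_neg is not None else self.log10_p_bak
        return (-self.z, pn, str(self.motif))


def assign_scores(scored, clip_log10=-320.0) -> list:
    """Compute population z-scores and rank motifs by assigned z, descending.

    ``scored`` is a list of ScoredMotifs with p-values filled; z_neg and
    z_bak are standardized over the whole population (pooled across masks
    and lengths) and z = min of the two (or the only one available).
    Exact-zero p-values are clipped to ``clip_log10`` before standardizing
    so an infinitely significant motif still ranks first with finite z.
    Returns a new, stably sorted list.
    """
    if not scored:
        raise ScoringError("empty motif population")

    def clipped(v):
        return max(v, clip_log10) if v is not None else None

    pn = [clipped(sm.log10_p_neg) for sm in scored]
    pb = [clipped(sm.log10_p_bak) for sm in scored]
    have_neg = all(v is not None for v in pn)
    have_bak = all(v is not None for v in pb)
    if not (have_neg or have_bak):
        raise ScoringError("population mixes motifs with neither reference scored")
    zn = zscore_population(pn) if have_neg else [None] * len(scored)
    zb = zscore_population(pb) if have_bak else [None] * len(scored)
    for sm, a, b in zip(scored, zn, zb):
        sm.z_neg = float(a) if a is not None else None
        sm.z_bak = float(b) if b is not None else None
        zs = [v for v in (sm.z_neg, sm.z_bak) if v is not None]
        sm.z = min(zs)
    return sorted(scored, key=ScoredMotif.sort_key)
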