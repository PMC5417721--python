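"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own code paths: exact
big-integer rationals for the hypergeometric tail, and per-motif regular
expression scanning for presence counts.
"""

from __future__ import annotations

import math
import re
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from linmotif.io import SequenceRecord
from linmotif.motif import AMINO_ACIDS


# ---------------------------------------------------------------------------
# exact hypergeometric oracle
# ---------------------------------------------------------------------------

def _log10_int(x: int) -> float:
    """log10 of a positive big integer to ~1e-15 relative accuracy."""
    if x.bit_length() <= 900:
        return math.log10(x)
    shift = x.bit_length() - 900
    return math.log10(x >> shift) + shift * math.log10(2.0)


def exact_log10_tail(k: int, N: int, m: int, n: int) -> float:
    """Exact log10 upper-tail hypergeometric via big-integer rationals."""
    lo = max(0, n + m - N)
    hi = min(m, n)
    if k <= lo:
        return 0.0
    if k > hi:
        return -math.inf
    den = comb(N, n)
    num = sum(comb(m, i) * comb(N - m, n - i) for i in range(k, hi + 1))
    if 2 * num > den:
        # complement route keeps log(p) accurate when p is close to 1
        q = Fraction(den - num, den)
        return math.log1p(-float(q)) / math.log(10.0)
    return _log10_int(num) - _log10_int(den)


# ---------------------------------------------------------------------------
# regex presence-count oracle
# ---------------------------------------------------------------------------

def regex_presence(motif_text_or_motif, records) -> int:
    """Distinct records containing >=1 match of the motif (regex oracle)."""
    from linmotif.motif import Motif, parse_motif

    m = (
        motif_text_or_motif
        if isinstance(motif_text_or_motif, Motif)
        else parse_motif(motif_text_or_motif)
    )
    pat = re.compile("(?=" + m.to_regex() + ")")
    return sum(1 for r in records if pat.search(r.residues))


# ---------------------------------------------------------------------------
# random sequence sets
# ---------------------------------------------------------------------------

def random_records(rng, n, length, prefix="S", sentinel_rate=0.0):
    recs = []
    letters = list(AMINO_ACIDS)
    for i in range(n):
        chars = rng.choice(letters, size=length)
        if sentinel_rate:
            hit = rng.random(length) < sentinel_rate
            chars = np.where(hit, "X", chars)
        recs.append(SequenceRecord(f"{prefix}{i}", "".join(chars)))
    return recs


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
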