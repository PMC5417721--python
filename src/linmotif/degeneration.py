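"""Degeneration search: grow bracketed amino-acid sets at wildcard positions.

Starting from a motif containing wildcards, each wildcard is substituted by
each of the 20 single amino acids; substitutions that improve the motif's
enrichment p-value(s) are retained, then each retained bracket is extended
one amino acid at a time, keeping improving extensions, until no further
improvement.  Whenever a substitution at one position improves, the other
wildcard positions are explored from that state too, so correlated
preferences at distinct positions are captured.  The search is greedy with
recursion over an exponentially large lattice; it returns all locally
maximal improved variants, not a certified global optimum.

Variants are re-counted from the cached match windows of the seed (a
bracket variant can only match where its wildcard parent matched), which is
equivalent to — and much cheaper than — a full rescan.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .index import PresenceCount
from .motif import (
    AA_INDEX,
    AMINO_ACIDS,
    Motif,
    SENTINEL as SENTINEL_CODE,
    WILDCARD,
    Wildcard,
    encode_residues,
)
from .scoring import ScoredMotif, score_motif


@dataclass
class DegenerationConfig:
    max_bracket: int = 19          # 20 letters = a wildcard again, never a variant
    variant_budget: int = 50_000   # max distinct variants scored per seed
    improve_rule: str = "composite"  # or "either"
    improve_margin: float = 0.0    # log10 units each accepted step must gain;
                                   # ~log10(20) cancels the 20-way letter choice
    alphabet: str = AMINO_ACIDS
    background_mode: str = "proteome"


@dataclass
class DegenerationResult:
    variants: list
    truncated: bool = False
    scored_count: int = 0


def count_variant(m: Motif, partition) -> PresenceCount:
    """Presence counts of a motif by direct scanning of all three sets."""
    pat = m.compiled()

    def present(records):
        return sum(1 for r in records if pat.search(r.residues))

    return PresenceCount(
        k_pos=present(partition.positives),
        q_neg=present(partition.negatives),
        m_bak=present(partition.background),
    )


class PartitionMatcher:
    """Vectorized motif matcher over a partition's concatenated sequences.

    Each set's residues are concatenated with sentinel spacers (a sentinel
    fails every motif position, so windows crossing record boundaries can
    never match).  Matching a motif is one boolean table lookup per motif
    position over the whole concatenation — much faster than a per-record
    regex scan when many variants are matched against the same partition.
    """

    _SPACER = 14  # >= longest supported motif minus one

    def __init__(self, partition):
        self.sets = []
        self._valid = {}  # (set index, l) -> sentinel-free-window mask
        spacer = np.full(self._SPACER, SENTINEL_CODE, dtype=np.uint8)
        for records in (partition.positives, partition.negatives, partition.background):
            codes_parts, pid_parts = [], []
            for i, rec in enumerate(records):
                codes_parts.append(encode_residues(rec.residues))
                pid_parts.append(np.full(len(codes_parts[-1]), i, dtype=np.int64))
                codes_parts.append(spacer)
                pid_parts.append(np.full(self._SPACER, -1, dtype=np.int64))
            if codes_parts:
                self.sets.append(
                    (np.concatenate(codes_parts), np.concatenate(pid_parts))
                )
            else:
                self.sets.append(
                    (np.zeros(0, dtype=np.uint8), np.zeros(0, dtype=np.int64))
                )

    @staticmethod
    def _tables(motif: Motif) -> np.ndarray:
        tabs = np.zeros((len(motif), 21), dtype=bool)
        for j, p in enumerate(motif.positions):
            if isinstance(p, Wildcard):
                tabs[j, :20] = True
            elif isinstance(p, frozenset):
                for aa in p:
                    tabs[j, AA_INDEX[aa]] = True
            else:
                tabs[j, AA_INDEX[p]] = True
        return tabs

    def _valid_windows(self, set_idx: int, l: int, codes) -> np.ndarray:
        """Windows free of sentinels (cached): wildcards match all of these."""
        key = (set_idx, l)
        if key not in self._valid:
            n = len(codes) - l + 1
            canon = codes[: len(codes)] != SENTINEL_CODE
            ok = canon[:n].copy()
            for j in range(1, l):
                ok &= canon[j : j + n]
            self._valid[key] = ok
        return self._valid[key]

    def match_rows(self, motif: Motif, columns):
        """Per set: (protein ids, residue codes at ``columns``) of all matches."""
        tabs = self._tables(motif)
        l = len(motif)
        constrained = [
            j for j, p in enumerate(motif.positions) if not isinstance(p, Wildcard)
        ]
        out = []
        for set_idx, (codes, pids) in enumerate(self.sets):
            n = len(codes) - l + 1
            if n <= 0:
                out.append(
                    (np.zeros(0, dtype=np.int64),
                     np.zeros((0, len(columns)), dtype=np.int64))
                )
                continue
            ok = self._valid_windows(set_idx, l, codes).copy()
            for j in constrained:
                ok &= tabs[j][codes[j : j + n]]
            idx = np.flatnonzero(ok)
            rows = (
                np.stack([codes[idx + w] for w in columns], axis=1).astype(np.int64)
                if columns
                else np.zeros((len(idx), 0), dtype=np.int64)
            )
            out.append((pids[idx], rows))
        return out


class _MatchCache:
    """Seed match windows per set: protein index + residues at wildcard columns."""

    def __init__(self, seed: Motif, partition, matcher: PartitionMatcher | None = None):
        self.wild = seed.wildcard_positions()
        if matcher is not None:
            self.sets = matcher.match_rows(seed, list(self.wild))
            return
        pat = re.compile("(?=" + seed.to_regex() + ")")
        self.sets = []
        for records in (partition.positives, partition.negatives, partition.background):
            pids, rows = [], []
            for pid, rec in enumerate(records):
                codes = encode_residues(rec.residues)
                for mobj in pat.finditer(rec.residues):
                    off = mobj.start()
                    pids.append(pid)
                    rows.append([codes[off + w] for w in self.wild])
            self.sets.append(
                (
                    np.asarray(pids, dtype=np.int64),
                    np.asarray(rows, dtype=np.int64).reshape(len(pids), len(self.wild)),
                )
            )

    def count(self, assignment: dict) -> PresenceCount:
        """Counts of the seed with some wildcard positions bracket-constrained."""
        tables = []
        for j, w in enumerate(self.wild):
            if w in assignment:
                tab = np.zeros(21, dtype=bool)
                for aa in assignment[w]:
                    tab[AA_INDEX[aa]] = True
                tables.append((j, tab))
        out = []
        for pids, rows in self.sets:
            ok = None
            for j, tab in tables:
                v = tab[rows[:, j]]
                ok = v if ok is None else ok & v
            p = pids if ok is None else pids[ok]
            # match pids are nondecreasing (matches found in scan order), so
            # distinct proteins = boundary count, no sort needed
            out.append(0 if len(p) == 0 else int((p[1:] != p[:-1]).sum()) + 1)
        return PresenceCount(k_pos=out[0], q_neg=out[1], m_bak=out[2])


def _apply_assignment(seed: Motif, assignment: dict) -> Motif:
    positions = list(seed.positions)
    for pos, letters in assignment.items():
        positions[pos] = frozenset(letters)
    return Motif(tuple(positions))


def _improves(parent, cand, rule: str, margin: float = 0.0) -> bool:
    """Strict improvement of candidate p-values over the parent's.

    ``composite``: the worse (larger) log10 p must strictly decrease, or
    stay equal while the other strictly decreases — consistent with the
    final min-z ranking.  ``either``: at least one strictly decreases.
    A positive ``margin`` (log10 units) demands that much gain per accepted
    step, offsetting the selection advantage of picking the best of the 20
    candidate letters at every step.
    """
    pp = [v for v in parent if v is not None]
    cc = [v for v in cand if v is not None]
    if rule == "either":
        return any(
            c < p - margin
            for p, c in zip(parent, cand)
            if p is not None and c is not None
        )
    if rule != "composite":
        raise ValueError(f"unknown improvement rule {rule!r}")
    pw, cw = max(pp), max(cc)
    if cw < pw - margin:
        return True
    if margin == 0.0 and cw == pw:
        return min(cc) < min(pp)
    return False


def degenerate(
    seed: ScoredMotif,
    partition,
    config: DegenerationConfig | None = None,
    matcher: PartitionMatcher | None = None,
) -> DegenerationResult:
    """All locally maximal bracket variants of a seed that improve its p-values.

    Returns the seed alone when it has no wildcards or nothing improves.
    Budget exhaustion is reported via ``truncated`` (best-so-far returned,
    never silently).
    """
    config = config or DegenerationConfig()
    wild = seed.motif.wildcard_positions()
    if not wild:
        return DegenerationResult(variants=[seed])

    cache = _MatchCache(seed.motif, partition, matcher)
    if seed.counts is None:
        seed.counts = cache.count({})
        seed.log10_p_neg, seed.log10_p_bak = score_motif(
            seed.counts, partition, config.background_mode
        )
    alphabet = sorted(config.alphabet)
    visited = {str(seed.motif)}
    scored_count = 0
    truncated = False
    results: dict = {}

    def pvals(counts):
        return score_motif(counts, partition, config.background_mode)

    seed_p = (seed.log10_p_neg, seed.log10_p_bak)

    # state: (assignment dict, its p-values); explicit stack to avoid deep recursion
    def explore(assignment, state_p):
        nonlocal scored_count, truncated
        accepted_any = False
        for pos in wild:
            current = assignment.get(pos, frozenset())
            if len(current) >= config.max_bracket:
                continue
            for aa in alphabet:
                if aa in current:
                    continue
                if scored_count >= config.variant_budget:
                    truncated = True
                    return accepted_any
                new_assignment = dict(assignment)
                new_assignment[pos] = current | {aa}
                motif = _apply_assignment(seed.motif, new_assignment)
                name = str(motif)
                if name in visited:
                    continue
                visited.add(name)
                counts = cache.count(new_assignment)
                cand_p = pvals(counts)
                scored_count += 1
                if _improves(state_p, cand_p, config.improve_rule,
                             config.improve_margin):
                    accepted_any = True
                    child_accepted = explore(new_assignment, cand_p)
                    if not child_accepted:
                        results[name] = ScoredMotif(
                            motif=motif,
                            counts=counts,
                            log10_p_neg=cand_p[0],
                            log10_p_bak=cand_p[1],
                        )
                    if truncated:
                        return accepted_any
        return accepted_any

    explore({}, seed_p)
    variants = sorted(results.values(), key=lambda sm: str(sm.motif))
    if not variants:
        variants = [seed]
    return DegenerationResult(
        variants=variants, truncated=truncated, scored_count=scored_count
    )
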