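"""Bracket-degeneration search: counting identities, planted-bracket
recovery, single-position optimality vs exhaustive subset enumeration."""

import itertools

import numpy as np
import pytest

from conftest import random_records, regex_presence
from linmotif.degeneration import (
    DegenerationConfig,
    PartitionMatcher,
    _MatchCache,
    count_variant,
    degenerate,
)
from linmotif.io import ProteomePartition, SequenceRecord
from linmotif.motif import Motif, parse_motif
from linmotif.scoring import ScoredMotif, score_motif


def _random_partition(rng, n_pos=12, n_neg=8, n_bak=15, length=60):
    return ProteomePartition(
        "T",
        random_records(rng, n_pos, length, "p"),
        random_records(rng, n_neg, length, "n"),
        random_records(rng, n_bak, length, "b"),
    )


def _planted_partition(rng, letters="ST", n_pos=30):
    """Positives carry one R{letter}SL window each; negatives and background
    carry decoy R{other}SL windows, so the wildcard seed is common everywhere
    but only the {letters} bracket separates positives from references."""
    # every non-planted letter appears as a decoy, so absorbing a chance
    # letter into the bracket always costs reference counts
    decoys = "ACDEFGHIKLMNPQVWY"

    def with_window(rec, letter):
        chars = list(rec.residues)
        off = int(rng.integers(0, len(chars) - 4))
        chars[off : off + 4] = ["R", letter, "S", "L"]
        return SequenceRecord(rec.id, "".join(chars))

    positives = [
        with_window(rec, letters[i % len(letters)])
        for i, rec in enumerate(random_records(rng, n_pos, 80, "p"))
    ]
    negatives = [
        with_window(rec, decoys[i % 17])
        for i, rec in enumerate(random_records(rng, 20, 80, "n"))
    ]
    background = [
        with_window(rec, decoys[i % 17])
        for i, rec in enumerate(random_records(rng, 40, 80, "b"))
    ]
    return ProteomePartition("T", positives, negatives, background)


class TestCountVariant:
    def test_matches_regex_oracle(self, rng):
        part = _random_partition(rng)
        for text in ("PxP", "K[LV]x", "[ST]x[AG]"):
            c = count_variant(parse_motif(text), part)
            assert c.k_pos == regex_presence(text, part.positives)
            assert c.q_neg == regex_presence(text, part.negatives)
            assert c.m_bak == regex_presence(text, part.background)

    def test_bracket_union_identity(self, rng):
        part = _random_partition(rng)
        union_pos = set()
        for single in ("PLP", "PVP"):
            pat = parse_motif(single).compiled()
            union_pos |= {r.id for r in part.positives if pat.search(r.residues)}
        assert count_variant(parse_motif("P[LV]P"), part).k_pos == len(union_pos)

    def test_cached_path_equals_full_scan(self, rng):
        part = _random_partition(rng, n_pos=15, length=80)
        seed = parse_motif("PxxL")
        cache = _MatchCache(seed, part)
        letters = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(100):
            size = int(rng.integers(1, 6))
            bracket = frozenset(rng.choice(letters, size=size, replace=False))
            variant = Motif(("P", bracket, seed.positions[2], "L"))
            by_cache = cache.count({1: bracket})
            by_scan = count_variant(variant, part)
            assert (by_cache.k_pos, by_cache.q_neg, by_cache.m_bak) == (
                by_scan.k_pos,
                by_scan.q_neg,
                by_scan.m_bak,
            )

    def test_matcher_rows_equal_regex_path(self, rng):
        part = _random_partition(rng)
        seed = parse_motif("KxxA")
        fast = _MatchCache(seed, part, PartitionMatcher(part))
        slow = _MatchCache(seed, part)
        for (pf, rf), (ps, rs) in zip(fast.sets, slow.sets):
            assert np.array_equal(pf, ps)
            assert np.array_equal(rf, rs)


def _scored_seed(text, part):
    counts = count_variant(parse_motif(text), part)
    pn, pb = score_motif(counts, part)
    return ScoredMotif(parse_motif(text), counts, pn, pb)


def _objective(sm):
    ps = [p for p in (sm.log10_p_neg, sm.log10_p_bak) if p is not None]
    return max(ps)


class TestDegenerate:
    def test_seed_without_wildcards_returned_unchanged(self, rng):
        part = _random_partition(rng)
        seed = _scored_seed("KAK", part)
        res = degenerate(seed, part)
        assert res.variants == [seed]

    def test_planted_st_bracket_recovered(self, rng):
        part = _planted_partition(rng)
        seed = _scored_seed("RxSL", part)
        res = degenerate(seed, part)
        best = min(res.variants, key=_objective)
        assert best.motif.positions[1] == frozenset("ST")

    def test_full_bracket_collapses_to_wildcard_never_returned(self, rng):
        part = _random_partition(rng)
        seed = _scored_seed("PxP", part)
        res = degenerate(seed, part, DegenerationConfig(max_bracket=19))
        assert all(str(v.motif) != "PxP" or v is seed for v in res.variants)

    def test_accepted_variants_improve_on_seed(self, rng):
        part = _planted_partition(rng)
        seed = _scored_seed("RxSL", part)
        res = degenerate(seed, part)
        if res.variants != [seed]:
            for var in res.variants:
                assert _objective(var) < _objective(seed)

    def test_budget_exhaustion_flagged_not_silent(self, rng):
        part = _planted_partition(rng)
        seed = _scored_seed("RxxL", part)
        res = degenerate(seed, part, DegenerationConfig(variant_budget=10))
        assert res.truncated
        assert res.scored_count <= 10

    def test_no_motif_scored_twice(self, rng):
        part = _planted_partition(rng)
        seed = _scored_seed("RxSL", part)
        res = degenerate(seed, part, DegenerationConfig(variant_budget=3000))
        names = [str(v.motif) for v in res.variants]
        assert len(names) == len(set(names))

    @pytest.mark.parametrize("trial", range(3))
    def test_single_position_globally_optimal_on_restricted_alphabet(
        self, rng, trial
    ):
        """With one wildcard and a 6-letter alphabet, the search returns the
        best of all 2^6-1 = 63 brackets (exhaustively enumerated oracle)."""
        alphabet = "ALRSTV"
        part = _planted_partition(rng, letters="ST")
        seed = _scored_seed("RxSL", part)
        cfg = DegenerationConfig(alphabet=alphabet)
        res = degenerate(seed, part, cfg)
        best_found = min(_objective(v) for v in res.variants)

        best_exhaustive = _objective(seed)
        for r in range(1, 7):
            for combo in itertools.combinations(alphabet, r):
                variant = Motif(("R", frozenset(combo), "S", "L"))
                counts = count_variant(variant, part)
                pn, pb = score_motif(counts, part)
                best_exhaustive = min(
                    best_exhaustive, _objective(ScoredMotif(variant, counts, pn, pb))
                )
        assert best_found == pytest.approx(best_exhaustive, abs=1e-12)

    def test_either_rule_accepts_one_sided_improvement(self, rng):
        part = _planted_partition(rng)
        seed = _scored_seed("RxSL", part)
        strict = degenerate(seed, part, DegenerationConfig(improve_rule="composite"))
        loose = degenerate(seed, part, DegenerationConfig(improve_rule="either"))
        assert len(loose.variants) >= len(strict.variants)
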