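"""Planted-motif benchmark: fixtures, generator, planting, reproducibility."""

import numpy as np
import pytest

from linmotif.benchmark import (
    DEFAULT_DISCOVERY,
    ELM_MOTIFS,
    BenchmarkError,
    ElmMotifSpec,
    benchmark_plan,
    child_seed,
    expand_combinations,
    make_background,
    plant,
    run_benchmark,
    run_one,
)
from linmotif.io import SequenceRecord
from linmotif.motif import parse_motif

# composition bookkeeping of the eight packaged consensus motifs:
# (size, defined, ambiguous, wildcard)
EXPECTED_SDAW = {
    "ELME000170": (4, 2, 2, 0),
    "ELME000141": (5, 2, 3, 0),
    "ELME000099": (6, 3, 1, 2),
    "ELME000175": (7, 4, 3, 0),
    "ELME000097": (8, 2, 2, 4),
    "ELME000013": (9, 2, 5, 2),
    "ELME000022": (10, 2, 5, 3),
    "ELME000021": (11, 3, 4, 4),
}


class TestSpecs:
    def test_eight_packaged_motifs(self):
        assert len(ELM_MOTIFS) == 8

    @pytest.mark.parametrize("spec", ELM_MOTIFS, ids=lambda s: s.accession)
    def test_composition_counts(self, spec):
        s, d, a, w = EXPECTED_SDAW[spec.accession]
        assert (spec.size, spec.n_defined, spec.n_ambiguous, spec.n_wildcard) == (
            s, d, a, w,
        )
        assert spec.size == spec.n_defined + spec.n_ambiguous + spec.n_wildcard

    def test_combination_counts_are_bracket_products(self):
        spec = next(s for s in ELM_MOTIFS if s.accession == "ELME000170")
        assert spec.n_combinations == 2 * 3  # [FY] x [DEP]


class TestExpandCombinations:
    def test_three_two_letter_brackets_give_eight(self):
        spec = ElmMotifSpec("TEST", "[AC]x[DE]x[FG]")
        combos = expand_combinations(spec)
        assert len(combos) == 8 == spec.n_combinations

    def test_two_by_three(self):
        combos = expand_combinations(ElmMotifSpec("T", "[FY][DEP]WM"))
        assert len(combos) == 6
        assert combos[0] == "FDWM"  # alphabetical, leftmost slowest

    def test_zero_ambiguous_single_combination(self):
        assert expand_combinations(ElmMotifSpec("T", "PxAP")) == ["PxAP"]


class TestBackground:
    def test_seeded_determinism(self):
        a = make_background(5, seed=42)
        b = make_background(5, seed=42)
        assert [(r.id, r.residues) for r in a] == [(r.id, r.residues) for r in b]

    def test_lengths_and_mean(self):
        recs = make_background(300, seed=7)
        lengths = np.array([len(r) for r in recs])
        assert lengths.min() >= 100 and lengths.max() <= 500
        # mean of U(100,500) is 300, sd of the mean ~ 115/sqrt(300)
        assert abs(lengths.mean() - 300) < 3 * 115 / np.sqrt(300)

    def test_fasta_mode_rejects_identical_sequence(self):
        seq = "MKTAYIAKQR" * 10
        records = [SequenceRecord("a", seq), SequenceRecord("b", seq),
                   SequenceRecord("c", "WYHQNEDCGI" * 10)]
        kept = make_background(2, source="fasta", records=records)
        assert [r.id for r in kept] == ["a", "c"]

    def test_fasta_mode_insufficient_survivors(self):
        seq = "MKTAYIAKQR" * 10
        records = [SequenceRecord("a", seq), SequenceRecord("b", seq)]
        with pytest.raises(BenchmarkError, match="1"):
            make_background(2, source="fasta", records=records)


class TestPlant:
    @pytest.fixture
    def spec(self):
        return next(s for s in ELM_MOTIFS if s.accession == "ELME000099")

    def test_exact_occurrences_at_most_one_per_sequence(self, spec):
        bg = make_background(50, seed=3)
        bench = plant(bg, spec, 10, seed=4)
        assert len(bench.planted) == 10
        assert len({i.sequence_id for i in bench.planted}) == 10
        changed = sum(
            1 for old, new in zip(bg, bench.sequences) if old.residues != new.residues
        )
        assert changed == 10

    def test_planted_windows_match_pattern(self, spec):
        bench = plant(make_background(50, seed=3), spec, 12, seed=5)
        by_id = {r.id: r for r in bench.sequences}
        for inst in bench.planted:
            assert spec.pattern.matches_at(by_id[inst.sequence_id].residues, inst.offset)

    def test_wildcard_columns_keep_underlying_residues(self, spec):
        # xP[TS]APx: positions 0 and 5 must be untouched by planting
        bg = make_background(50, seed=6)
        bench = plant(bg, spec, 10, seed=7)
        old_by_id = {r.id: r for r in bg}
        new_by_id = {r.id: r for r in bench.sequences}
        for inst in bench.planted:
            old = old_by_id[inst.sequence_id].residues
            new = new_by_id[inst.sequence_id].residues
            for col in (0, 5):
                assert new[inst.offset + col] == old[inst.offset + col]

    def test_each_changed_position_is_defined_or_ambiguous(self, spec):
        bg = make_background(50, seed=8)
        bench = plant(bg, spec, 10, seed=9)
        old_by_id = {r.id: r for r in bg}
        new_by_id = {r.id: r for r in bench.sequences}
        max_changes = spec.n_defined + spec.n_ambiguous
        for inst in bench.planted:
            old = old_by_id[inst.sequence_id].residues
            new = new_by_id[inst.sequence_id].residues
            diff = sum(1 for a, b in zip(old, new) if a != b)
            assert diff <= max_changes

    def test_occurrences_out_of_range(self, spec):
        with pytest.raises(BenchmarkError):
            plant(make_background(10, seed=1), spec, 11, seed=2)


class TestRunBenchmark:
    def test_full_plan_is_640_sets(self):
        assert benchmark_plan(ELM_MOTIFS, (5, 10, 15, 20), 20) == 640

    def test_child_seed_below_2_31_and_stable(self):
        s1 = child_seed(17, "ELME000099", 10, 3)
        s2 = child_seed(17, "ELME000099", 10, 3)
        assert s1 == s2 < 2**31

    def test_reduced_run_reproducible(self):
        spec = next(s for s in ELM_MOTIFS if s.accession == "ELME000099")
        _, r1, p1 = run_one(spec, 10, 0, master_seed=11, n_background=100)
        _, r2, p2 = run_one(spec, 10, 0, master_seed=11, n_background=100)
        assert [str(s.motif) for s in r1.ranked] == [str(s.motif) for s in r2.ranked]
        assert p1.precision == p2.precision

    def test_saturated_trivial_motif_always_discovered(self):
        # unique-letter, zero-wildcard motif planted in every sequence
        spec = ElmMotifSpec("SAT", "WCHWC")
        table = run_benchmark(
            [spec], (20,), replicates=2, master_seed=5, n_sequences=20,
            n_background=80,
        )
        assert table["accuracy"].iloc[0] == 1.0

    def test_accuracy_table_shape_and_errors_column(self):
        spec = next(s for s in ELM_MOTIFS if s.accession == "ELME000175")
        table = run_benchmark(
            [spec], (10, 20), replicates=2, master_seed=3, n_sequences=25,
            n_background=75,
        )
        assert list(table["occurrences"]) == [10, 20]
        assert (table["errors"] == 0).all()
        assert set(table.columns) >= {
            "accession", "pattern", "occurrences", "successes", "accuracy",
            "identified",
        }
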