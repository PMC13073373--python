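"""Penalty terms of the design objective and the weighted total."""

import numpy as np
import pytest

from tchur.codec import NucleotideSequence
from tchur.fitness import (
    ConstraintConfig,
    FitnessWeights,
    ThermoTable,
    dg_penalty,
    gc_content,
    gc_penalty,
    hamming_penalty,
    homopolymer_blocks,
    hp_penalty,
    melting_temperature,
    melting_temperature_from_gc,
    rc_penalty,
    rc_similarity,
    tm_penalty,
    total_fitness,
)

S = NucleotideSequence.from_bases


class TestComposition:
    @pytest.mark.parametrize("bases,gc", [("ATCG", 50.0), ("AAAA", 0.0), ("GGCC", 100.0)])
    def test_gc_content(self, bases, gc):
        assert gc_content(S(bases)) == gc

    @pytest.mark.parametrize("bases,pen", [("ATCG", 0.0), ("AAAA", 2500.0)])
    def test_gc_penalty_quadratic(self, bases, pen):
        assert gc_penalty(S(bases)) == pen

    def test_gc_and_tm_permutation_invariant(self, rng):
        base = rng.integers(0, 4, size=120)
        ref_gc = gc_penalty(NucleotideSequence.from_digits(base))
        ref_tm = melting_temperature(NucleotideSequence.from_digits(base))
        for _ in range(100):
            shuf = NucleotideSequence.from_digits(rng.permutation(base))
            assert gc_penalty(shuf) == ref_gc
            assert melting_temperature(shuf) == ref_tm


class TestHomopolymer:
    @pytest.mark.parametrize(
        "bases,blocks",
        [
            ("AAAT", [("A", 3), ("T", 1)]),
            ("ACGT", [("A", 1), ("C", 1), ("G", 1), ("T", 1)]),
            ("AAAACCCCC", [("A", 4), ("C", 5)]),
        ],
    )
    def test_blocks(self, bases, blocks):
        got = homopolymer_blocks(S(bases))
        assert got == blocks
        assert sum(h for _, h in got) == len(bases)

    @pytest.mark.parametrize(
        "bases,pen", [("AAATTTCCC", 0.0), ("AAAAA", 4.0), ("AAAACCCCC", 5.0)]
    )
    def test_penalty(self, bases, pen):
        assert hp_penalty(S(bases)) == pen

    def test_zero_iff_no_run_exceeds_limit(self, rng):
        for _ in range(50):
            seq = NucleotideSequence.from_digits(rng.integers(0, 4, size=60))
            max_run = max(h for _, h in homopolymer_blocks(seq))
            assert (hp_penalty(seq) == 0) == (max_run <= 3)


class TestStackingEnergy:
    def test_uniform_table_gives_zero(self, uniform_thermo):
        assert dg_penalty(S("ACGTACGT"), uniform_thermo) == pytest.approx(0.0, abs=1e-9)

    def test_single_step_deviation(self, thermo):
        # default table has dg(AT) = -0.88
        assert dg_penalty(S("AT"), thermo) == pytest.approx(57.0)

    def test_mean_invariant_to_repetition(self, thermo):
        # AT and TA both sit at -0.88 and -0.58... use a custom table where both match
        table = dict.fromkeys([a + b for a in "ACGT" for b in "ACGT"], -1.45)
        table["AT"] = table["TA"] = -0.88
        custom = ThermoTable(dg=table)
        assert dg_penalty(S("AT"), custom) == pytest.approx(57.0)
        assert dg_penalty(S("ATAT"), custom) == pytest.approx(57.0)

    def test_short_sequence_warns_and_returns_zero(self, thermo):
        with pytest.warns(UserWarning):
            assert dg_penalty(S("A"), thermo) == 0.0


class TestMeltingTemperature:
    @pytest.mark.parametrize(
        "gc,tm",
        [(40.53, 74.79), (41.12, 75.04), (41.77, 75.30), (46.84, 77.38)],
    )
    def test_salt_corrected_model(self, gc, tm):
        assert round(melting_temperature_from_gc(gc), 2) == tm

    def test_zero_gc(self):
        assert melting_temperature(S("AAAA")) == pytest.approx(58.176)

    def test_penalty_inside_and_outside_range(self):
        assert tm_penalty(S("ATTA")) == 0.0  # Tm 58.18 in [55, 65]
        tm = melting_temperature(S("GGCC"))  # 99.18, above the band
        assert tm_penalty(S("GGCC")) == pytest.approx((tm - 65.0) ** 2)
        cfg = ConstraintConfig(tm_range=(60.0, 65.0))
        assert tm_penalty(S("ATTA"), cfg) == pytest.approx((60.0 - 58.176) ** 2)


class TestHamming:
    def test_distance_beyond_threshold(self):
        cfg = ConstraintConfig(archive=(S("TTTT"),), d_min=3)
        assert hamming_penalty(S("AAAA"), cfg) == (4, 0.0)

    def test_violation_squared(self):
        cfg = ConstraintConfig(archive=(S("AAAA"),), d_min=3)
        assert hamming_penalty(S("AAAT"), cfg) == (1, 4.0)

    def test_empty_archive_zero_penalty(self):
        assert hamming_penalty(S("ACGT"), ConstraintConfig()) == (None, 0.0)

    def test_length_mismatch_rejected(self):
        cfg = ConstraintConfig(archive=(S("AAAAA"),), d_min=1)
        with pytest.raises(ValueError, match="mismatch"):
            hamming_penalty(S("ACGT"), cfg)


class TestReverseComplement:
    @pytest.mark.parametrize("bases,ratio", [("ACGT", 1.0), ("AAAA", 0.0), ("AACT", 0.5)])
    def test_similarity(self, bases, ratio):
        assert rc_similarity(S(bases)) == ratio

    def test_symmetry_under_rc(self, rng):
        for _ in range(30):
            seq = NucleotideSequence.from_digits(rng.integers(0, 4, size=41))
            assert rc_similarity(seq) == pytest.approx(rc_similarity(seq.reverse_complement()))

    def test_penalty_threshold(self):
        assert rc_penalty(S("AAAA")) == 0.0
        assert rc_penalty(S("ACGT")) == pytest.approx((1.0 - 0.15) * 100.0)


class TestTotalFitness:
    def test_zero_total_iff_all_terms_zero(self, uniform_thermo):
        # GC 50%, no run > 3, every step at target, RC 0.25 -> need a seq with
        # RC <= 0.15 too; Tm(50%) = 78.68 so the band must cover it
        cfg = ConstraintConfig(tm_range=(70.0, 85.0))
        seq = S("AACCAACCAACCAACCAACC")  # GC 50, max run 2, RC match 0
        brk = total_fitness(seq, FitnessWeights(), cfg, uniform_thermo)
        assert brk.total == 0.0
        assert all(
            getattr(brk, t) == 0.0 for t in ("f_gc", "f_hp", "f_dg", "c_tm", "c_ham", "c_rc")
        )

    def test_total_is_weighted_sum_and_linear(self, thermo, rng):
        seq = NucleotideSequence.from_digits(rng.integers(0, 4, size=80))
        w = FitnessWeights(w_obj=(1.0, 2.0, 3.0), w_cons=(4.0, 5.0, 6.0))
        cfg = ConstraintConfig()
        brk = total_fitness(seq, w, cfg, thermo)
        manual = (
            1.0 * brk.f_gc + 2.0 * brk.f_hp + 3.0 * brk.f_dg
            + 4.0 * brk.c_tm + 5.0 * brk.c_ham + 6.0 * brk.c_rc
        )
        assert brk.total == pytest.approx(manual)
        dbl = FitnessWeights(w_obj=(2.0, 4.0, 6.0), w_cons=(8.0, 10.0, 12.0))
        assert total_fitness(seq, dbl, cfg, thermo).total == pytest.approx(2 * brk.total)

    def test_all_terms_nonnegative(self, thermo, rng):
        for _ in range(50):
            seq = NucleotideSequence.from_digits(rng.integers(0, 4, size=rng.integers(2, 150)))
            brk = total_fitness(seq, thermo=thermo)
            assert min(brk.f_gc, brk.f_hp, brk.f_dg, brk.c_tm, brk.c_ham, brk.c_rc) >= 0
            assert brk.total >= 0

    def test_weight_validation(self):
        with pytest.raises(ValueError):
            FitnessWeights(w_obj=(-1.0, 0.0, 0.0))
        with pytest.raises(ValueError):
            FitnessWeights(w_obj=(0.0, 0.0, 0.0), w_cons=(0.0, 0.0, 0.0))
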