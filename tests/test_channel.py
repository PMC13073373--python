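"""Error-channel simulator, edit-distance scoring and error decomposition."""

from functools import lru_cache

import numpy as np
import pytest

from tchur.channel import (
    ChannelProfile,
    REGIMES,
    context_error_summary,
    decompose_errors,
    homopolymer_stats,
    normalized_edit_distance,
    regime_profile,
    replay_events,
    simulate_read,
    ReadRecord,
)
from tchur.codec import NucleotideSequence

S = NucleotideSequence.from_bases


def oracle_edit_distance(a: str, b: str) -> int:
    """Exhaustive recursion (strings <= 8), independent of the DP path."""

    @lru_cache(maxsize=None)
    def rec(i, j):
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


class TestRegimes:
    def test_table_central_cycles(self):
        assert REGIMES["low"].central_cycles == 50
        assert REGIMES["medium"].central_cycles == 200
        assert REGIMES["high"].central_cycles == 500

    def test_monotone_in_cycles(self):
        lo, hi = regime_profile("low"), regime_profile("high")
        assert hi.p_sub >= lo.p_sub and hi.p_ins >= lo.p_ins and hi.p_del >= lo.p_del

    def test_high_regime_magnitudes(self):
        hi = regime_profile("high")
        assert (hi.p_sub, hi.p_ins, hi.p_del) == pytest.approx((0.03, 0.08, 0.02))

    def test_unknown_regime_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            regime_profile("extreme")

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            ChannelProfile(p_sub=0.5, p_ins=0.4, p_del=0.2)
        with pytest.raises(ValueError):
            ChannelProfile(p_sub=0.1, p_ins=0.1, p_del=0.1, hp_indel_multiplier=0.5)


class TestSimulator:
    def test_zero_rates_identity(self, rng):
        ref = S("ACGTACGTAC")
        rec = simulate_read(ref, ChannelProfile(0.0, 0.0, 0.0), rng)
        assert rec.read == ref.bases and rec.events == []

    def test_replay_reconstructs_read(self, rng):
        ref = NucleotideSequence.from_digits(rng.integers(0, 4, size=500))
        profile = regime_profile("high")
        for _ in range(100):
            rec = simulate_read(ref, profile, rng)
            assert replay_events(ref, rec.events) == rec.read

    def test_event_log_tallies_match(self, rng):
        ref = NucleotideSequence.from_digits(rng.integers(0, 4, size=300))
        rec = simulate_read(ref, regime_profile("high"), rng)
        n_ins = sum(1 for e in rec.events if e[1] == "ins")
        n_del = sum(1 for e in rec.events if e[1] == "del")
        assert len(rec.read) == len(ref) + n_ins - n_del

    def test_heavy_deletion_shrinks_read(self, rng):
        ref = S("ACGT" * 20)
        rec = simulate_read(ref, ChannelProfile(0.0, 0.0, 0.9), rng)
        assert len(rec.read) < len(ref) / 2

    def test_homopolymer_boost_raises_indel_rate(self, rng):
        profile = ChannelProfile(0.0, 0.02, 0.02, hp_threshold=4, hp_indel_multiplier=4.0)
        homo = S("A" * 300)
        hetero = S("ACGT" * 75)
        n_homo = sum(len(simulate_read(homo, profile, rng).events) for _ in range(400))
        n_het = sum(len(simulate_read(hetero, profile, rng).events) for _ in range(400))
        assert n_homo > n_het * 2  # 4x boost on every position vs none


class TestEditDistance:
    @pytest.mark.parametrize(
        "a,b,ned", [("ACGT", "ACGT", 0.0), ("ACGT", "", 1.0), ("ACGT", "AGT", 0.25), ("", "", 0.0)]
    )
    def test_ned_examples(self, a, b, ned):
        assert normalized_edit_distance(a, b) == ned

    def test_symmetry_and_identity(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(200):
            a = "".join(rng.choice(bases, size=rng.integers(0, 9)))
            b = "".join(rng.choice(bases, size=rng.integers(0, 9)))
            assert normalized_edit_distance(a, b) == normalized_edit_distance(b, a)
            assert (normalized_edit_distance(a, b) == 0) == (a == b)

    def test_dp_matches_recursive_oracle(self, rng):
        bases = np.array(list("ACGT"))
        for _ in range(500):
            a = "".join(rng.choice(bases, size=rng.integers(1, 9)))
            b = "".join(rng.choice(bases, size=rng.integers(1, 9)))
            counts, _ = decompose_errors(a, b)
            assert sum(counts) == oracle_edit_distance(a, b)


class TestDecomposition:
    @pytest.mark.parametrize(
        "a,b,counts",
        [
            ("AAAA", "AATA", (1, 0, 0)),
            ("AAAA", "AAA", (0, 0, 1)),
            ("AAAA", "AAAAA", (0, 1, 0)),
            ("ACGT", "ACGT", (0, 0, 0)),
        ],
    )
    def test_examples(self, a, b, counts):
        got, rates = decompose_errors(a, b)
        assert got == counts
        assert rates == tuple(c / len(a) for c in counts)

    def test_counts_sum_to_distance_on_simulated_pairs(self, rng):
        ref = NucleotideSequence.from_digits(rng.integers(0, 4, size=120))
        profile = regime_profile("medium")
        for _ in range(25):
            rec = simulate_read(ref, profile, rng)
            counts, _ = decompose_errors(ref.bases, rec.read)
            assert sum(counts) == round(
                normalized_edit_distance(ref.bases, rec.read) * max(len(ref), len(rec.read))
            )


class TestHomopolymerStats:
    def test_single_read(self):
        avg_max, avg_count, _ = homopolymer_stats(["AAAACCGT"])
        assert (avg_max, avg_count) == (4.0, 1.0)
        assert homopolymer_stats(["ACGT"])[:2] == (1.0, 0.0)

    def test_mean_over_reads(self):
        avg_max, _, _ = homopolymer_stats(["AAAA", "CCCCCC"])
        assert avg_max == 5.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            homopolymer_stats([])

    def test_hp_indel_attribution(self):
        ref = S("AAAACGTC")
        rec = ReadRecord(read="AAACGTC", events=[(2, "del", "A", "")])
        _, _, pct = homopolymer_stats([rec], ref)
        assert pct == 100.0


class TestContextSummary:
    def test_single_gc_to_at(self):
        ref = S("AGGA")
        rec = ReadRecord(read="AAGA", events=[(1, "sub", "G", "A")])
        s = context_error_summary(ref, [rec])
        assert s.gc_to_at_pct == 100.0 and s.at_to_gc_pct == 0.0

    def test_at_to_gc_only(self):
        ref = S("ATAT")
        rec = ReadRecord(
            read="GTCT", events=[(0, "sub", "A", "G"), (2, "sub", "A", "C")]
        )
        s = context_error_summary(ref, [rec])
        assert s.at_to_gc_pct == 100.0 and s.gc_to_at_pct == 0.0

    def test_substitution_in_run_counts_as_hp_sub(self):
        ref = S("AAAAG")
        rec = ReadRecord(read="AATAG", events=[(2, "sub", "A", "T")])
        s = context_error_summary(ref, [rec])
        assert s.hp_sub_pct == 100.0

    def test_no_substitutions_reported_as_none(self):
        ref = S("ACGT")
        rec = ReadRecord(read="ACGT", events=[])
        s = context_error_summary(ref, [rec])
        assert s.gc_to_at_pct is None and s.hp_sub_pct is None
        assert s.ned == 0.0
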