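"""Degradome profiles, peak categories, dinucleotide shuffling, validation."""

from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from apexmir._seq import revcomp
from apexmir.degradome import (
    DegradomeProfile,
    build_profile,
    compare_contrasts,
    dinucleotide_shuffle,
    peak_category,
    validate_interaction,
)
from apexmir.simulate import simulate_degradome


def _dinucs(seq):
    return Counter(seq[i : i + 2] for i in range(len(seq) - 1))


class TestBuildProfile:
    TRANSCRIPTS = {"t1": "ACGTACGTAC" * 60, "t2": "TTGCA" * 100}

    def test_no_matching_tags_zero_profile(self):
        profiles = build_profile(["GGGGGGGGGGGGGGGGGGGG"], self.TRANSCRIPTS)
        assert profiles["t1"].total == 0
        assert profiles["t2"].total == 0

    def test_stacked_tags_pile_at_one_position(self, rng):
        body = "".join(rng.choice(list("ACGT"), size=700))
        tag = body[500:520]
        profiles = build_profile([tag] * 100, {"t1": body})
        assert profiles["t1"].counts[500] == 100
        assert profiles["t1"].total == 100

    def test_simulated_signal_peaks_at_planted_position(self, small_ref):
        tags = simulate_degradome(small_ref, depth=4000, signal_fraction=0.8, seed=5)
        profiles = build_profile(tags, small_ref.transcripts)
        for tid, pos, _frac in small_ref.truth.planted_cleavage:
            counts = profiles[tid].counts
            assert int(np.argmax(counts)) == pos - 1

    def test_short_tags_skipped(self):
        profiles = build_profile(["ACGTACGTAC"], self.TRANSCRIPTS)  # 10 < 15 nt
        assert profiles["t1"].total == 0


def _category_oracle(counts, pos1):
    c = int(counts[pos1 - 1])
    if c == 0:
        return None
    if c == 1:
        return 4
    top = int(counts.max())
    occupied = counts[counts > 0]
    mean = float(occupied.mean())
    if c == top:
        return 0 if int((counts == top).sum()) == 1 else 1
    return 2 if c > mean else 3


class TestPeakCategory:
    def _profile(self, counts):
        return DegradomeProfile("t", np.array(counts, dtype=np.int64))

    def test_unique_maximum_is_category_zero(self):
        assert peak_category(self._profile([0, 50, 10, 0]), 2) == 0

    def test_tied_maximum_is_category_one(self):
        assert peak_category(self._profile([50, 50, 10]), 1) == 1

    def test_count_one_is_category_four(self):
        assert peak_category(self._profile([0, 1, 7]), 2) == 4

    def test_zero_count_has_no_category(self):
        assert peak_category(self._profile([0, 1, 7]), 1) is None

    def test_randomized_profiles_match_rule_oracle(self, rng):
        for _ in range(50):
            counts = rng.integers(0, 20, size=30)
            profile = self._profile(counts)
            pos = int(rng.integers(1, 31))
            assert peak_category(profile, pos) == _category_oracle(
                np.asarray(counts), pos
            )


class TestDinucleotideShuffle:
    @given(st.text(alphabet="ACGU", min_size=3, max_size=40))
    def test_dinucleotide_counts_preserved(self, seq):
        rng = np.random.default_rng(0)
        shuffled = dinucleotide_shuffle(seq, rng)
        assert _dinucs(shuffled) == _dinucs(seq)
        assert len(shuffled) == len(seq)

    def test_homopolymer_unchanged(self):
        rng = np.random.default_rng(0)
        assert dinucleotide_shuffle("AAAAAAA", rng) == "AAAAAAA"

    def test_many_draws_all_valid_and_varied(self, rng):
        seq = "UGACAGAAGAGAGUGAGCACU"
        outcomes = set()
        for _ in range(500):
            s = dinucleotide_shuffle(seq, rng)
            assert _dinucs(s) == _dinucs(seq)
            outcomes.add(s)
        assert len(outcomes) > 50  # the sampler explores many Eulerian paths


class TestValidateInteraction:
    def test_planted_interaction_validated(self, small_ref):
        tags = simulate_degradome(small_ref, depth=10_000, signal_fraction=0.9, seed=6)
        profiles = build_profile(tags, small_ref.transcripts)
        by_name = {p.name: p for p in small_ref.truth.planted_mirnas}
        planted = small_ref.truth.planted_targets[0]
        mirna = by_name[planted.mirna]
        res = validate_interaction(
            mirna.name, mirna.mature, planted.transcript_id,
            small_ref.transcripts[planted.transcript_id], profiles, seed=3,
        )
        assert not isinstance(res, str), res
        expected_pos = planted.site_start + planted.site_len - 9
        assert res.cleavage_position == expected_pos
        assert res.shuffle_p <= 0.05
        assert res.category in (0, 1)

    def test_scrambled_mirna_rejected(self, small_ref, rng):
        tags = simulate_degradome(small_ref, depth=5_000, signal_fraction=0.9, seed=6)
        profiles = build_profile(tags, small_ref.transcripts)
        tid = small_ref.truth.planted_cleavage[0][0]
        scrambled = "".join(rng.permutation(list("UGACAGAAGAGAGUGAGCACU")))
        res = validate_interaction(
            "scrambled", scrambled, tid, small_ref.transcripts[tid], profiles, seed=3
        )
        assert isinstance(res, str)

    def test_missing_transcript_rejected_with_reason(self):
        res = validate_interaction(
            "m", "UGACAGAAGAGAGUGAGCACU", "absent", "ACGT" * 30, {}, seed=0
        )
        assert isinstance(res, str) and "absent" in res

    def test_deterministic_under_seed(self, small_ref):
        tags = simulate_degradome(small_ref, depth=5_000, signal_fraction=0.9, seed=6)
        profiles = build_profile(tags, small_ref.transcripts)
        by_name = {p.name: p for p in small_ref.truth.planted_mirnas}
        planted = small_ref.truth.planted_targets[0]
        mirna = by_name[planted.mirna]
        args = (
            mirna.name, mirna.mature, planted.transcript_id,
            small_ref.transcripts[planted.transcript_id], profiles,
        )
        r1 = validate_interaction(*args, seed=9)
        r2 = validate_interaction(*args, seed=9)
        assert r1.shuffle_p == r2.shuffle_p
        assert r1.cleavage_position == r2.cleavage_position

    def test_p_value_lower_bound(self, small_ref):
        tags = simulate_degradome(small_ref, depth=5_000, signal_fraction=0.9, seed=6)
        profiles = build_profile(tags, small_ref.transcripts)
        by_name = {p.name: p for p in small_ref.truth.planted_mirnas}
        planted = small_ref.truth.planted_targets[0]
        mirna = by_name[planted.mirna]
        res = validate_interaction(
            mirna.name, mirna.mature, planted.transcript_id,
            small_ref.transcripts[planted.transcript_id], profiles,
            n_shuffles=50, seed=1,
        )
        assert res.shuffle_p >= 1 / 51


class TestCompareContrasts:
    def test_opposite_and_concordant_labels(self):
        a = [("miR160", "t1", "up"), ("miR166", "t2", "down")]
        b = [("miR160", "t1", "down"), ("miR166", "t2", "down")]
        out = compare_contrasts(a, b)
        assert out[("miR160", "t1")] == "opposite"
        assert out[("miR166", "t2")] == "concordant"

    def test_exclusive_labels(self):
        out = compare_contrasts([("miR159", "t3", "up")], [])
        assert out[("miR159", "t3")] == "exclusive:A1-A9"

    def test_empty_second_set_all_exclusive(self):
        a = [("miR1", "t1", "up"), ("miR2", "t2", "down")]
        out = compare_contrasts(a, [])
        assert all(v == "exclusive:A1-A9" for v in out.values())
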