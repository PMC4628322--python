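"""Duplex penalty scoring, target scanning and regulation-mode classification."""

import pytest

from apexmir._seq import revcomp, to_rna
from apexmir.targets import (
    TargetInteraction,
    classify_mode,
    find_targets,
    score_duplex,
)

MIRNA = "UGACAGAAGAGAGUGAGCACU"  # 21 nt, G/U-rich enough for wobble edits
PERFECT_SITE = revcomp(MIRNA)  # DNA site on the transcript, 5'->3'


def _mutate_site(site, mirna_pos, new_base):
    """Replace the site base pairing the given 1-based miRNA position."""
    idx = len(site) - mirna_pos
    return site[:idx] + new_base + site[idx + 1 :]


def _wobble_site(site, mirna, mirna_pos):
    base = to_rna(mirna)[mirna_pos - 1]
    assert base in "GU", "wobble needs G or U on the miRNA side"
    return _mutate_site(site, mirna_pos, "T" if base == "G" else "G")


class TestScoreDuplex:
    def test_perfect_complement_scores_zero(self):
        penalty, aln = score_duplex(MIRNA, PERFECT_SITE)
        assert penalty == 0.0
        assert set(aln.pair_status) == {"WC"}

    def test_wobble_position_weighting(self):
        # G:U outside the core (position 15) costs 0.5 ...
        site = _wobble_site(PERFECT_SITE, MIRNA, 15)
        assert score_duplex(MIRNA, site)[0] == pytest.approx(0.5)
        # ... the same wobble inside positions 2-13 costs double
        site = _wobble_site(PERFECT_SITE, MIRNA, 6)
        assert score_duplex(MIRNA, site)[0] == pytest.approx(1.0)

    def test_mismatch_plus_bulge(self):
        # mismatch at position 5 (doubled: 2) plus a 1-nt site bulge at
        # position 16 (2) -> 4
        site = _mutate_site(PERFECT_SITE, 5, "C" if PERFECT_SITE[16] != "C" else "A")
        m_base = to_rna(MIRNA)[4]
        mm = {"A": "C", "C": "A", "G": "A", "U": "C"}[m_base]
        site = _mutate_site(PERFECT_SITE, 5, mm)
        idx = len(site) - 16
        bulged = site[:idx] + "A" + site[idx:]
        penalty, _ = score_duplex(MIRNA, bulged)
        assert penalty == pytest.approx(4.0)

    def test_length_bounds_enforced(self):
        with pytest.raises(ValueError):
            score_duplex("ACGU" * 3, PERFECT_SITE)
        with pytest.raises(ValueError):
            score_duplex(MIRNA, PERFECT_SITE + "ACGTACGT")

    def test_reverse_complement_symmetry(self):
        """Scoring depends only on the pairing pattern, so rebuilding the
        duplex from the other strand's perspective gives the same penalty."""
        site = _wobble_site(PERFECT_SITE, MIRNA, 15)
        p1, _ = score_duplex(MIRNA, site)
        # swap roles: the site (as RNA) becomes the guide and the miRNA the
        # site; both are still written 5'->3'
        p2, _ = score_duplex(to_rna(site), MIRNA)
        # weighting regions differ between the two orientations only if a
        # penalty sits in exactly one core; position 15 maps to position 7
        # of the swapped guide (inside its core) so p2 doubles p1
        assert p2 == pytest.approx(2 * p1)


def _brute_force_scan(mirna, transcripts, cutoff):
    """Oracle: score every window of every admissible length directly."""
    hits = set()
    lm = len(mirna)
    for tid, seq in transcripts.items():
        for site_len in range(lm - 2, lm + 3):
            if not 18 <= site_len <= 26:
                continue
            for start in range(len(seq) - site_len + 1):
                pen, _ = score_duplex(mirna, seq[start : start + site_len])
                if pen <= cutoff:
                    hits.add((tid, start, site_len, pen))
    return hits


class TestFindTargets:
    def test_planted_perfect_site_found(self, rng):
        body = "".join(rng.choice(list("ACGT"), size=300))
        transcript = body[:100] + PERFECT_SITE + body[100:]
        hits = find_targets("m1", MIRNA, {"t1": transcript})
        assert any(h.start == 100 and h.penalty == 0.0 for h in hits)

    def test_no_site_below_cutoff_empty(self):
        # a transcript that cannot pair: pure A against an A-poor miRNA
        hits = find_targets("m1", MIRNA, {"t1": "A" * 100}, cutoff=4.0)
        assert hits == []

    def test_matches_brute_force_on_random_fixture(self, rng):
        transcripts = {
            f"t{i}": "".join(rng.choice(list("ACGT"), size=120)) for i in range(4)
        }
        # plant one perfect and one wobbled site so the scan has true hits
        transcripts["t0"] = transcripts["t0"][:40] + PERFECT_SITE + transcripts["t0"][40:]
        transcripts["t1"] = (
            transcripts["t1"][:60]
            + _wobble_site(PERFECT_SITE, MIRNA, 15)
            + transcripts["t1"][60:]
        )
        cutoff = 4.0
        found = find_targets("m1", MIRNA, transcripts, cutoff=cutoff)
        oracle = _brute_force_scan(MIRNA, transcripts, cutoff)
        # every reported hit must be in the oracle set with the same penalty
        for h in found:
            assert (h.transcript_id, h.start, h.end - h.start, h.penalty) in oracle
        # every oracle hit must be covered by a reported hit that overlaps it
        # with an equal-or-lower penalty (overlap merging keeps the best)
        for tid, start, slen, pen in oracle:
            covering = [
                h for h in found
                if h.transcript_id == tid and h.start < start + slen and start < h.end
            ]
            assert covering and min(c.penalty for c in covering) <= pen

    def test_invariant_to_transcript_order(self, rng):
        transcripts = {
            f"t{i}": "".join(rng.choice(list("ACGT"), size=150)) for i in range(3)
        }
        transcripts["t2"] = transcripts["t2"][:50] + PERFECT_SITE + transcripts["t2"][50:]
        a = find_targets("m1", MIRNA, transcripts)
        b = find_targets("m1", MIRNA, dict(reversed(list(transcripts.items()))))
        assert [(h.transcript_id, h.start, h.penalty) for h in a] == [
            (h.transcript_id, h.start, h.penalty) for h in b
        ]

    def test_raising_cutoff_never_removes_hits(self, rng):
        transcripts = {"t0": "".join(rng.choice(list("ACGT"), size=400))}
        transcripts["t0"] = transcripts["t0"][:200] + PERFECT_SITE + transcripts["t0"][200:]
        tight = find_targets("m1", MIRNA, transcripts, cutoff=1.0)
        loose = find_targets("m1", MIRNA, transcripts, cutoff=4.0)
        tight_keys = {(h.transcript_id, h.start) for h in tight}
        loose_keys = {(h.transcript_id, h.start) for h in loose}
        assert tight_keys <= loose_keys


class TestClassifyMode:
    def test_perfect_complement_is_cleavage(self):
        _, aln = score_duplex(MIRNA, PERFECT_SITE)
        it = TargetInteraction("m", "t", 0, 21, 0.0, aln)
        assert classify_mode(it) == "cleavage"

    def test_central_mismatch_blocks_cleavage(self):
        m_base = to_rna(MIRNA)[9]
        mm = {"A": "C", "C": "A", "G": "A", "U": "C"}[m_base]
        site = _mutate_site(PERFECT_SITE, 10, mm)
        pen, aln = score_duplex(MIRNA, site)
        it = TargetInteraction("m", "t", 0, 21, pen, aln)
        assert classify_mode(it) == "translational_repression"

    def test_peripheral_wobble_keeps_cleavage(self):
        site = _wobble_site(PERFECT_SITE, MIRNA, 17)
        pen, aln = score_duplex(MIRNA, site)
        it = TargetInteraction("m", "t", 0, 21, pen, aln)
        assert classify_mode(it) == "cleavage"
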