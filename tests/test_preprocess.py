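"""Read cleaning, tag collapsing and contaminant removal."""

import numpy as np
import pytest

from apexmir._seq import revcomp, write_fastq
from apexmir.preprocess import (
    clean_reads,
    collapse,
    remove_contaminants,
)

ADAPTER = "TGGAATTCTCGGGTGCCAAGG"


def _write(tmp_path, reads, name="lib.fastq"):
    path = tmp_path / name
    write_fastq(path, ((f"r{i}", s) for i, s in enumerate(reads)))
    return path


class TestCleanReads:
    def test_empty_fastq(self, tmp_path):
        path = _write(tmp_path, [])
        survivors, stats = clean_reads(path, ADAPTER)
        assert survivors == []
        assert stats.raw_reads == stats.clean_reads == 0
        assert all(v == 0 for v in stats.removed.values())

    def test_constructed_fixture_counts(self, tmp_path, rng):
        good = ["".join(rng.choice(list("CGT"), size=21)) + ADAPTER for _ in range(5)]
        no_adapter = ["CGTACGTACGTACGTACGTACGTACGTACG", ADAPTER + "CGTACG"]
        polya = ["A" * 24 + ADAPTER]
        outliers = ["CGTACGTACGTACGT" + ADAPTER, "CGT" * 13 + ADAPTER]  # 15 and 39 nt
        path = _write(tmp_path, good + no_adapter + polya + outliers)
        survivors, stats = clean_reads(path, ADAPTER)
        assert stats.raw_reads == 10
        assert stats.clean_reads == 5
        assert stats.removed == {"no_insert": 2, "polyA": 1, "length": 2}
        assert sorted(survivors) == sorted(s[:21] for s in good)

    def test_16nt_insert_removed_by_length_rule(self, tmp_path):
        path = _write(tmp_path, ["CGTACGTACGTACGTC" + ADAPTER])  # 16-nt insert
        survivors, stats = clean_reads(path, ADAPTER)
        assert survivors == []
        assert stats.removed["length"] == 1

    def test_17nt_insert_survives(self, tmp_path):
        path = _write(tmp_path, ["CGTACGTACGTACGTCG" + ADAPTER])
        survivors, _ = clean_reads(path, ADAPTER)
        assert len(survivors) == 1

    def test_count_conservation(self, tmp_path, rng):
        reads = []
        for _ in range(200):
            ln = int(rng.integers(10, 45))
            reads.append("".join(rng.choice(list("ACGT"), size=ln)) + ADAPTER)
        path = _write(tmp_path, reads)
        _, stats = clean_reads(path, ADAPTER)
        assert stats.clean_reads + sum(stats.removed.values()) == stats.raw_reads

    def test_malformed_record_reports_index(self, tmp_path):
        path = tmp_path / "bad.fastq"
        path.write_text("@r0\nACGT\n+\nIIII\n@r1\nACGT\n+\nII\n")
        with pytest.raises(ValueError, match="index 1"):
            clean_reads(path, ADAPTER)

    def test_invalid_parameters(self, tmp_path):
        path = _write(tmp_path, [])
        with pytest.raises(ValueError):
            clean_reads(path, "")
        with pytest.raises(ValueError):
            clean_reads(path, ADAPTER, min_len=30, max_len=20)


class TestCollapse:
    def test_basic_counting(self):
        tags = collapse({"A1": ["AAAT" * 5, "AAAT" * 5, "CCCG" * 5]})
        by_seq = {t.sequence: t for t in tags}
        assert len(tags) == 2
        assert by_seq["AAAT" * 5].counts == {"A1": 2}
        assert by_seq["CCCG" * 5].counts == {"A1": 1}

    def test_disjoint_libraries_independent(self):
        tags = collapse({"A1": ["ACGT" * 5], "A9": ["TTTA" * 5]})
        by_seq = {t.sequence: t for t in tags}
        assert by_seq["ACGT" * 5].counts.get("A9", 0) == 0
        assert by_seq["TTTA" * 5].counts.get("A1", 0) == 0

    def test_total_count_conservation(self, rng):
        reads = ["".join(rng.choice(list("ACGT"), size=20)) for _ in range(1000)]
        # force duplicates so collapsing is non-trivial
        reads = [reads[i % 300] for i in range(1000)]
        tags = collapse({"A1": reads})
        assert sum(t.counts["A1"] for t in tags) == 1000


def _brute_force_contaminant(tag, refs, max_mm):
    """Oracle: all-offset Hamming scan, both strands, U/T-insensitive."""
    tag = tag.upper().replace("U", "T")
    for seq in refs.values():
        for ref in (seq.upper().replace("U", "T"), revcomp(seq)):
            for off in range(len(ref) - len(tag) + 1):
                window = ref[off : off + len(tag)]
                if sum(a != b for a, b in zip(tag, window)) <= max_mm:
                    return True
    return False


class TestRemoveContaminants:
    REFS = {"tRNA_1": "ACGGTTACCGGATCGATCGGCTAGCTAGGCTACGGATCGGCTA" * 2}

    def _tags(self, seqs):
        return collapse({"A1": seqs})

    def test_exact_substring_is_contaminant(self):
        tag = self.REFS["tRNA_1"][5:28]
        hit, kept = remove_contaminants(self._tags([tag]), self.REFS)
        assert len(hit) == 1 and not kept
        assert hit[0].annotation == "contaminant"
        assert hit[0].annotation_detail == "tRNA"

    def test_two_mismatches_retained_at_max_one(self):
        tag = list(self.REFS["tRNA_1"][5:28])
        tag[3] = "A" if tag[3] != "A" else "C"
        tag[10] = "A" if tag[10] != "A" else "C"
        hit, kept = remove_contaminants(self._tags(["".join(tag)]), self.REFS)
        assert not hit and len(kept) == 1

    def test_reverse_strand_match(self):
        tag = revcomp(self.REFS["tRNA_1"][10:32])
        hit, _ = remove_contaminants(self._tags([tag]), self.REFS)
        assert len(hit) == 1

    def test_matches_brute_force_oracle(self, rng):
        refs = {
            f"rRNA_{i}": "".join(rng.choice(list("ACGT"), size=120)) for i in range(3)
        }
        tags = []
        for _ in range(30):
            tags.append("".join(rng.choice(list("ACGT"), size=20)))
        for _ in range(20):  # near-copies of reference windows
            src = refs[f"rRNA_{int(rng.integers(3))}"]
            off = int(rng.integers(0, 100))
            t = list(src[off : off + 20])
            for _m in range(int(rng.integers(0, 3))):
                t[int(rng.integers(20))] = "ACGT"[int(rng.integers(4))]
            tags.append("".join(t))
        tag_objs = self._tags(tags)
        hit, kept = remove_contaminants(tag_objs, refs, max_mismatch=1)
        hit_seqs = {t.sequence for t in hit}
        for seq in {t.sequence for t in tag_objs}:
            assert (seq in hit_seqs) == _brute_force_contaminant(seq, refs, 1)

    def test_zero_mismatch_subset_of_one(self, rng):
        refs = {"snRNA_1": "".join(rng.choice(list("ACGT"), size=150))}
        tags = []
        for _ in range(40):
            off = int(rng.integers(0, 130))
            t = list(refs["snRNA_1"][off : off + 20])
            if rng.random() < 0.5:
                t[int(rng.integers(20))] = "ACGT"[int(rng.integers(4))]
            tags.append("".join(t))
        strict_hits = {
            t.sequence
            for t in remove_contaminants(self._tags(tags), refs, max_mismatch=0)[0]
        }
        loose_hits = {
            t.sequence
            for t in remove_contaminants(self._tags(tags), refs, max_mismatch=1)[0]
        }
        assert strict_hits <= loose_hits

    def test_empty_contaminant_set_rejected(self):
        with pytest.raises(ValueError):
            remove_contaminants([], {})
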