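"""Raw small-RNA FASTQ -> collapsed, annotated unique tags.

The cleaning rules mirror a standard plant sRNA-seq pipeline: 3' adapter
trimming, discarding reads with no recoverable insert (adapter missing, or
adapter at position 0 meaning an empty insert / 5'-primer artifact),
poly(A) inserts, and inserts outside the 17-35 nt window.  Cleaned reads are
collapsed to unique tags with per-library counts, then tags matching a
contaminant ncRNA set (tRNA/rRNA/sn(o)RNA) end-to-end with at most one
substitution are partitioned out.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from ._seq import iter_fastq, revcomp, to_dna

#: annotation classes, in assignment-precedence order
ANNOTATION_PRECEDENCE = ("contaminant", "known_miRNA", "novel_miRNA", "unannotated")


@dataclass
class SequenceTag:
    """A unique small-RNA sequence with per-library read counts."""

    sequence: str
    counts: dict[str, int] = field(default_factory=dict)
    annotation: str = "unannotated"
    annotation_detail: str | None = None  # contaminant class or miRNA name

    @property
    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class LibraryStats:
    library: str
    raw_reads: int = 0
    clean_reads: int = 0
    unique_reads: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def check(self) -> None:
        if self.clean_reads + sum(self.removed.values()) != self.raw_reads:
            raise AssertionError("read counts do not conserve across filters")


def _find_adapter(read: str, adapter: str, min_overlap: int = 6) -> int | None:
    """Return the insert length (adapter start), or None if no adapter found.

    The full adapter is searched first; failing that, a 3'-terminal prefix of
    the adapter of at least ``min_overlap`` nt is accepted (adapter running
    off the end of the read).
    """
    pos = read.find(adapter)
    if pos >= 0:
        return pos
    max_tail = min(len(adapter) - 1, len(read))
    for k in range(max_tail, min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            return len(read) - k
    return None


def clean_reads(
    fastq_path: str | Path,
    adapter: str,
    *,
    min_len: int = 17,
    max_len: int = 35,
    polya_frac: float = 0.8,
    library: str | None = None,
) -> tuple[list[str], LibraryStats]:
    """Adapter-trim and filter one library; returns surviving inserts + stats.

    Removal classes: ``no_insert`` (adapter absent or at position 0),
    ``polyA`` (>= ``polya_frac`` adenine in the trimmed insert), ``length``
    (insert outside [min_len, max_len]).
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    adapter = to_dna(adapter)
    stats = LibraryStats(library=library or Path(fastq_path).stem)
    removed = Counter({"no_insert": 0, "polyA": 0, "length": 0})
    survivors: list[str] = []
    for _name, seq in iter_fastq(fastq_path):
        stats.raw_reads += 1
        seq = to_dna(seq)
        ins_len = _find_adapter(seq, adapter)
        if ins_len is None or ins_len == 0:
            removed["no_insert"] += 1
            continue
        insert = seq[:ins_len]
        if insert.count("A") >= polya_frac * len(insert):
            removed["polyA"] += 1
            continue
        if not min_len <= len(insert) <= max_len:
            removed["length"] += 1
            continue
        survivors.append(insert)
    stats.clean_reads = len(survivors)
    stats.removed = dict(removed)
    stats.unique_reads = len(set(survivors))
    stats.check()
    return survivors, stats


def collapse(reads_per_library: Mapping[str, Iterable[str]]) -> list[SequenceTag]:
    """Collapse cleaned reads into unique tags with per-library counts."""
    counts: dict[str, dict[str, int]] = defaultdict(dict)
    for lib, reads in reads_per_library.items():
        c = Counter(to_dna(r) for r in reads)
        for seq, n in c.items():
            counts[seq][lib] = n
    tags = [SequenceTag(sequence=seq, counts=dict(libc)) for seq, libc in counts.items()]
    tags.sort(key=lambda t: (-t.total, t.sequence))
    return tags


def _hamming_hits(tag: str, reference: str, max_mismatch: int) -> bool:
    """End-to-end, gap-free alignment of tag at every offset of reference."""
    n, m = len(reference), len(tag)
    if m > n:
        return False
    ref = np.frombuffer(reference.encode(), dtype=np.uint8)
    t = np.frombuffer(tag.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(ref, m)
    mismatches = (windows != t).sum(axis=1)
    return bool((mismatches <= max_mismatch).any())


def remove_contaminants(
    tags: Sequence[SequenceTag],
    contaminants: Mapping[str, str],
    *,
    max_mismatch: int = 1,
) -> tuple[list[SequenceTag], list[SequenceTag]]:
    """Partition tags into (contaminant, retained).

    A tag is contaminant iff it aligns end-to-end without gaps to any
    contaminant reference, on either strand, with at most ``max_mismatch``
    substitutions.  Matching is U/T-insensitive.  The contaminant class is
    taken from the reference id (text before the first '_' or '|').
    """
    if not contaminants:
        raise ValueError("contaminant set must be non-empty")
    refs = [(rid, to_dna(seq)) for rid, seq in contaminants.items()]
    refs_rc = [(rid, revcomp(seq)) for rid, seq in refs]
    hit, kept = [], []
    for tag in tags:
        seq = to_dna(tag.sequence)
        match_id = None
        for rid, rseq in refs + refs_rc:
            if _hamming_hits(seq, rseq, max_mismatch):
                match_id = rid
                break
        if match_id is not None:
            tag.annotation = "contaminant"
            tag.annotation_detail = match_id.split("_")[0].split("|")[0]
            hit.append(tag)
        else:
            kept.append(tag)
    return hit, kept


def write_tag_fasta(tags: Sequence[SequenceTag], path) -> None:
    """Collapsed tags as FASTA with ``tag<N>_x<count>`` headers (total count)."""
    with open(path, "w") as fh:
        for i, tag in enumerate(tags, start=1):
            fh.write(f">tag{i}_x{tag.total}\n{tag.sequence}\n")


def count_matrix(tags: Sequence[SequenceTag], libraries: Sequence[str]):
    """Tag x library count matrix as a DataFrame (tag sequences as index)."""
    import pandas as pd

    data = {
        tag.sequence: [tag.counts.get(lib, 0) for lib in libraries] for tag in tags
    }
    return pd.DataFrame.from_dict(data, orient="index", columns=list(libraries))


def stats_table(stats: Iterable[LibraryStats]):
    """LibraryStats rows as a DataFrame shaped like a data-set summary table."""
    import pandas as pd

    rows = []
    for s in stats:
        row = {
            "library": s.library,
            "raw_reads": s.raw_reads,
            "clean_reads": s.clean_reads,
            "unique_reads": s.unique_reads,
        }
        row.update({f"removed_{k}": v for k, v in sorted(s.removed.items())})
        rows.append(row)
    return pd.DataFrame(rows)
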