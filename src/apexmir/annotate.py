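"""Known-miRNA identification, family grouping, precursor recovery, star detection.

Identification is by exact (U/T-insensitive) match of a tag to a catalog of
mature miRNAs with miRBase-style names (``ghr-miR162a``), the conservative
no-mismatch rule.  Families are derived from names (``ghr-miR162a`` ->
``miR162``); unknown families pool under "NA".  For tags that map exactly to
the genome, a precursor window of +/-150 nt flanking the mature locus is
extracted strand-orientedly, and star-strand evidence is sought at the
duplex position implied by the 2-nt 3' overhang of Dicer processing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ._seq import revcomp, to_dna, to_rna
from .folding import pair_table
from .preprocess import SequenceTag

_FAMILY_RE = re.compile(r"(?:^|-)(miR|MIR)(\d+)", re.IGNORECASE)


@dataclass(frozen=True)
class MiRNACatalogEntry:
    """One mature miRNA from a miRBase-style catalog."""

    name: str
    mature: str  # RNA string
    family_override: str | None = None

    @property
    def species(self) -> str:
        return self.name.split("-", 1)[0] if "-" in self.name else ""

    @property
    def family(self) -> str:
        if self.family_override:
            return self.family_override
        m = _FAMILY_RE.search(self.name)
        return f"miR{m.group(2)}" if m else "NA"


@dataclass(frozen=True)
class Locus:
    """0-based half-open genomic interval with strand."""

    ref: str
    start: int
    end: int
    strand: str  # '+' or '-'


@dataclass
class PrecursorCandidate:
    """A genomic hairpin candidate around a mature miRNA locus."""

    locus: Locus
    sequence: str  # strand-oriented (5'->3' of the miRNA-bearing strand)
    mature: tuple[int, int]  # 0-based half-open interval in precursor coords
    structure: str | None = None
    mfe: float | None = None
    gc: float | None = None
    mfei: float | None = None
    star: tuple[int, int] | None = None
    paired_in_duplex: int | None = None
    arm_size_diff: int | None = None
    name: str | None = None
    engine: str | None = None

    def __post_init__(self) -> None:
        m0, m1 = self.mature
        if not (0 <= m0 < m1 <= len(self.sequence)):
            raise ValueError("mature arm outside precursor bounds")


def load_catalog(
    fasta: Mapping[str, str], family_override: Mapping[str, str] | None = None
) -> list[MiRNACatalogEntry]:
    override = family_override or {}
    return [
        MiRNACatalogEntry(name=n, mature=to_rna(s), family_override=override.get(n))
        for n, s in fasta.items()
    ]


def match_known(
    tags: Sequence[SequenceTag],
    catalog: Sequence[MiRNACatalogEntry],
    *,
    own_species: str = "ghr",
) -> dict[str, MiRNACatalogEntry]:
    """Assign tags to catalog entries by exact sequence identity.

    Ties across species for the same mature sequence are resolved by own
    species first, then lexicographic name order.  Returns {tag sequence ->
    entry}; matched tags are annotated in place as known miRNAs.
    """
    if not catalog:
        raise ValueError("catalog must be non-empty")
    by_seq: dict[str, list[MiRNACatalogEntry]] = {}
    for entry in catalog:
        by_seq.setdefault(to_dna(entry.mature), []).append(entry)
    for seq, entries in by_seq.items():
        entries.sort(key=lambda e: (e.species != own_species, e.name))
    assignments: dict[str, MiRNACatalogEntry] = {}
    for tag in tags:
        hit = by_seq.get(to_dna(tag.sequence))
        if hit:
            assignments[tag.sequence] = hit[0]
            tag.annotation = "known_miRNA"
            tag.annotation_detail = hit[0].name
    return assignments


def group_families(
    tags: Sequence[SequenceTag],
    assignments: Mapping[str, MiRNACatalogEntry],
    libraries: Sequence[str],
):
    """Per-family per-library count matrix (DataFrame, families as index).

    Family counts are the exact sums of member-tag counts; entries whose
    family cannot be derived pool under "NA".
    """
    import pandas as pd

    if not assignments:
        raise ValueError("no assignments to group")
    rows: dict[str, dict[str, float]] = {}
    for tag in tags:
        entry = assignments.get(tag.sequence)
        if entry is None:
            continue
        fam = entry.family
        row = rows.setdefault(fam, {lib: 0 for lib in libraries})
        for lib in libraries:
            row[lib] += tag.counts.get(lib, 0)
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(libraries))
    return df.fillna(0).sort_index()


def map_exact(
    sequence: str, genome: Mapping[str, str], *, max_loci: int = 20
) -> list[Locus]:
    """All exact genomic loci of a tag, both strands, up to ``max_loci``."""
    seq = to_dna(sequence)
    rc = revcomp(seq)
    loci: list[Locus] = []
    for ref, chrom_seq in genome.items():
        chrom_seq = to_dna(chrom_seq)
        for query, strand in ((seq, "+"), (rc, "-")):
            start = chrom_seq.find(query)
            while start >= 0:
                loci.append(Locus(ref, start, start + len(query), strand))
                if len(loci) >= max_loci:
                    return loci
                start = chrom_seq.find(query, start + 1)
    return loci


def recover_precursor(
    locus: Locus, genome: Mapping[str, str], *, flank: int = 150
) -> PrecursorCandidate:
    """Extract the strand-oriented window [start-flank, end+flank), clipped.

    The mature interval is re-expressed in precursor coordinates; on the
    minus strand the window is reverse-complemented so the mature sequence
    reads 5'->3' in the returned precursor.
    """
    chrom = to_dna(genome[locus.ref])
    win_start = max(0, locus.start - flank)
    win_end = min(len(chrom), locus.end + flank)
    window = chrom[win_start:win_end]
    if locus.strand == "+":
        mature = (locus.start - win_start, locus.end - win_start)
        seq = window
    else:
        seq = revcomp(window)
        mature = (win_end - locus.end, win_end - locus.start)
    return PrecursorCandidate(locus=locus, sequence=seq, mature=mature)


def expected_star(
    structure: str, mature: tuple[int, int], *, overhang: int = 2
) -> tuple[int, int] | None:
    """Expected star interval from the duplex, with a 2-nt 3' overhang.

    Returns a 0-based half-open interval, or None when the mature arm forms
    no duplex.  Unpaired terminal mature bases are handled by scanning
    inward to the nearest paired position and restoring the offset.
    """
    pt = pair_table(structure)
    m0, m1 = mature

    def partner_from(pos: int, step: int, bound: int) -> tuple[int, int] | None:
        offset = 0
        p = pos
        while (p < bound if step > 0 else p >= bound):
            if 0 <= p < len(pt) and pt[p] >= 0:
                return pt[p], offset
            p += step
            offset += 1
        return None

    # star 5' end pairs the mature position 2 nt in from the mature 3' end
    res5 = partner_from(m1 - 1 - overhang, -1, m0)
    # star 3' end is `overhang` nt past the partner of the mature 5' end
    res3 = partner_from(m0, +1, m1)
    if res5 is None or res3 is None:
        return None
    star5 = res5[0] - res5[1]
    star3 = res3[0] + res3[1] + overhang  # inclusive
    if star3 < star5:
        return None
    star5 = max(0, star5)
    star3 = min(len(structure) - 1, star3)
    return star5, star3 + 1


def detect_star(
    tags_with_loci: Iterable[tuple[SequenceTag, tuple[int, int]]],
    candidate: PrecursorCandidate,
    *,
    tolerance: int = 2,
) -> tuple[SequenceTag, tuple[int, int]] | None:
    """Star evidence: a tag whose precursor-coordinate interval matches the
    expected star interval within +/-``tolerance`` nt at both ends.

    ``tags_with_loci`` yields (tag, (start, end)) in precursor coordinates.
    Returns (tag, interval) or None (also None when the mature arm has no
    duplex).
    """
    if candidate.structure is None:
        raise ValueError("candidate must be folded before star detection")
    exp = expected_star(candidate.structure, candidate.mature)
    if exp is None:
        return None
    s0, s1 = exp
    for tag, (t0, t1) in tags_with_loci:
        if abs(t0 - s0) <= tolerance and abs(t1 - s1) <= tolerance:
            return tag, (t0, t1)
    return None
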