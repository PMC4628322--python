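"""Novel miRNA prediction from unannotated tags by hairpin folding and screening.

A candidate precursor passes the screen when it folds into a single-loop
hairpin whose mature/star duplex has at least 16 paired positions, the two
arms differ by at most 4 nt in length, the MFEI exceeds 0.85, and the
precursor length falls in a configured range.  All thresholds are knobs on
:class:`ScreenThresholds`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

from .annotate import (
    PrecursorCandidate,
    expected_star,
    map_exact,
    recover_precursor,
)
from .folding import (
    FoldingEngine,
    count_hairpin_loops,
    fold as fold_engine,
    gc_fraction,
    mfei as mfei_index,
    pair_table,
)
from .preprocess import SequenceTag


@dataclass(frozen=True)
class ScreenThresholds:
    min_pairs: int = 16          # duplex pairs required (>= by default; see strict_pairs)
    strict_pairs: bool = False   # True reads the rule as strictly > min_pairs
    max_size_diff: int = 4       # |len(mature) - len(star)| cap, nt
    min_mfei: float = 0.85       # strict inequality: mfei must exceed this
    len_range: tuple[int, int] = (70, 300)


@dataclass
class ScreenVerdict:
    candidate_id: str
    passed: bool
    failures: list[str] = field(default_factory=list)
    metrics: dict[str, float] = field(default_factory=dict)


def fold_candidate(
    candidate: PrecursorCandidate, engine: FoldingEngine | None = None
) -> PrecursorCandidate:
    """Fold the candidate and fill structure, MFE, GC, MFEI and duplex stats."""
    structure, mfe = fold_engine(candidate.sequence, engine)
    gc = gc_fraction(candidate.sequence)
    candidate.structure = structure
    candidate.mfe = mfe
    candidate.gc = gc
    candidate.mfei = mfei_index(mfe, len(candidate.sequence), gc) if 0 < gc < 1 else 0.0
    candidate.engine = getattr(engine, "name", "viennarna")
    paired, diff, _loops = duplex_stats(candidate)
    candidate.paired_in_duplex = paired
    candidate.arm_size_diff = diff
    candidate.star = expected_star(structure, candidate.mature)
    return candidate


def duplex_stats(candidate: PrecursorCandidate) -> tuple[int, int, int]:
    """(paired_in_duplex, arm_size_diff, n_loops) for a folded candidate.

    ``paired_in_duplex`` counts mature-arm positions paired with a position
    outside the mature arm; ``arm_size_diff`` compares mature and inferred
    star lengths (0 when no star can be inferred alongside a 0 pair count).
    """
    if candidate.structure is None:
        raise ValueError("candidate must be folded first")
    m0, m1 = candidate.mature
    if m1 > len(candidate.structure):
        raise ValueError("mature arm outside structure")
    pt = pair_table(candidate.structure)
    paired = sum(1 for i in range(m0, m1) if pt[i] >= 0 and not (m0 <= pt[i] < m1))
    star = expected_star(candidate.structure, candidate.mature)
    if star is None:
        diff = len(candidate.sequence)  # sentinel: no duplex at all
    else:
        diff = abs((m1 - m0) - (star[1] - star[0]))
    loops = count_hairpin_loops(candidate.structure)
    return paired, diff, loops


def screen_candidate(
    candidate: PrecursorCandidate,
    thresholds: ScreenThresholds = ScreenThresholds(),
    candidate_id: str | None = None,
) -> ScreenVerdict:
    """Apply the hairpin screen; every failure names its measured value."""
    paired, diff, loops = duplex_stats(candidate)
    length = len(candidate.sequence)
    mfei_val = candidate.mfei if candidate.mfei is not None else 0.0
    failures: list[str] = []
    if loops != 1:
        failures.append(f"not_hairpin(n_loops={loops})")
    min_required = thresholds.min_pairs + (1 if thresholds.strict_pairs else 0)
    if paired < min_required:
        failures.append(f"duplex_pairs_lt_16(paired={paired})")
    if diff > thresholds.max_size_diff:
        failures.append(f"size_diff_gt_4(diff={diff})")
    if not mfei_val > thresholds.min_mfei:
        failures.append(f"mfei_le_0.85(mfei={mfei_val:.3f})")
    lo, hi = thresholds.len_range
    if not lo <= length <= hi:
        failures.append(f"length_out_of_range(length={length})")
    return ScreenVerdict(
        candidate_id=candidate_id or f"{candidate.locus.ref}:{candidate.locus.start}",
        passed=not failures,
        failures=failures,
        metrics={
            "paired_in_duplex": paired,
            "arm_size_diff": diff,
            "n_loops": loops,
            "mfe": candidate.mfe or 0.0,
            "gc": candidate.gc or 0.0,
            "mfei": mfei_val,
            "length": length,
        },
    )


def trim_to_hairpin(
    candidate: PrecursorCandidate,
    engine: FoldingEngine | None = None,
    *,
    pad: int = 10,
) -> PrecursorCandidate | None:
    """Trim a folded flanking window down to the mature/star hairpin + pad.

    Extraction windows (mature +/- 150 nt) are much longer than genuine
    precursors, so the window is folded once, the star arm located, the
    sequence cut to the span of both arms plus ``pad`` nt, and the cut
    refolded.  Returns None when the mature arm pairs nowhere.
    """
    if candidate.structure is None:
        candidate = fold_candidate(candidate, engine)
    star = expected_star(candidate.structure, candidate.mature)
    if star is None:
        return None
    m0, m1 = candidate.mature
    lo = max(0, min(m0, star[0]) - pad)
    hi = min(len(candidate.sequence), max(m1, star[1]) + pad)
    trimmed = PrecursorCandidate(
        locus=candidate.locus,
        sequence=candidate.sequence[lo:hi],
        mature=(m0 - lo, m1 - lo),
    )
    return fold_candidate(trimmed, engine)


def _arm_suffix(candidate: PrecursorCandidate) -> str:
    """'-5p' when the mature arm lies 5' of the hairpin loop, else '-3p'."""
    if candidate.structure is None:
        return "-5p"
    m0, m1 = candidate.mature
    mid = (m0 + m1) / 2
    pt = pair_table(candidate.structure)
    paired_idx = [i for i in range(len(pt)) if pt[i] >= 0]
    if not paired_idx:
        return "-5p"
    # loop centre: midpoint between the innermost pair
    inner_open = max(i for i in paired_idx if pt[i] > i)
    loop_mid = (inner_open + pt[inner_open]) / 2
    return "-5p" if mid < loop_mid else "-3p"


@dataclass
class NovelMiRNA:
    name: str
    mature_sequence: str
    candidate: PrecursorCandidate
    verdict: ScreenVerdict


def discover_novel(
    tags: Sequence[SequenceTag],
    genome: Mapping[str, str],
    thresholds: ScreenThresholds = ScreenThresholds(),
    *,
    flank: int = 150,
    engine: FoldingEngine | None = None,
    max_loci: int = 20,
    merge_slop: int = 5,
    name_prefix: str = "ghr-m",
) -> tuple[list[NovelMiRNA], list[ScreenVerdict]]:
    """Fold and screen every exact genomic locus of every unannotated tag.

    Passing candidates are named ``ghr-mNNNN-5p/3p`` by arm; candidates whose
    trimmed precursor intervals coincide within ``merge_slop`` nt are merged,
    keeping the lowest-MFEI... highest-scoring (lowest MFE) representative.
    Returns (novel miRNAs, all verdicts including failures).
    """
    verdicts: list[ScreenVerdict] = []
    accepted: list[NovelMiRNA] = []
    seen_intervals: list[tuple[str, int, int]] = []
    serial = 0
    for tag in tags:
        if tag.annotation != "unannotated":
            continue
        for locus in map_exact(tag.sequence, genome, max_loci=max_loci):
            window = recover_precursor(locus, genome, flank=flank)
            window = fold_candidate(window, engine)
            trimmed = trim_to_hairpin(window, engine)
            cid = f"{locus.ref}:{locus.start}-{locus.end}({locus.strand})"
            if trimmed is None:
                verdicts.append(
                    ScreenVerdict(cid, False, ["not_hairpin(no_duplex)"], {})
                )
                continue
            verdict = screen_candidate(trimmed, thresholds, candidate_id=cid)
            verdicts.append(verdict)
            if not verdict.passed:
                continue
            if locus.strand == "+":
                g0 = locus.start - trimmed.mature[0]  # genomic precursor start
                g1 = g0 + len(trimmed.sequence)
            else:
                g1 = locus.end + trimmed.mature[0]
                g0 = g1 - len(trimmed.sequence)
            key_hit = False
            for ref, s, e in seen_intervals:
                if ref == locus.ref and abs(s - g0) <= merge_slop and abs(e - g1) <= merge_slop:
                    key_hit = True
                    break
            if key_hit:
                continue
            seen_intervals.append((locus.ref, g0, g1))
            serial += 1
            name = f"{name_prefix}{serial:04d}{_arm_suffix(trimmed)}"
            trimmed.name = name
            tag.annotation = "novel_miRNA"
            tag.annotation_detail = name
            accepted.append(
                NovelMiRNA(
                    name=name,
                    mature_sequence=tag.sequence,
                    candidate=trimmed,
                    verdict=verdict,
                )
            )
    return accepted, verdicts


def relax(thresholds: ScreenThresholds, **changes) -> ScreenThresholds:
    """Convenience for threshold sweeps in monotonicity checks."""
    return replace(thresholds, **changes)


def write_novel(novel: Sequence[NovelMiRNA], prefix) -> None:
    """Novel miRNAs as mature FASTA, precursor GFF3 (1-based inclusive) and
    Vienna-style dot-bracket structure file."""
    from pathlib import Path

    prefix = Path(prefix)
    with open(prefix.with_suffix(".fa"), "w") as fh:
        for n in novel:
            fh.write(f">{n.name}\n{n.mature_sequence}\n")
    with open(prefix.with_suffix(".gff3"), "w") as fh:
        fh.write("##gff-version 3\n")
        for n in novel:
            loc = n.candidate.locus
            m0, m1 = n.candidate.mature
            if loc.strand == "+":
                p0 = loc.start - m0
                p1 = p0 + len(n.candidate.sequence)
            else:
                p1 = loc.end + m0
                p0 = p1 - len(n.candidate.sequence)
            fh.write(
                f"{loc.ref}\tapexmir\tmiRNA_primary_transcript\t{p0 + 1}\t{p1}\t.\t"
                f"{loc.strand}\t.\tID={n.name}_precursor\n"
            )
            fh.write(
                f"{loc.ref}\tapexmir\tmiRNA\t{loc.start + 1}\t{loc.end}\t.\t"
                f"{loc.strand}\t.\tID={n.name};Derives_from={n.name}_precursor\n"
            )
    with open(prefix.with_suffix(".str"), "w") as fh:
        for n in novel:
            c = n.candidate
            fh.write(f">{n.name}\n{c.sequence}\n{c.structure} ({c.mfe:.2f})\n")
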