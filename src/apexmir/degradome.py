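"""Degradome (PARE) evidence for miRNA-guided cleavage.

Degradome tags are 5' ends of uncapped mRNA fragments; a miRNA-guided cut
leaves a pile-up of tag 5' ends at the transcript position opposite miRNA
position 10.  Validation PAREsnip-style: a candidate duplex (penalty <= 4.0
on the target-prediction scale) whose cleavage position carries signal is
scored against a null of dinucleotide-shuffled miRNAs; the empirical
p-value uses add-one smoothing and the hit is reported at p <= 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from ._seq import iter_fastq, to_dna, to_rna
from .targets import TargetInteraction, _encode, _window_penalties, find_targets


@dataclass
class DegradomeProfile:
    transcript_id: str
    counts: np.ndarray  # per-position tag 5'-end counts, index 0 = position 1
    multi_mapped: int = 0  # tags that also matched other transcripts

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class DegradomeHit:
    interaction: TargetInteraction
    cleavage_position: int  # 1-based transcript coordinate
    peak_count: int
    category: int
    shuffle_p: float
    n_shuffles: int


def build_profile(
    degradome: str | Path | Iterable[str],
    transcripts: Mapping[str, str],
    *,
    min_tag_len: int = 15,
) -> dict[str, DegradomeProfile]:
    """Exact sense-strand matching of degradome tags onto transcripts.

    ``degradome`` is a FASTQ path or an iterable of tag sequences.  Every
    exact match start increments that transcript's profile; tags hitting
    more than one transcript increment each and are counted in
    ``multi_mapped``.
    """
    if isinstance(degradome, (str, Path)):
        tags: Iterable[str] = (seq for _n, seq in iter_fastq(degradome))
    else:
        tags = degradome
    t_seqs = {tid: to_dna(seq) for tid, seq in transcripts.items()}
    profiles = {
        tid: DegradomeProfile(tid, np.zeros(len(seq), dtype=np.int64))
        for tid, seq in t_seqs.items()
    }
    for tag in tags:
        tag = to_dna(tag)
        if len(tag) < min_tag_len:
            continue
        hits: list[tuple[str, int]] = []
        for tid, seq in t_seqs.items():
            start = seq.find(tag)
            while start >= 0:
                hits.append((tid, start))
                start = seq.find(tag, start + 1)
        n_transcripts_hit = len({tid for tid, _ in hits})
        for tid, start in hits:
            profiles[tid].counts[start] += 1
            if n_transcripts_hit > 1:
                profiles[tid].multi_mapped += 1
    return profiles


def peak_category(profile: DegradomeProfile, position: int) -> int | None:
    """Five-category PARE peak classification at a 1-based position.

    0: unique transcript maximum with count > 1; 1: tied maximum, > 1;
    2: above the mean of occupied positions, not a maximum; 3: <= mean,
    > 1; 4: count == 1.  Returns None for a zero count (no evidence).
    """
    counts = profile.counts
    if not 1 <= position <= len(counts):
        raise ValueError("position outside transcript")
    c = int(counts[position - 1])
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


def dinucleotide_shuffle(sequence: str, rng: np.random.Generator) -> str:
    """Altschul-Erickson shuffle preserving the dinucleotide multiset.

    Builds the transition multigraph of the sequence and samples a random
    Eulerian path with the original first and last residues, so every draw
    has exactly the input's dinucleotide (and hence mononucleotide) counts.
    """
    s = to_dna(sequence)
    n = len(s)
    if n < 3:
        return sequence
    edges: dict[str, list[str]] = {}
    for a, b in zip(s, s[1:]):
        edges.setdefault(a, []).append(b)
    vertices = sorted(edges.keys() | set(s))
    last = s[-1]
    for _attempt in range(1000):
        # pick a candidate terminal edge per non-terminal vertex
        last_edge: dict[str, str] = {}
        for v in vertices:
            if v == last or not edges.get(v):
                continue
            last_edge[v] = edges[v][rng.integers(len(edges[v]))]
        # the chosen terminal edges must form a tree rooted at `last`
        ok = True
        for v in last_edge:
            seen = {v}
            cur = v
            while cur != last:
                nxt = last_edge.get(cur)
                if nxt is None or nxt in seen:
                    ok = False
                    break
                seen.add(nxt)
                cur = nxt
            if not ok:
                break
        if not ok:
            continue
        shuffled_adj: dict[str, list[str]] = {}
        for v, targets in edges.items():
            rest = list(targets)
            if v in last_edge:
                rest.remove(last_edge[v])
            rng.shuffle(rest)
            if v in last_edge:
                rest.append(last_edge[v])
            shuffled_adj[v] = rest
        out: list[str] = [s[0]]
        cur = s[0]
        idx = {v: 0 for v in shuffled_adj}
        for _ in range(n - 1):
            nxt = shuffled_adj[cur][idx[cur]]
            idx[cur] += 1
            out.append(nxt)
            cur = nxt
        result = "".join(out)
        if "U" in sequence.upper():
            result = to_rna(result)
        return result
    raise RuntimeError("dinucleotide shuffle failed to find an Eulerian path")


def _best_peak_sites(
    mirna: str,
    transcript: str,
    counts: np.ndarray,
    max_penalty: float,
    *,
    max_bulge: int = 2,
) -> list[tuple[int, int, float, int]]:
    """(start, site_len, penalty, peak count) for every candidate site whose
    cleavage position (opposite miRNA position 10) has a nonzero count."""
    m = _encode(to_rna(mirna))
    t = _encode(to_rna(transcript))
    lm = len(m)
    out = []
    for site_len in range(max(18, lm - max_bulge), min(26, lm + max_bulge) + 1):
        pens = _window_penalties(m, t, site_len)
        for start in np.nonzero(pens <= max_penalty)[0]:
            pos0 = int(start) + site_len - 10  # pairs miRNA position 10
            if 0 <= pos0 < len(counts) and counts[pos0] > 0:
                out.append((int(start), site_len, float(pens[start]), int(counts[pos0])))
    return out


def validate_interaction(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    profiles: Mapping[str, DegradomeProfile],
    *,
    max_penalty: float = 4.0,
    n_shuffles: int = 100,
    alpha: float = 0.05,
    seed: int = 0,
) -> DegradomeHit | str:
    """Validate one miRNA/transcript pair against the degradome.

    Finds duplex sites under the penalty cap whose cleavage position carries
    degradome signal, keeps the strongest (highest peak, then lowest
    penalty), and computes a dinucleotide-shuffle p-value: the fraction of
    shuffled miRNAs achieving an equally supported site, with add-one
    smoothing p = (k+1)/(n+1).  Returns a DegradomeHit when p <= alpha,
    otherwise a rejection reason string.
    """
    if transcript_id not in profiles:
        return f"rejected: transcript {transcript_id!r} absent from degradome profile"
    if not 18 <= len(mirna) <= 26:
        raise ValueError("miRNA length outside [18, 26]")
    counts = profiles[transcript_id].counts
    sites = _best_peak_sites(mirna, transcript, counts, max_penalty)
    if not sites:
        return "rejected: no duplex under the penalty cap with cleavage signal"
    start, site_len, _pen, peak = max(sites, key=lambda s: (s[3], -s[2]))
    rng = np.random.default_rng(seed)
    k = 0
    for _ in range(n_shuffles):
        shuf = dinucleotide_shuffle(mirna, rng)
        null_sites = _best_peak_sites(shuf, transcript, counts, max_penalty)
        if any(c >= peak for _s, _l, _p, c in null_sites):
            k += 1
    p = (k + 1) / (n_shuffles + 1)
    if p > alpha:
        return f"rejected: shuffle p = {p:.4f} > {alpha}"
    from .targets import classify_mode, score_duplex

    penalty, aln = score_duplex(mirna, transcript[start : start + site_len])
    interaction = TargetInteraction(
        mirna_id=mirna_id, transcript_id=transcript_id,
        start=start, end=start + site_len, penalty=penalty, alignment=aln,
    )
    classify_mode(interaction)
    cleavage_pos = start + site_len - 9  # 1-based, opposite miRNA position 10
    return DegradomeHit(
        interaction=interaction,
        cleavage_position=cleavage_pos,
        peak_count=peak,
        category=peak_category(profiles[transcript_id], cleavage_pos),
        shuffle_p=p,
        n_shuffles=n_shuffles,
    )


def compare_contrasts(
    hits_a: Iterable[tuple[str, str, str]],
    hits_b: Iterable[tuple[str, str, str]],
    *,
    label_a: str = "A1-A9",
    label_b: str = "A3-A9",
) -> dict[tuple[str, str], str]:
    """Join validated interactions across two contrasts.

    Each hit is (miRNA family, transcript id, de_flag).  Pairs present in
    both contrasts are 'concordant' (same direction), 'opposite' (up in one,
    down in the other) or 'mixed' (a non-significant side); pairs in one
    contrast only are 'exclusive:<label>'.
    """
    a = {(fam, tid): flag for fam, tid, flag in hits_a}
    b = {(fam, tid): flag for fam, tid, flag in hits_b}
    out: dict[tuple[str, str], str] = {}
    for key in sorted(a.keys() | b.keys()):
        if key in a and key in b:
            fa, fb = a[key], b[key]
            if {fa, fb} == {"up", "down"}:
                out[key] = "opposite"
            elif fa == fb and fa in ("up", "down"):
                out[key] = "concordant"
            else:
                out[key] = "mixed"
        elif key in a:
            out[key] = f"exclusive:{label_a}"
        else:
            out[key] = f"exclusive:{label_b}"
    return out
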