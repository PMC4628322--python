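"""Plant miRNA target prediction by complementarity penalty scoring.

The duplex is scored 5'->3' of the miRNA against 3'->5' of the target site:
each mismatch costs 1, each G:U wobble 0.5, each bulged nucleotide 2, and
penalties falling in miRNA positions 2-13 (the seed-plus-central region that
plant cleavage requires) are doubled.  A site is reported when its minimum
penalty over all alignments with at most one bulge (of <= 2 nt, on either
strand) stays at or below the cutoff, 4.0 by default.  Regulation mode is
read off the duplex centre: cleavage needs Watson-Crick pairing at miRNA
positions 9-11, anything else is scored as translational repression.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from ._seq import to_rna

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3, "T": 3}
# pair cost by (miRNA base, site base): WC 0, G:U wobble 0.5, mismatch 1
_PAIR_COST = np.ones((4, 4))
for _a, _b in ((0, 3), (3, 0), (2, 1), (1, 2)):
    _PAIR_COST[_a, _b] = 0.0
for _a, _b in ((2, 3), (3, 2)):
    _PAIR_COST[_a, _b] = 0.5

_MIN_LEN, _MAX_LEN = 18, 26
_CORE = (2, 13)  # 1-based miRNA positions whose penalties double


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_CODE[c] for c in seq.upper()], dtype=np.int8)
    except KeyError as exc:
        raise ValueError(f"illegal nucleotide {exc.args[0]!r}") from None


def _weight(position: int) -> float:
    """Doubling weight for a 1-based miRNA position."""
    return 2.0 if _CORE[0] <= position <= _CORE[1] else 1.0


@dataclass
class DuplexAlignment:
    """One scored miRNA/site alignment.

    ``pair_status`` holds, per 1-based miRNA position, one of 'WC', 'GU',
    'MM' or 'bulge' (a bulged miRNA base).  Site-side bulges are kept in
    ``site_bulges`` as (miRNA position they precede, length).
    """

    mirna: str
    site: str
    penalty: float
    pair_status: list[str]
    site_bulges: list[tuple[int, int]]

    def text(self) -> str:
        """Three-line rendering: miRNA 5'->3', bonds, site 3'->5'."""
        m, s = to_rna(self.mirna), to_rna(self.site)[::-1]
        bonds = []
        mi = si = 0
        mline, sline = [], []
        bulge_at = dict(self.site_bulges)
        while mi < len(m) or si < len(s):
            if (mi + 1) in bulge_at and bulge_at.get(mi + 1):
                g = bulge_at.pop(mi + 1)
                mline.append("-" * g)
                sline.append(s[si : si + g])
                bonds.append(" " * g)
                si += g
                continue
            if mi < len(m) and self.pair_status[mi] == "bulge":
                mline.append(m[mi])
                sline.append("-")
                bonds.append(" ")
                mi += 1
                continue
            if mi >= len(m) or si >= len(s):
                break
            mline.append(m[mi])
            sline.append(s[si])
            bonds.append({"WC": "|", "GU": "o", "MM": " "}[self.pair_status[mi]])
            mi += 1
            si += 1
        return (
            f"miR 5' {''.join(mline)} 3'\n"
            f"       {''.join(bonds)}\n"
            f"tgt 3' {''.join(sline)} 5'"
        )


def _score_alignment(
    m: np.ndarray, s_rev: np.ndarray, bulge_side: str, gap_pos: int, gap_len: int
) -> tuple[float, list[str], list[tuple[int, int]]]:
    """Penalty of one fixed alignment; bulge of gap_len after aligned prefix gap_pos."""
    status: list[str] = []
    site_bulges: list[tuple[int, int]] = []
    penalty = 0.0
    mi = si = 0
    n_m, n_s = len(m), len(s_rev)
    while mi < n_m:
        if bulge_side == "mirna" and mi == gap_pos and gap_len:
            for k in range(gap_len):
                penalty += 2.0 * _weight(mi + 1 + k)
                status.append("bulge")
            mi += gap_len
            gap_len = 0
            continue
        if bulge_side == "site" and mi == gap_pos and gap_len:
            penalty += 2.0 * gap_len * _weight(min(mi + 1, n_m))
            site_bulges.append((mi + 1, gap_len))
            si += gap_len
            gap_len = 0
            continue
        if si >= n_s:
            penalty += _weight(mi + 1)  # dangling miRNA base scored as mismatch
            status.append("MM")
            mi += 1
            continue
        cost = _PAIR_COST[m[mi], s_rev[si]]
        penalty += cost * _weight(mi + 1)
        status.append("WC" if cost == 0 else ("GU" if cost == 0.5 else "MM"))
        mi += 1
        si += 1
    if bulge_side == "site" and gap_len and gap_pos == n_m:
        # site bulge past the miRNA 3' end
        penalty += 2.0 * gap_len * _weight(n_m)
        site_bulges.append((n_m + 1, gap_len))
    return penalty, status, site_bulges


def score_duplex(mirna: str, site: str) -> tuple[float, DuplexAlignment]:
    """Minimum penalty over all <=1-bulge alignments of a miRNA and a site.

    Both sequences are given 5'->3'; the site is a transcript subsequence.
    Lengths must lie in [18, 26] and differ by at most 2 (the bulge cap).
    """
    for name, seq in (("miRNA", mirna), ("site", site)):
        if not _MIN_LEN <= len(seq) <= _MAX_LEN:
            raise ValueError(f"{name} length {len(seq)} outside [{_MIN_LEN}, {_MAX_LEN}]")
    m = _encode(to_rna(mirna))
    s_rev = _encode(to_rna(site))[::-1]
    diff = len(s_rev) - len(m)
    if abs(diff) > 2:
        raise ValueError("site and miRNA lengths differ by more than the 2-nt bulge cap")
    if diff == 0:
        combos = [("none", 0, 0)]
    elif diff > 0:  # site longer: bulge on the site strand
        combos = [("site", p, diff) for p in range(len(m) + 1)]
    else:  # miRNA longer: bulged miRNA bases
        combos = [("mirna", p, -diff) for p in range(len(m) + 1 + diff)]
    best: tuple[float, list[str], list[tuple[int, int]]] | None = None
    for side, pos, g in combos:
        res = _score_alignment(m, s_rev, side, pos, g)
        if best is None or res[0] < best[0]:
            best = res
    penalty, status, site_bulges = best
    return penalty, DuplexAlignment(
        mirna=to_rna(mirna), site=to_rna(site), penalty=penalty,
        pair_status=status, site_bulges=site_bulges,
    )


@dataclass
class TargetInteraction:
    mirna_id: str
    transcript_id: str
    start: int  # 0-based half-open on the transcript
    end: int
    penalty: float
    alignment: DuplexAlignment
    mode: str | None = None
    correlation: str | None = None

    @property
    def cleavage_position(self) -> int:
        """1-based transcript coordinate opposite miRNA position 10."""
        return self.start + (self.end - self.start) - 9


def _window_penalties(m: np.ndarray, t: np.ndarray, site_len: int) -> np.ndarray:
    """Vectorised minimum penalty for every window of one site length."""
    n_windows = len(t) - site_len + 1
    if n_windows <= 0:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(t, site_len)[:, ::-1]
    lm = len(m)
    diff = site_len - lm
    weights = np.array([_weight(i + 1) for i in range(lm)])
    if diff == 0:
        cost = _PAIR_COST[m[None, :], windows] * weights[None, :]
        return cost.sum(axis=1)
    best = np.full(n_windows, np.inf)
    if diff > 0:  # site bulge of length diff after miRNA prefix p
        for p in range(lm + 1):
            cost = np.zeros(n_windows)
            if p:
                cost += (_PAIR_COST[m[None, :p], windows[:, :p]] * weights[None, :p]).sum(axis=1)
            cost += 2.0 * diff * _weight(min(p + 1, lm))
            if p < lm:
                cost += (
                    _PAIR_COST[m[None, p:], windows[:, p + diff :]] * weights[None, p:]
                ).sum(axis=1)
            np.minimum(best, cost, out=best)
    else:  # miRNA bulge of length -diff after prefix p
        g = -diff
        for p in range(lm + 1 + diff):
            cost = np.zeros(n_windows)
            if p:
                cost += (_PAIR_COST[m[None, :p], windows[:, :p]] * weights[None, :p]).sum(axis=1)
            cost += 2.0 * sum(_weight(p + 1 + k) for k in range(g))
            rest = lm - p - g
            if rest:
                cost += (
                    _PAIR_COST[m[None, p + g :], windows[:, p:]] * weights[None, p + g :]
                ).sum(axis=1)
            np.minimum(best, cost, out=best)
    return best


def find_targets(
    mirna_id: str,
    mirna: str,
    transcripts: Mapping[str, str],
    cutoff: float = 4.0,
    *,
    max_bulge: int = 2,
) -> list[TargetInteraction]:
    """Scan every transcript window for sites with penalty <= cutoff.

    Overlapping sites of one miRNA on one transcript merge to the lowest
    penalty (ties: leftmost, then shortest).  Output order is deterministic:
    (transcript id, site start).
    """
    if not transcripts:
        raise ValueError("transcript set must be non-empty")
    m = _encode(to_rna(mirna))
    lm = len(m)
    hits: list[TargetInteraction] = []
    for tid in sorted(transcripts):
        t = _encode(to_rna(transcripts[tid]))
        raw: list[tuple[int, int, float]] = []
        for site_len in range(max(_MIN_LEN, lm - max_bulge), min(_MAX_LEN, lm + max_bulge) + 1):
            pens = _window_penalties(m, t, site_len)
            for start in np.nonzero(pens <= cutoff)[0]:
                raw.append((int(start), site_len, float(pens[start])))
        raw.sort(key=lambda r: (r[2], r[0], r[1]))
        chosen: list[tuple[int, int, float]] = []
        for start, slen, pen in raw:
            if any(start < c0 + cl and c0 < start + slen for c0, cl, _ in chosen):
                continue  # overlaps an already-kept (better) site
            chosen.append((start, slen, pen))
        for start, slen, pen in sorted(chosen):
            site = transcripts[tid][start : start + slen]
            penalty, aln = score_duplex(mirna, site)
            hits.append(
                TargetInteraction(
                    mirna_id=mirna_id, transcript_id=tid,
                    start=start, end=start + slen,
                    penalty=penalty, alignment=aln,
                )
            )
    return hits


def classify_mode(
    interaction: TargetInteraction, *, center: tuple[int, int] = (9, 11)
) -> str:
    """'cleavage' when miRNA positions 9-11 are all Watson-Crick paired,
    otherwise 'translational_repression'."""
    status = interaction.alignment.pair_status
    lo, hi = center
    ok = all(
        lo <= pos <= hi and status[pos - 1] == "WC" or not (lo <= pos <= hi)
        for pos in range(1, len(status) + 1)
    )
    # site bulge falling inside the centre also breaks cleavage
    for pos, _g in interaction.alignment.site_bulges:
        if lo < pos <= hi:
            ok = False
    interaction.mode = "cleavage" if ok else "translational_repression"
    return interaction.mode
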