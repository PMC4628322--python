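"""Count normalisation, fold changes, count-based significance and DE calls.

The workflow matches single-library-per-genotype sRNA studies: counts are
normalised to reads per million (RPM), zeros are floored at 0.01 so ratios
stay finite, fold changes are log2(mutant/wild), and significance comes from
the Audic-Claverie count test in its conditional-binomial form.  DE calls
use |log2FC| >= 1 with p <= 0.05 for miRNAs, or FDR <= 0.001 (Benjamini-
Hochberg) for transcripts.  Also provides miRNA/target correlation classes
and the 2^-ddCt qPCR quantity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.stats import binom

GENOTYPES = ("A1", "A3", "A9")
CONTRASTS = ("A1-A9", "A3-A9")


@dataclass
class ExpressionRecord:
    feature: str
    rpm: dict[str, float] = field(default_factory=dict)
    log2fc: dict[str, float] = field(default_factory=dict)
    pvalue: dict[str, float] = field(default_factory=dict)
    fdr: dict[str, float] = field(default_factory=dict)
    de_flag: dict[str, str] = field(default_factory=dict)


def rpm(count: float, library_total: float) -> float:
    """Reads per million: count / total x 10^6."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    if not 0 <= count <= library_total:
        raise ValueError("count must lie in [0, library_total]")
    return count / library_total * 1e6


def substitute_zero(rpm_value: float, floor: float = 0.01) -> float:
    """Replace an RPM of exactly 0 by a small floor so log-ratios exist."""
    if rpm_value < 0:
        raise ValueError("rpm must be non-negative")
    return floor if rpm_value == 0 else rpm_value


def log2fc(rpm_mutant: float, rpm_wild: float) -> float:
    """log2(mutant/wild); zero substitution must already have run."""
    if rpm_mutant <= 0 or rpm_wild <= 0:
        raise ValueError("inputs must be positive (apply substitute_zero first)")
    # difference of logs rather than log of ratio: antisymmetry is then exact
    return math.log2(rpm_mutant) - math.log2(rpm_wild)


def count_test_p(x: int, y: int, n1: float, n2: float) -> float:
    """Two-sided Audic-Claverie count test between two libraries.

    Conditional form: given t = x + y, under the null of equal per-read
    rates y ~ Binomial(t, N2/(N1+N2)); the two-sided p is twice the smaller
    tail, capped at 1.  This form is exactly exchange-symmetric:
    p(x, y, N1, N2) == p(y, x, N2, N1).
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("library totals must be positive")
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    t = x + y
    if t == 0:
        return 1.0
    pi = n2 / (n1 + n2)
    lower = binom.cdf(y, t, pi)
    upper = binom.sf(y - 1, t, pi)
    return float(min(1.0, 2.0 * min(lower, upper)))


def bh_fdr(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_de(
    record: ExpressionRecord,
    contrast: str,
    mode: str = "miRNA",
    *,
    min_abs_log2fc: float = 1.0,
    max_p: float = 0.05,
    max_fdr: float = 0.001,
) -> str:
    """'up' / 'down' / 'ns' for one contrast.

    miRNA mode gates on the raw count-test p; transcript mode on BH FDR.
    Boundaries are inclusive.
    """
    lfc = record.log2fc.get(contrast)
    if lfc is None:
        raise ValueError(f"record lacks log2fc for {contrast}")
    if mode == "miRNA":
        stat = record.pvalue.get(contrast)
        cut = max_p
    elif mode == "transcript":
        stat = record.fdr.get(contrast)
        cut = max_fdr
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if stat is None:
        raise ValueError(f"record lacks significance statistic for {contrast}")
    if stat <= cut and lfc >= min_abs_log2fc:
        return "up"
    if stat <= cut and lfc <= -min_abs_log2fc:
        return "down"
    return "ns"


def correlate_pairs(
    mirna: ExpressionRecord, target: ExpressionRecord, contrast: str
) -> str:
    """'anti' (opposite directions), 'positive' (same), 'none' (either ns)."""
    a = mirna.de_flag.get(contrast)
    b = target.de_flag.get(contrast)
    if a is None or b is None:
        raise ValueError("both records need a de_flag for the contrast")
    if "ns" in (a, b):
        return "none"
    return "positive" if a == b else "anti"


def qpcr_relative(
    ct_target_test: float,
    ct_ref_test: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
) -> float:
    """Relative expression 2^-ddCt with ddCt = dCt(test) - dCt(control)."""
    ddct = (ct_target_test - ct_ref_test) - (ct_target_ctrl - ct_ref_ctrl)
    return 2.0 ** (-ddct)


def build_expression_table(
    counts: Mapping[str, Mapping[str, int]],
    library_totals: Mapping[str, float],
    *,
    contrasts: Sequence[tuple[str, str, str]] = (("A1-A9", "A1", "A9"), ("A3-A9", "A3", "A9")),
    floor: float = 0.01,
    mode: str = "miRNA",
) -> dict[str, ExpressionRecord]:
    """Full per-feature expression records from a count matrix.

    ``counts`` maps feature -> {library: count}; ``contrasts`` are
    (label, mutant library, wild-type library) triples.  FDR is computed per
    contrast across all features (BH), regardless of mode, so transcript
    calls can gate on it.
    """
    records: dict[str, ExpressionRecord] = {}
    libs = list(library_totals)
    for feat, per_lib in counts.items():
        rec = ExpressionRecord(feature=feat)
        for lib in libs:
            rec.rpm[lib] = rpm(per_lib.get(lib, 0), library_totals[lib])
        records[feat] = rec
    for label, mut, wt in contrasts:
        pvals = []
        feats = list(records)
        for feat in feats:
            rec = records[feat]
            a = substitute_zero(rec.rpm[mut], floor)
            b = substitute_zero(rec.rpm[wt], floor)
            rec.log2fc[label] = log2fc(a, b)
            rec.pvalue[label] = count_test_p(
                counts[feat].get(mut, 0), counts[feat].get(wt, 0),
                library_totals[mut], library_totals[wt],
            )
            pvals.append(rec.pvalue[label])
        qvals = bh_fdr(pvals)
        for feat, q in zip(feats, qvals):
            records[feat].fdr[label] = float(q)
        for feat in feats:
            records[feat].de_flag[label] = call_de(records[feat], label, mode)
    return records
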