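"""RNA secondary-structure folding behind a pluggable engine contract.

An engine maps an RNA sequence to a (dot-bracket structure, MFE kcal/mol)
pair with structure length equal to sequence length, balanced brackets and
MFE <= 0.  Two engines ship:

* :class:`ViennaFolder` — ViennaRNA's MFE folder, the default.
* :class:`SimpleFolder` — a self-contained dynamic-programming folder with a
  base-pair/stacking score, for dependency-free smoke testing.  Its energies
  are a crude surrogate and are not comparable with ViennaRNA's.

Pair tables, loop counting and the MFEI statistic live here too since they
operate on structures rather than on candidates.
"""

from __future__ import annotations

import re
from typing import Protocol

from ._seq import to_rna

_RNA_ALPHABET = set("ACGU")
_PAIRS = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G"), ("G", "U"), ("U", "G")}

_HAIRPIN_LOOP_RE = re.compile(r"\(\.*\)")


class FoldingEngine(Protocol):
    name: str

    def fold(self, sequence: str) -> tuple[str, float]: ...


def _check_sequence(seq: str) -> str:
    rna = to_rna(seq)
    bad = set(rna) - _RNA_ALPHABET
    if bad:
        raise ValueError(f"illegal characters in RNA sequence: {sorted(bad)}")
    return rna


class ViennaFolder:
    """MFE folding via the ViennaRNA python bindings."""

    name = "viennarna"

    def fold(self, sequence: str) -> tuple[str, float]:
        import RNA

        rna = _check_sequence(sequence)
        structure, mfe = RNA.fold(rna)
        return structure, min(0.0, float(mfe))


class SimpleFolder:
    """Nussinov-style DP folder with stacking bonuses.

    Scores: GC pair -3, AU pair -2, GU wobble -1, extra -1 when a pair
    stacks directly on another pair; hairpin loops shorter than 3 nt are
    forbidden.  The score is reported as a pseudo-MFE in the same (<= 0)
    direction as a thermodynamic model.
    """

    name = "simple-dp"

    _PAIR_E = {("G", "C"): -3.0, ("C", "G"): -3.0, ("A", "U"): -2.0, ("U", "A"): -2.0,
               ("G", "U"): -1.0, ("U", "G"): -1.0}
    _MIN_LOOP = 3

    def fold(self, sequence: str) -> tuple[str, float]:
        rna = _check_sequence(sequence)
        n = len(rna)
        # E[i][j]: best score of subsequence i..j; P[i][j] whether (i,j) pair in optimum
        E = [[0.0] * n for _ in range(n)]
        choice: dict[tuple[int, int], tuple] = {}
        for span in range(self._MIN_LOOP + 1, n):
            for i in range(0, n - span):
                j = i + span
                best = E[i][j - 1]
                best_c: tuple = ("unpaired", None)
                for k in range(i, j - self._MIN_LOOP):
                    e = self._PAIR_E.get((rna[k], rna[j]))
                    if e is None:
                        continue
                    stack = -1.0 if (k + 1 <= j - 1 and self._PAIR_E.get((rna[k + 1], rna[j - 1]))) else 0.0
                    left = E[i][k - 1] if k > i else 0.0
                    inner = E[k + 1][j - 1] if k + 1 <= j - 1 else 0.0
                    cand = left + e + stack + inner
                    if cand < best:
                        best = cand
                        best_c = ("pair", k)
                E[i][j] = best
                choice[(i, j)] = best_c
        structure = ["."] * n
        stack = [(0, n - 1)]
        while stack:
            i, j = stack.pop()
            if i >= j or (i, j) not in choice:
                continue
            kind, k = choice[(i, j)]
            if kind == "unpaired":
                stack.append((i, j - 1))
            else:
                structure[k], structure[j] = "(", ")"
                if k > i:
                    stack.append((i, k - 1))
                if k + 1 <= j - 1:
                    stack.append((k + 1, j - 1))
        return "".join(structure), min(0.0, E[0][n - 1])


_DEFAULT_ENGINE: FoldingEngine = ViennaFolder()


def get_engine(name: str = "viennarna") -> FoldingEngine:
    if name == "viennarna":
        return ViennaFolder()
    if name == "simple-dp":
        return SimpleFolder()
    raise ValueError(f"unknown folding engine: {name!r}")


def fold(sequence: str, engine: FoldingEngine | None = None) -> tuple[str, float]:
    """Fold a sequence (length >= 40 for precursor work) into (structure, mfe)."""
    eng = engine or _DEFAULT_ENGINE
    return eng.fold(sequence)


def pair_table(structure: str) -> list[int]:
    """0-based pair table: pt[i] = partner of i, or -1 when unpaired."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced dot-bracket structure")
            j = stack.pop()
            pt[i], pt[j] = j, i
    if stack:
        raise ValueError("unbalanced dot-bracket structure")
    return pt


def count_hairpin_loops(structure: str) -> int:
    """Number of terminal (hairpin) loops; a clean stem-loop has exactly 1."""
    return len(_HAIRPIN_LOOP_RE.findall(structure))


def gc_fraction(sequence: str) -> float:
    seq = sequence.upper()
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)


def mfei(mfe: float, length: int, gc: float) -> float:
    """Minimal folding free energy index: (|MFE|/length x 100) / GC%.

    The index is positive; values above ~0.85 separate miRNA precursors
    from other non-coding RNA.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    if not 0.0 < gc < 1.0:
        raise ValueError("gc must be strictly between 0 and 1")
    amfe = abs(mfe) / length * 100.0
    return amfe / (gc * 100.0)


def is_watson_crick(a: str, b: str) -> bool:
    a, b = to_rna(a), to_rna(b)
    return (a, b) in {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}


def is_wobble(a: str, b: str) -> bool:
    a, b = to_rna(a), to_rna(b)
    return (a, b) in {("G", "U"), ("U", "G")}


def can_pair(a: str, b: str) -> bool:
    return (to_rna(a), to_rna(b)) in _PAIRS
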