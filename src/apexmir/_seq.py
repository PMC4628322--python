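"""Small sequence and FASTA/FASTQ helpers shared across the package.

All public operations are U/T-insensitive: catalogs and mature miRNAs are
conventionally written as RNA (U) while sequencing reads arrive as DNA (T).
Internally we normalise to uppercase DNA for matching and to RNA only at the
folding boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTUacgtu", "TGCAAtgcaa")


def to_dna(seq: str) -> str:
    """Uppercase and rewrite U as T."""
    return seq.upper().replace("U", "T")


def to_rna(seq: str) -> str:
    """Uppercase and rewrite T as U."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    """Reverse complement (DNA output, accepts RNA input)."""
    return seq.translate(_COMPLEMENT)[::-1].upper().replace("U", "T")


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file as an ordered {id: uppercase sequence} mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records]
    SeqIO.write(recs, str(path), "fasta")


def iter_fastq(path: str | Path) -> Iterator[tuple[str, str]]:
    """Yield (read id, sequence) from a FASTQ file.

    A hand-checked 4-line walk rather than SeqIO so that a malformed record
    can be reported with its index, as the cleaning stage requires.
    """
    with open(path) as fh:
        idx = 0
        while True:
            header = fh.readline()
            if not header:
                return
            seq = fh.readline()
            plus = fh.readline()
            qual = fh.readline()
            header, seq, plus, qual = (s.rstrip("\n") for s in (header, seq, plus, qual))
            if (
                not header.startswith("@")
                or not plus.startswith("+")
                or not seq
                or len(qual) != len(seq)
            ):
                raise ValueError(f"malformed FASTQ record at index {idx} in {path}")
            yield header[1:].split()[0], seq.upper()
            idx += 1


def write_fastq(path: str | Path, reads: Iterable[tuple[str, str]], qual_char: str = "I") -> None:
    """Write (id, sequence) pairs as FASTQ with a constant quality string."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{qual_char * len(seq)}\n")
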