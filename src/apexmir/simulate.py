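"""Self-contained synthetic test universe for the small-RNA pipeline.

Generates a genome with planted miRNA precursors (validated at build time
against the same hairpin screen the pipeline applies, so truth and detection
criteria cannot drift apart), shuffled non-hairpin decoy loci, a
miRBase-style catalog, contaminant ncRNAs, three genotype read libraries
(A1 dwarf, A3 tall-culm, A9 wild type) with planted log2 fold changes,
transcripts with planted target sites at controlled penalties, and
degradome 5' tags concentrated at the planted cleavage positions.  A
machine-readable truth table records everything planted.

Count noise is negative-binomial with user dispersion (Poisson in the
dispersion -> 0 limit); a single configurable 3' adapter is appended to
every simulated read; degradome tags are 20 nt.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from ._seq import revcomp, to_dna, to_rna, write_fasta, write_fastq
from .annotate import Locus, PrecursorCandidate
from .folding import FoldingEngine
from .hairpin import ScreenThresholds, fold_candidate, screen_candidate

DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # TruSeq-style small-RNA 3' adapter
GENOTYPES = ("A1", "A3", "A9")
CONTRASTS = (("A1-A9", "A1", "A9"), ("A3-A9", "A3", "A9"))
DEGRADOME_TAG_LEN = 20

_FAMILY_POOL = (156, 159, 160, 162, 164, 166, 167, 168, 169, 171, 172, 390,
                393, 394, 396, 399, 403, 408, 482, 828, 858, 2949, 2950, 3476)


class GenerationError(RuntimeError):
    """Raised when a planted constraint cannot be satisfied within budget."""


@dataclass
class PlantedMiRNA:
    name: str
    mature: str            # RNA string
    arm: str               # '5p' or '3p'
    locus: Locus           # mature locus on the genome, 0-based half-open
    family: str
    known: bool            # present in the catalog
    precursor: str         # DNA, 5'->3' of the miRNA-bearing strand
    mature_iv: tuple[int, int]  # mature interval in precursor coordinates
    star: str | None = None     # star-arm sequence (DNA), when inferred
    emit_star: bool = False


@dataclass
class PlantedTarget:
    mirna: str
    transcript_id: str
    site_start: int  # 0-based on the transcript
    site_len: int
    penalty: float
    mode: str  # 'cleavage' or 'translational_repression'


@dataclass
class TruthTable:
    seed: int
    planted_mirnas: list[PlantedMiRNA] = field(default_factory=list)
    planted_abundance: dict[str, dict[str, float]] = field(default_factory=dict)
    planted_log2fc: dict[tuple[str, str], float] = field(default_factory=dict)
    planted_targets: list[PlantedTarget] = field(default_factory=list)
    planted_cleavage: list[tuple[str, int, float]] = field(default_factory=list)
    decoy_loci: list[Locus] = field(default_factory=list)
    decoy_matures: list[str] = field(default_factory=list)

    def check(self) -> None:
        for (name, contrast), fc in self.planted_log2fc.items():
            label, mut, wt = next(c for c in CONTRASTS if c[0] == contrast)
            ab = self.planted_abundance[name]
            if abs(fc - math.log2(ab[mut] / ab[wt])) > 1e-12:
                raise AssertionError(f"log2fc inconsistent with abundances for {name}")


@dataclass
class Reference:
    """Everything build_reference produced, ready for simulation or disk."""

    genome: dict[str, str]
    catalog: dict[str, str]          # name -> mature (RNA)
    contaminants: dict[str, str]
    transcripts: dict[str, str]
    truth: TruthTable
    params: dict = field(default_factory=dict)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fa", self.genome.items())
        write_fasta(outdir / "catalog.fa", self.catalog.items())
        write_fasta(outdir / "contaminants.fa", self.contaminants.items())
        write_fasta(outdir / "transcripts.fa", self.transcripts.items())
        t = self.truth
        with open(outdir / "truth_mirnas.tsv", "w") as fh:
            fh.write("name\tmature\tarm\tref\tstart\tend\tstrand\tfamily\tknown\n")
            for p in t.planted_mirnas:
                fh.write(
                    f"{p.name}\t{p.mature}\t{p.arm}\t{p.locus.ref}\t{p.locus.start}"
                    f"\t{p.locus.end}\t{p.locus.strand}\t{p.family}\t{int(p.known)}\n"
                )
        with open(outdir / "truth_abundance.tsv", "w") as fh:
            fh.write("name\t" + "\t".join(GENOTYPES) + "\tlog2fc_A1-A9\tlog2fc_A3-A9\n")
            for name, ab in t.planted_abundance.items():
                fh.write(
                    f"{name}\t" + "\t".join(f"{ab[g]:.6f}" for g in GENOTYPES)
                    + f"\t{t.planted_log2fc[(name, 'A1-A9')]:.6f}"
                    + f"\t{t.planted_log2fc[(name, 'A3-A9')]:.6f}\n"
                )
        with open(outdir / "truth_targets.tsv", "w") as fh:
            fh.write("mirna\ttranscript\tsite_start\tsite_len\tpenalty\tmode\n")
            for tg in t.planted_targets:
                fh.write(
                    f"{tg.mirna}\t{tg.transcript_id}\t{tg.site_start}\t{tg.site_len}"
                    f"\t{tg.penalty}\t{tg.mode}\n"
                )
        with open(outdir / "truth_cleavage.tsv", "w") as fh:
            fh.write("transcript\tposition_1based\texpected_fraction\n")
            for tid, pos, frac in t.planted_cleavage:
                fh.write(f"{tid}\t{pos}\t{frac}\n")
        with open(outdir / "params.txt", "w") as fh:
            for k, v in sorted(self.params.items()):
                fh.write(f"{k} = {v}\n")


def _random_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=probs))


def _make_precursor(
    rng: np.random.Generator,
    thresholds: ScreenThresholds,
    engine: FoldingEngine | None,
    *,
    mature_len: int = 21,
    max_tries: int = 200,
) -> tuple[str, tuple[int, int], str, str | None]:
    """A 70-101 nt single-loop hairpin passing the screen.

    Returns (precursor DNA, mature interval, arm, star sequence).  Built as
    a perfect inverted repeat around an AU-rich loop, then verified by the
    pipeline's own folding + screening contract; failures are redrawn.
    """
    for _ in range(max_tries):
        arm_len = int(rng.integers(32, 44))
        loop_len = int(rng.integers(8, 12))
        arm = _random_seq(rng, arm_len, float(rng.uniform(0.48, 0.62)))
        loop = _random_seq(rng, loop_len, 0.25)
        prec = arm + loop + revcomp(arm)
        if not 70 <= len(prec) <= 101:
            continue
        arm_choice = "5p" if rng.random() < 0.5 else "3p"
        offset = int(rng.integers(0, arm_len - mature_len + 1))
        if arm_choice == "5p":
            iv = (offset, offset + mature_len)
        else:
            iv = (arm_len + loop_len + offset, arm_len + loop_len + offset + mature_len)
        cand = PrecursorCandidate(
            locus=Locus("synthetic", 0, len(prec), "+"), sequence=prec, mature=iv
        )
        cand = fold_candidate(cand, engine)
        verdict = screen_candidate(cand, thresholds)
        if not verdict.passed:
            continue
        star = None
        if cand.star is not None:
            star = prec[cand.star[0] : cand.star[1]]
        return prec, iv, arm_choice, star
    raise GenerationError(
        "could not draw a precursor passing the hairpin screen "
        f"(duplex/MFEI/length constraints) in {max_tries} tries"
    )


def _make_decoy(
    rng: np.random.Generator,
    thresholds: ScreenThresholds,
    engine: FoldingEngine | None,
    *,
    max_tries: int = 50,
) -> tuple[str, str]:
    """A shuffled non-hairpin sequence plus a central 21-mer decoy tag."""
    for _ in range(max_tries):
        length = int(rng.integers(75, 100))
        seq = _random_seq(rng, length, float(rng.uniform(0.35, 0.55)))
        mid = (length - 21) // 2
        cand = PrecursorCandidate(
            locus=Locus("synthetic", 0, length, "+"), sequence=seq, mature=(mid, mid + 21)
        )
        cand = fold_candidate(cand, engine)
        if not screen_candidate(cand, thresholds).passed:
            return seq, seq[mid : mid + 21]
    raise GenerationError("could not draw a non-hairpin decoy")


def _mismatch_base(base: str, rng: np.random.Generator) -> str:
    """A site base that neither Watson-Crick- nor wobble-pairs ``base``."""
    base = to_dna(base)
    forbidden = {"A": {"T"}, "C": {"G"}, "G": {"C", "T"}, "T": {"A", "G"}}[base]
    options = sorted(set("ACGT") - forbidden)
    return options[int(rng.integers(len(options)))]


def _plant_site(
    mature_rna: str, penalty_class: float, mode: str, rng: np.random.Generator
) -> tuple[str, float]:
    """A target-site DNA sequence whose duplex with the miRNA scores exactly
    ``penalty_class`` (mode 'translational_repression' forces a centre
    mismatch instead)."""
    from .targets import score_duplex

    m = to_rna(mature_rna)
    L = len(m)
    site = list(revcomp(m))  # DNA, 5'->3' on the transcript; perfect duplex

    def set_mismatch(pos_1based: int) -> None:
        j = L - pos_1based  # site index pairing miRNA position pos
        site[j] = _mismatch_base(m[pos_1based - 1], rng)

    def set_wobble(pos_1based: int) -> bool:
        b = m[pos_1based - 1]
        j = L - pos_1based
        if b == "G":
            site[j] = "T"
            return True
        if b == "U":
            site[j] = "G"
            return True
        return False

    if mode == "translational_repression":
        set_mismatch(10)
        expected = 2.0
    elif penalty_class == 0.0:
        expected = 0.0
    elif penalty_class == 2.0:
        set_mismatch(5)
        expected = 2.0
    elif penalty_class == 3.5:
        set_mismatch(5)
        set_mismatch(16)
        wob = next(
            (p for p in (1, *range(14, L + 1)) if p != 16 and m[p - 1] in "GU"), None
        )
        if wob is None:
            raise GenerationError("mature has no wobble-capable position outside the core")
        set_wobble(wob)
        expected = 3.5
    else:
        raise ValueError(f"unsupported penalty class {penalty_class}")
    site_seq = "".join(site)
    got, _aln = score_duplex(mature_rna, site_seq)
    if abs(got - expected) > 1e-9:
        raise GenerationError(
            f"planted site scored {got}, wanted {expected} (mature {mature_rna})"
        )
    return site_seq, expected


def build_reference(
    n_known: int = 20,
    n_novel: int = 5,
    n_decoys: int = 20,
    *,
    genome_len: int | None = None,
    gc: float = 0.42,
    seed: int = 0,
    thresholds: ScreenThresholds = ScreenThresholds(),
    engine: FoldingEngine | None = None,
    n_targets: int = 5,
    transcript_len: int = 600,
    base_rpm_range: tuple[float, float] = (100.0, 2000.0),
    fc_cycle: Sequence[tuple[float, float]] = ((2.0, -2.0), (0.0, 0.0), (-2.0, 2.0)),
) -> Reference:
    """Build the synthetic genome, catalog, contaminants, transcripts + truth.

    Planted precursors are rejection-sampled against the pipeline's own
    hairpin screen; decoys are verified to fail it.  Per-genotype expected
    RPM and log2 fold changes (cycled over ``fc_cycle``) are recorded in the
    truth table, exactly consistent with each other.
    """
    if not 0 < gc < 1:
        raise ValueError("gc must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    truth = TruthTable(seed=seed)

    # --- contaminants ------------------------------------------------------
    contaminants = {
        "tRNA_1": _random_seq(rng, 76, 0.55),
        "tRNA_2": _random_seq(rng, 74, 0.5),
        "rRNA_1": _random_seq(rng, 900, 0.52),
        "rRNA_2": _random_seq(rng, 1500, 0.5),
        "snRNA_1": _random_seq(rng, 160, 0.45),
        "snoRNA_1": _random_seq(rng, 120, 0.45),
    }

    # --- precursors and decoys --------------------------------------------
    inserts: list[tuple[str, dict]] = []  # (sequence on + strand pre-orientation, meta)
    matures_seen: set[str] = set()
    fam_iter = iter(_FAMILY_POOL)
    for i in range(n_known + n_novel):
        while True:
            prec, iv, arm, star = _make_precursor(rng, thresholds, engine)
            mature = prec[iv[0] : iv[1]]
            if mature not in matures_seen and not any(
                mature in c for c in contaminants.values()
            ):
                matures_seen.add(mature)
                break
        known = i < n_known
        if known:
            fam_no = next(fam_iter, 9000 + i)
            name = f"ghr-miR{fam_no}a"
            family = f"miR{fam_no}"
        else:
            name = f"novel_{i - n_known + 1}"
            family = "NA"
        inserts.append(
            (prec, dict(kind="precursor", name=name, family=family, known=known,
                        mature_iv=iv, arm=arm, star=star))
        )
    for d in range(n_decoys):
        while True:
            seq, dm = _make_decoy(rng, thresholds, engine)
            if dm not in matures_seen:
                matures_seen.add(dm)
                break
        inserts.append((seq, dict(kind="decoy", name=f"decoy_{d + 1}", mature=dm)))

    # --- genome assembly ---------------------------------------------------
    total_insert = sum(len(s) for s, _ in inserts)
    min_gap = 30
    n_ins = len(inserts)
    if genome_len is None:
        genome_len = max(20000, total_insert * 3)
    free = genome_len - total_insert - (n_ins + 1) * min_gap
    if free < 0:
        raise GenerationError(
            f"genome_len {genome_len} too short for {n_ins} inserts plus spacing"
        )
    raw = rng.random(n_ins + 1)
    gaps = (min_gap + raw / raw.sum() * free).astype(int)
    order = rng.permutation(n_ins)
    background = _random_seq(rng, genome_len, gc)
    genome_parts: list[str] = []
    cursor = 0
    ref = "chr1"
    for slot, idx in enumerate(order):
        seq, meta = inserts[idx]
        gap = int(gaps[slot])
        genome_parts.append(background[cursor : cursor + gap])
        cursor += gap
        start = sum(len(p) for p in genome_parts)
        strand = "+" if rng.random() < 0.5 else "-"
        placed = seq if strand == "+" else revcomp(seq)
        genome_parts.append(placed)
        L = len(seq)
        if meta["kind"] == "precursor":
            m0, m1 = meta["mature_iv"]
            if strand == "+":
                locus = Locus(ref, start + m0, start + m1, "+")
            else:
                locus = Locus(ref, start + L - m1, start + L - m0, "-")
            mature = seq[m0:m1]
            truth.planted_mirnas.append(
                PlantedMiRNA(
                    name=meta["name"], mature=to_rna(mature), arm=meta["arm"],
                    locus=locus, family=meta["family"], known=meta["known"],
                    precursor=seq, mature_iv=(m0, m1), star=meta["star"],
                )
            )
        else:
            dm = meta["mature"]
            off = seq.find(dm)
            if strand == "+":
                locus = Locus(ref, start + off, start + off + len(dm), "+")
            else:
                locus = Locus(ref, start + L - off - len(dm), start + L - off, "-")
            truth.decoy_loci.append(locus)
            truth.decoy_matures.append(dm)
    genome_parts.append(background[cursor : cursor + genome_len - sum(len(p) for p in genome_parts) + 0])
    genome_seq = "".join(genome_parts)[:genome_len]
    if len(genome_seq) < genome_len:
        genome_seq += background[: genome_len - len(genome_seq)]
    genome = {ref: genome_seq}

    # star emission for a few known precursors (star-strand evidence)
    for p in [q for q in truth.planted_mirnas if q.known][:3]:
        if p.star:
            p.emit_star = True

    # --- catalog -----------------------------------------------------------
    catalog: dict[str, str] = {}
    for p in truth.planted_mirnas:
        if p.known:
            catalog[p.name] = p.mature
    # cross-species duplicates of the first entries exercise tie precedence
    known_planted = [p for p in truth.planted_mirnas if p.known]
    for p in known_planted[:2]:
        catalog[f"ath-{p.name.split('-', 1)[1]}"] = p.mature
    for j in range(5):  # catalog entries never planted in the genome
        catalog[f"ath-miR99{j}0"] = to_rna(_random_seq(rng, 21, 0.5))

    # --- abundances and fold changes --------------------------------------
    lo, hi = base_rpm_range
    for i, p in enumerate(truth.planted_mirnas):
        base = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        fc1, fc3 = fc_cycle[i % len(fc_cycle)]
        ab = {"A9": base, "A1": base * 2.0**fc1, "A3": base * 2.0**fc3}
        truth.planted_abundance[p.name] = ab
        truth.planted_log2fc[(p.name, "A1-A9")] = fc1
        truth.planted_log2fc[(p.name, "A3-A9")] = fc3
    truth.check()

    # --- transcripts with planted target sites ----------------------------
    transcripts: dict[str, str] = {}
    classes = [0.0, 2.0, 3.5]
    targetable = truth.planted_mirnas[: max(0, n_targets)]
    for k, p in enumerate(targetable):
        mode = "translational_repression" if k == len(targetable) - 1 and k >= 3 else "cleavage"
        pen_class = classes[k % len(classes)]
        try:
            site, penalty = _plant_site(p.mature, pen_class, mode, rng)
        except GenerationError:
            # rare matures with no wobble-capable position outside the core
            # cannot carry a 3.5 site; fall back to the 2.0 recipe
            site, penalty = _plant_site(p.mature, 2.0, mode, rng)
        tid = f"transcript_{k + 1:03d}"
        body = _random_seq(rng, transcript_len, 0.45)
        s = int(rng.integers(100, transcript_len - 100 - len(site)))
        seq = body[:s] + site + body[s + len(site):]
        transcripts[tid] = seq
        truth.planted_targets.append(
            PlantedTarget(
                mirna=p.name, transcript_id=tid, site_start=s,
                site_len=len(site), penalty=penalty,
                mode=mode,
            )
        )
        if mode == "cleavage":
            cleavage_pos = s + len(site) - 9  # 1-based, opposite miRNA position 10
            truth.planted_cleavage.append((tid, cleavage_pos, 0.8))
    for k in range(2):  # decoy transcripts with no planted site
        transcripts[f"transcript_d{k + 1:02d}"] = _random_seq(rng, transcript_len, 0.45)

    params = dict(
        n_known=n_known, n_novel=n_novel, n_decoys=n_decoys,
        genome_len=genome_len, gc=gc, seed=seed, n_targets=n_targets,
        transcript_len=transcript_len, base_rpm_range=base_rpm_range,
        fc_cycle=tuple(fc_cycle),
    )
    return Reference(
        genome=genome, catalog=catalog, contaminants=contaminants,
        transcripts=transcripts, truth=truth, params=params,
    )


def _nb_counts(
    rng: np.random.Generator, mean: float, dispersion: float, size: int = 1
) -> np.ndarray:
    """Negative-binomial counts with Var = mu + dispersion * mu^2."""
    if mean <= 0:
        return np.zeros(size, dtype=np.int64)
    if dispersion <= 0:
        return rng.poisson(mean, size=size)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion, size=size)
    return rng.poisson(lam)


@dataclass
class SimulatedLibraries:
    reads: dict[str, list[str]]          # library -> raw read sequences (with adapter)
    totals: dict[str, int]
    realized_counts: dict[str, dict[str, int]]  # library -> miRNA name -> count
    adapter: str

    def counts_by_feature(self) -> dict[str, dict[str, int]]:
        """Realized counts pivoted to {miRNA name: {library: count}}."""
        out: dict[str, dict[str, int]] = {}
        for lib, counts in self.realized_counts.items():
            for name, c in counts.items():
                out.setdefault(name, {})[lib] = c
        return out

    def write(self, outdir: str | Path) -> dict[str, Path]:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for lib, reads in self.reads.items():
            path = outdir / f"{lib}.fastq"
            write_fastq(path, ((f"{lib}_r{i}", seq) for i, seq in enumerate(reads)))
            paths[lib] = path
        return paths


def simulate_sran_libraries(
    ref: Reference,
    depth: int = 100_000,
    dispersion: float = 0.0,
    seed: int = 0,
    *,
    counts_only: bool = False,
    adapter: str = DEFAULT_ADAPTER,
    contaminant_frac: float = 0.05,
    junk_frac: float = 0.02,
    polya_frac: float = 0.01,
    outlier_frac: float = 0.02,
    star_frac: float = 0.05,
    decoy_rpm: float = 300.0,
) -> SimulatedLibraries:
    """Three genotype FASTQ libraries with planted abundances.

    Per planted miRNA the read count is negative-binomial with mean
    expected RPM x depth / 10^6 (Poisson at the default dispersion 0, the
    sampling model for a single sequenced library); contaminant-derived
    reads, poly(A) reads, adapterless junk and length outliers are mixed in
    at the stated fractions so every cleaning filter has work to do.

    With ``counts_only`` the per-miRNA counts and library totals are drawn
    but no read sequences are materialised — the cheap route to count-level
    simulations at large depth.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    if not ref.truth.planted_mirnas and not ref.contaminants:
        raise ValueError("nothing to simulate: no planted miRNAs or contaminants")
    rng = np.random.default_rng(seed)
    truth = ref.truth
    reads: dict[str, list[str]] = {}
    totals: dict[str, int] = {}
    realized: dict[str, dict[str, int]] = {}
    for lib in GENOTYPES:
        lib_reads: list[str] = []
        lib_counts: dict[str, int] = {}
        n_extra = 0
        for p in truth.planted_mirnas:
            mean = truth.planted_abundance[p.name][lib] * depth / 1e6
            c = int(_nb_counts(rng, mean, dispersion)[0])
            lib_counts[p.name] = c
            if not counts_only:
                lib_reads.extend([to_dna(p.mature) + adapter] * c)
            if p.emit_star and p.star:
                cs = int(_nb_counts(rng, star_frac * mean, dispersion)[0])
                n_extra += cs
                if not counts_only:
                    lib_reads.extend([to_dna(p.star) + adapter] * cs)
        for dm in truth.decoy_matures:
            mean = decoy_rpm * depth / 1e6
            c = int(_nb_counts(rng, mean, dispersion)[0])
            n_extra += c
            if not counts_only:
                lib_reads.extend([dm + adapter] * c)
        if counts_only:
            # the nominal depth is the library-size denominator: planted
            # abundances are RPM on that scale, so RPM recomputed against it
            # is unbiased by compositional shifts between genotypes
            totals[lib] = depth
            realized[lib] = lib_counts
            reads[lib] = []
            continue
        n_cont = rng.poisson(contaminant_frac * depth)
        cont_ids = sorted(ref.contaminants)
        for _ in range(n_cont):
            cid = cont_ids[int(rng.integers(len(cont_ids)))]
            cseq = ref.contaminants[cid]
            ln = int(rng.integers(20, 25))
            # discretised starts keep the unique-tag space small
            max_start = max(1, (len(cseq) - ln) // 7)
            start = 7 * int(rng.integers(max_start))
            lib_reads.append(cseq[start : start + ln] + adapter)
        for _ in range(rng.poisson(junk_frac * depth)):
            lib_reads.append(_random_seq(rng, int(rng.integers(30, 41)), 0.5))
        for _ in range(rng.poisson(polya_frac * depth)):
            lib_reads.append("A" * int(rng.integers(20, 28)) + adapter)
        for _ in range(rng.poisson(outlier_frac * depth)):
            if rng.random() < 0.5:
                ln = int(rng.integers(10, 17))
            else:
                ln = int(rng.integers(36, 46))
            lib_reads.append(_random_seq(rng, ln, 0.5) + adapter)
        perm = rng.permutation(len(lib_reads))
        reads[lib] = [lib_reads[i] for i in perm]
        realized[lib] = lib_counts
        totals[lib] = len(lib_reads)
    return SimulatedLibraries(
        reads=reads, totals=totals, realized_counts=realized, adapter=adapter
    )


def simulate_degradome(
    ref: Reference,
    depth: int = 10_000,
    signal_fraction: float = 0.8,
    seed: int = 0,
) -> list[str]:
    """Degradome 5'-tag sequences (20 nt) over the reference transcripts.

    For each transcript with a planted cleavage site, ``signal_fraction``
    of its tags start exactly at the cleavage position (the first base of
    the 3' fragment); the rest start uniformly at other positions.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    cleavage = {tid: pos for tid, pos, _f in ref.truth.planted_cleavage}
    for tid, pos in cleavage.items():
        if tid not in ref.transcripts:
            raise ValueError(f"planted cleavage transcript {tid!r} missing")
        if not 1 <= pos <= len(ref.transcripts[tid]) - DEGRADOME_TAG_LEN + 1:
            raise ValueError(f"cleavage position {pos} outside transcript {tid!r}")
    tids = sorted(ref.transcripts)
    per_transcript = depth // len(tids)
    tags: list[str] = []
    for tid in tids:
        seq = to_dna(ref.transcripts[tid])
        max_start = len(seq) - DEGRADOME_TAG_LEN
        n_total = per_transcript
        pos0 = cleavage.get(tid)
        n_signal = round(signal_fraction * n_total) if pos0 is not None else 0
        if pos0 is not None:
            tags.extend([seq[pos0 - 1 : pos0 - 1 + DEGRADOME_TAG_LEN]] * n_signal)
        for _ in range(n_total - n_signal):
            while True:
                start = int(rng.integers(0, max_start + 1))
                if pos0 is None or start != pos0 - 1:
                    break
            tags.append(seq[start : start + DEGRADOME_TAG_LEN])
    perm = rng.permutation(len(tags))
    return [tags[i] for i in perm]
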