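"""End-to-end orchestration: simulate -> preprocess -> annotate -> discover
-> differential expression -> targets -> degradome -> report.

The pipeline runs either on a synthetic reference generated in-process or on
user-supplied FASTA/FASTQ paths.  Every stage logs its input/output row
counts, results are written as TSV tables shaped like a small-RNA study's
summary tables, and a provenance file records the config hash and seed so a
rerun with the same config reproduces identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import annotate, degradome, expression, hairpin, preprocess, simulate
from ._seq import read_fasta

logger = logging.getLogger("apexmir")


@dataclass
class RunConfig:
    seed: int = 1
    outdir: str = "apexmir_run"
    # synthetic generation (used when no external inputs are given)
    n_known: int = 20
    n_novel: int = 5
    n_decoys: int = 20
    depth: int = 100_000
    dispersion: float = 0.05
    degradome_depth: int = 10_000
    signal_fraction: float = 0.8
    # external inputs (override simulation when all sRNA inputs are set)
    genome_fasta: str | None = None
    catalog_fasta: str | None = None
    contaminant_fasta: str | None = None
    transcript_fasta: str | None = None
    srna_fastq: dict[str, str] = field(default_factory=dict)  # library -> path
    degradome_fastq: str | None = None
    # preprocessing
    adapter: str = simulate.DEFAULT_ADAPTER
    min_len: int = 17
    max_len: int = 35
    polya_frac: float = 0.8
    contaminant_max_mismatch: int = 1
    # hairpin screen
    min_pairs: int = 16
    max_size_diff: int = 4
    min_mfei: float = 0.85
    precursor_len_range: tuple[int, int] = (70, 300)
    flank: int = 150
    # expression
    zero_floor: float = 0.01
    min_abs_log2fc: float = 1.0
    max_p: float = 0.05
    max_fdr: float = 0.001
    # targets / degradome
    target_cutoff: float = 4.0
    n_shuffles: int = 100
    alpha: float = 0.05

    def validate(self) -> None:
        if self.min_len > self.max_len:
            raise ValueError("min_len must be <= max_len")
        if not self.adapter:
            raise ValueError("adapter must be non-empty")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        lo, hi = self.precursor_len_range
        if lo > hi:
            raise ValueError("precursor_len_range must be (lo, hi) with lo <= hi")

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.as_dict(), fh, sort_keys=True)

    def as_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["precursor_len_range"] = list(self.precursor_len_range)
        return d

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if "precursor_len_range" in data:
            data["precursor_len_range"] = tuple(data["precursor_len_range"])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.as_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class PipelineResult:
    config: RunConfig
    reference: simulate.Reference | None
    stats: list[preprocess.LibraryStats]
    tags: list[preprocess.SequenceTag]
    assignments: dict
    novel: list[hairpin.NovelMiRNA]
    verdicts: list[hairpin.ScreenVerdict]
    records: dict[str, expression.ExpressionRecord]
    interactions: list
    degradome_hits: list[degradome.DegradomeHit]
    tables: dict[str, pd.DataFrame] = field(default_factory=dict)


def _screen_thresholds(cfg: RunConfig) -> hairpin.ScreenThresholds:
    return hairpin.ScreenThresholds(
        min_pairs=cfg.min_pairs,
        max_size_diff=cfg.max_size_diff,
        min_mfei=cfg.min_mfei,
        len_range=tuple(cfg.precursor_len_range),
    )


def run_pipeline(cfg: RunConfig) -> PipelineResult:
    cfg.validate()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    use_synthetic = not cfg.srna_fastq

    # --- stage 0: reference ------------------------------------------------
    if use_synthetic:
        ref = simulate.build_reference(
            n_known=cfg.n_known, n_novel=cfg.n_novel, n_decoys=cfg.n_decoys,
            seed=cfg.seed, thresholds=_screen_thresholds(cfg),
        )
        libs = simulate.simulate_sran_libraries(
            ref, depth=cfg.depth, dispersion=cfg.dispersion, seed=cfg.seed + 1,
            adapter=cfg.adapter,
        )
        fastq_paths = libs.write(outdir / "reads")
        genome, catalog_fa, contaminants, transcripts = (
            ref.genome, {k: v for k, v in ref.catalog.items()}, ref.contaminants,
            ref.transcripts,
        )
        deg_tags = simulate.simulate_degradome(
            ref, depth=cfg.degradome_depth, signal_fraction=cfg.signal_fraction,
            seed=cfg.seed + 2,
        )
        ref.write(outdir / "reference")
    else:
        for name in ("genome_fasta", "catalog_fasta", "contaminant_fasta", "transcript_fasta"):
            if getattr(cfg, name) is None:
                raise FileNotFoundError(f"config requires {name} when srna_fastq is given")
        ref = None
        genome = read_fasta(cfg.genome_fasta)
        catalog_fa = read_fasta(cfg.catalog_fasta)
        contaminants = read_fasta(cfg.contaminant_fasta)
        transcripts = read_fasta(cfg.transcript_fasta)
        fastq_paths = {lib: Path(p) for lib, p in cfg.srna_fastq.items()}
        deg_tags = cfg.degradome_fastq

    # --- stage 1: preprocess ----------------------------------------------
    cleaned: dict[str, list[str]] = {}
    stats: list[preprocess.LibraryStats] = []
    for lib, path in sorted(fastq_paths.items()):
        reads, st = preprocess.clean_reads(
            path, cfg.adapter, min_len=cfg.min_len, max_len=cfg.max_len,
            polya_frac=cfg.polya_frac, library=lib,
        )
        cleaned[lib] = reads
        stats.append(st)
        logger.info("clean %s: %d raw -> %d clean", lib, st.raw_reads, st.clean_reads)
    tags = preprocess.collapse(cleaned)
    contaminant_tags, retained = preprocess.remove_contaminants(
        tags, contaminants, max_mismatch=cfg.contaminant_max_mismatch
    )
    logger.info("tags: %d unique, %d contaminant", len(tags), len(contaminant_tags))

    # --- stage 2: known miRNAs ---------------------------------------------
    catalog = annotate.load_catalog(catalog_fa)
    assignments = annotate.match_known(retained, catalog)

    # --- stage 3: novel discovery ------------------------------------------
    novel, verdicts = hairpin.discover_novel(
        retained, genome, _screen_thresholds(cfg), flank=cfg.flank
    )
    logger.info("novel: %d passing of %d candidates", len(novel), len(verdicts))

    # --- stage 4: expression ------------------------------------------------
    library_totals = {st.library: float(st.clean_reads) for st in stats}
    counts: dict[str, dict[str, int]] = {}
    for tag in retained:
        if tag.annotation in ("known_miRNA", "novel_miRNA"):
            feat = tag.annotation_detail or tag.sequence
            row = counts.setdefault(feat, {})
            for lib, c in tag.counts.items():
                row[lib] = row.get(lib, 0) + c
    records = (
        expression.build_expression_table(
            counts, library_totals, floor=cfg.zero_floor
        )
        if counts
        else {}
    )

    # --- stage 5: targets ---------------------------------------------------
    from . import targets as targets_mod

    mature_by_name: dict[str, str] = {}
    for tag in retained:
        if tag.annotation in ("known_miRNA", "novel_miRNA") and tag.annotation_detail:
            mature_by_name.setdefault(tag.annotation_detail, tag.sequence)
    interactions = []
    for name, seq in sorted(mature_by_name.items()):
        found = targets_mod.find_targets(name, seq, transcripts, cutoff=cfg.target_cutoff)
        for it in found:
            targets_mod.classify_mode(it)
        interactions.extend(found)

    # --- stage 6: degradome -------------------------------------------------
    degradome_hits: list[degradome.DegradomeHit] = []
    if deg_tags is not None:
        profiles = degradome.build_profile(deg_tags, transcripts)
        for it in interactions:
            res = degradome.validate_interaction(
                it.mirna_id, mature_by_name[it.mirna_id], it.transcript_id,
                transcripts[it.transcript_id], profiles,
                max_penalty=cfg.target_cutoff, n_shuffles=cfg.n_shuffles,
                alpha=cfg.alpha, seed=cfg.seed + 3,
            )
            if isinstance(res, degradome.DegradomeHit):
                degradome_hits.append(res)

    result = PipelineResult(
        config=cfg, reference=ref, stats=stats, tags=tags,
        assignments=assignments, novel=novel, verdicts=verdicts,
        records=records, interactions=interactions, degradome_hits=degradome_hits,
    )
    result.tables = render_tables(result)
    _write_outputs(result, outdir)
    return result


def render_tables(result: PipelineResult) -> dict[str, pd.DataFrame]:
    """Summary tables: library stats, family-level and miRNA-level expression."""
    libs = [st.library for st in result.stats]
    t1 = preprocess.stats_table(result.stats)

    def _expr_rows(level: str) -> pd.DataFrame:
        rows = []
        for feat, rec in sorted(result.records.items()):
            row: dict[str, Any] = {level: feat}
            for lib in libs:
                row[f"RPM_{lib}"] = round(rec.rpm.get(lib, 0.0), 2)
            for contrast in rec.log2fc:
                mut, wt = contrast.split("-")
                a = expression.substitute_zero(rec.rpm.get(mut, 0.0))
                b = expression.substitute_zero(rec.rpm.get(wt, 0.0))
                row[f"Log2_{contrast}"] = f"{expression.log2fc(a, b):.2f}"
                row[f"p_{contrast}"] = rec.pvalue[contrast]
                row[f"DE_{contrast}"] = rec.de_flag[contrast]
            rows.append(row)
        return pd.DataFrame(rows)

    t4 = _expr_rows("miRNA")
    # family level: sum member RPMs before fold change
    fam_rpm: dict[str, dict[str, float]] = {}
    by_name = {e.name: e for e in result.assignments.values()}
    for feat, rec in result.records.items():
        fam = by_name[feat].family if feat in by_name else "NA"
        row = fam_rpm.setdefault(fam, {lib: 0.0 for lib in libs})
        for lib in libs:
            row[lib] += rec.rpm.get(lib, 0.0)
    rows = []
    for fam in sorted(fam_rpm):
        row: dict[str, Any] = {"family": fam}
        for lib in libs:
            row[f"RPM_{lib}"] = round(fam_rpm[fam][lib], 2)
        for contrast, mut, wt in (("A1-A9", "A1", "A9"), ("A3-A9", "A3", "A9")):
            if mut in fam_rpm[fam] and wt in fam_rpm[fam]:
                a = expression.substitute_zero(fam_rpm[fam][mut])
                b = expression.substitute_zero(fam_rpm[fam][wt])
                row[f"Log2_{contrast}"] = f"{expression.log2fc(a, b):.2f}"
        rows.append(row)
    t3 = pd.DataFrame(rows)
    return {"library_stats": t1, "family_expression": t3, "mirna_expression": t4}


def _write_outputs(result: PipelineResult, outdir: Path) -> None:
    tables_dir = outdir / "tables"
    tables_dir.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables.items():
        df.to_csv(tables_dir / f"{name}.tsv", sep="\t", index=False)
    preprocess.write_tag_fasta(result.tags, tables_dir / "tags.fa")
    libs = [st.library for st in result.stats]
    preprocess.count_matrix(result.tags, libs).to_csv(
        tables_dir / "tag_counts.tsv", sep="\t"
    )
    hairpin.write_novel(result.novel, tables_dir / "novel_mirnas")
    inter_rows = [
        {
            "miRNA": it.mirna_id, "transcript": it.transcript_id,
            "start": it.start, "end": it.end, "penalty": it.penalty,
            "mode": it.mode,
        }
        for it in result.interactions
    ]
    pd.DataFrame(inter_rows).to_csv(tables_dir / "targets.tsv", sep="\t", index=False)
    hit_rows = [
        {
            "miRNA": h.interaction.mirna_id, "transcript": h.interaction.transcript_id,
            "cleavage_position": h.cleavage_position, "peak_count": h.peak_count,
            "category": h.category, "shuffle_p": h.shuffle_p,
        }
        for h in result.degradome_hits
    ]
    pd.DataFrame(hit_rows).to_csv(tables_dir / "degradome_hits.tsv", sep="\t", index=False)
    provenance = {
        "config_digest": result.config.digest(),
        "seed": result.config.seed,
        "n_tags": len(result.tags),
        "n_known_assigned": len(result.assignments),
        "n_novel": len(result.novel),
        "n_interactions": len(result.interactions),
        "n_degradome_hits": len(result.degradome_hits),
    }
    with open(outdir / "provenance.json", "w") as fh:
        json.dump(provenance, fh, indent=2, sort_keys=True)
    result.config.to_yaml(outdir / "config.yaml")
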