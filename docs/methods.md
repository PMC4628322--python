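# Methods

## Scope and data model

The package analyses one small-RNA library per genotype — a dwarf mutant
(A1), a tall-culm mutant (A3) and their wild type (A9) — against a genome,
a mature-miRNA catalog, a contaminant ncRNA set, a transcript set and a
degradome library. There are no biological replicates in this design;
every statistical procedure here is a two-library count comparison, not a
replicate-aware model. Transcript-level differential expression is
accepted as an input count matrix; assembling the transcriptome itself is
out of scope.

## Read cleaning

Reads are 3′-adapter trimmed by exact search for the adapter (or a
≥ 6-nt adapter prefix at the read end). A read is discarded as `no_insert`
when no adapter is found or when the adapter starts at position 0 — the
latter covers both empty inserts and 5′-primer artifacts, which cannot be
told apart once the insert is gone. The poly(A) rule is operationalised as
≥ 80% adenine in the trimmed insert (the threshold is a config knob; "has a
poly(A) tail" is not otherwise quantifiable). The length window is
17–35 nt, matching the gel cut of small-RNA library preparation. Cleaning
conserves counts exactly: clean = raw − Σ removed, asserted at run time.

Contaminant removal aligns each tag end-to-end, without gaps, at every
offset of every contaminant reference and on both strands, calling a tag
contaminant at ≤ 1 substitution. Both strands are searched because strand
provenance of ncRNA fragments in sRNA libraries is unreliable. Annotation
precedence when multiple classes could claim a tag: contaminant > known
miRNA > novel miRNA > unannotated, mirroring the sequential removal order
of the standard workflow.

## Known miRNAs, families, precursors, stars

Identification is exact, U/T-insensitive sequence identity to a catalog
mature sequence. When several catalog entries share one mature sequence the
own-species entry wins, then lexicographic name order — deterministic and
reported explicitly. Families derive from names by stripping the species
prefix and letter/arm suffixes; entries that do not parse pool under "NA".

Precursor candidates are the ±150 nt genomic windows flanking a mature
locus, reverse-complemented for minus-strand loci so the mature always
reads 5′→3′ in precursor coordinates; the coordinate maps are exact
bijections (round-trip tested). The expected miRNA\* interval is computed
from the fold's pair table with the canonical 2-nt 3′ overhang; a tag is
star evidence when its mapped interval matches the expectation within
±2 nt at both ends. When the mature arm is unpaired there is no duplex and
star detection reports absence rather than guessing.

## Hairpin screen and novel discovery

Folding is a pluggable engine. The default is ViennaRNA's MFE fold; a
bundled Nussinov-style dynamic-programming folder (base-pair scores with a
stacking bonus, minimum 3-nt loop) exists for dependency-free smoke
testing. Its pseudo-energies are not comparable with a thermodynamic
model, so screens that depend on energy magnitudes (MFEI) are only
meaningful under ViennaRNA; the engine identity is recorded on every
folded candidate.

A candidate passes the screen iff it is a single-loop hairpin, the
mature/star duplex has ≥ 16 paired positions, the arm lengths differ by
≤ 4 nt, MFEI > 0.85 (strict, per the criterion's "greater than"), and the
precursor length falls in [70, 300] nt. The pair-count reading "exceeding
16" is taken as ≥ 16 (the convention of the criteria this screen follows);
a strict > 16 is available via `ScreenThresholds(strict_pairs=True)`.
Screening is monotone in every threshold, which the tests assert.

Because a ±150 nt window (≈ 321 nt) always exceeds a genuine precursor,
discovery folds the window once, locates the star arm, trims to the span
of both arms plus 10 nt, and refolds the trimmed sequence before
screening. Without this step the length rule would reject every candidate;
with it, trimmed precursors of planted 70–101 nt hairpins come back at
essentially their planted extent. Candidates from overlapping loci whose
trimmed genomic intervals agree within ±5 nt are merged. Passing
candidates are named `ghr-mNNNN-5p/3p` by which side of the terminal loop
the mature occupies. The mature tag of a known miRNA never reaches
discovery (it is annotated first), but a sequenced star tag can — and may
legitimately surface the opposite arm of a known precursor as a novel arm.

## Expression statistics

RPM = count / library total × 10⁶, with the total being the library's
clean reads. RPM of exactly 0 is floored at 0.01 before ratios; the floor
is configurable (0.001 is the other convention in circulation) but 0.01 is
the default because the package's worked examples — fold changes like
log₂(37.81/0.01) = 11.88 — are arithmetically consistent only with 0.01.
Fold change is log₂(mutant) − log₂(wild); the difference-of-logs form
makes antisymmetry exact in floating point.

The count test is the Audic–Claverie comparison of one count in each of
two libraries, implemented in its conditional-binomial form: given
t = x + y, under the null y ~ Binomial(t, N₂/(N₁+N₂)); the two-sided p is
twice the smaller tail, capped at 1. This form is preferred over summing
the raw AC conditional pmf because it is exactly exchange-symmetric
(p(x, y, N₁, N₂) = p(y, x, N₂, N₁)), which the raw-pmf version is not,
while agreeing with it in the tail that matters. Type-I error at
α = 0.05 is calibrated on Poisson nulls in the acceptance suite (observed
≈ 4–5%).

DE calls use |log₂FC| ≥ 1 with raw p ≤ 0.05 for miRNAs and FDR ≤ 0.001
(Benjamini–Hochberg, per contrast, never pooled across contrasts) for
transcripts. Boundaries are inclusive. Correlation classes for a
miRNA/target pair in one contrast: `anti` when the two calls are opposite
directions, `positive` when they agree, `none` when either is `ns`. The
qPCR helper returns 2^(−ΔΔCt) with ΔΔCt = (Ct_target − Ct_ref)_test −
(Ct_target − Ct_ref)_control.

## Target prediction

The duplex penalty follows the standard plant scheme: mismatch 1, G:U
wobble 0.5, bulged nucleotide 2, with penalties at miRNA positions 2–13
doubled; default cutoff 4.0, chosen to match the mismatch cap used in
degradome validation so one scoring scale serves both stages. At most one
bulge (≤ 2 nt, either strand) keeps the alignment space exhaustively
enumerable: the scanner scores every transcript window at every admissible
site length with a vectorised penalty computation, and the tests hold it
to a brute-force per-window oracle. Overlapping sites of one miRNA on one
transcript merge to the lowest penalty. Regulation mode is `cleavage` iff
miRNA positions 9–11 are all Watson–Crick paired (window configurable);
anything weaker in the centre is `translational_repression`. This is a
deliberate operationalisation of the qualitative cleavage/translation
distinction; it is not a thermodynamic model.

## Degradome validation

Tags (≥ 15 nt) are matched exactly, sense strand, to transcripts; each
match start increments that transcript's 5′-end profile. The cleavage
position of a duplex is the transcript coordinate opposite miRNA position
10 (1-based: site_start + site_length − 9). A candidate interaction
validates when a duplex site under the penalty cap carries nonzero tag
count at its cleavage position and the add-one-smoothed shuffle p-value
(k+1)/(n+1) over n = 100 dinucleotide shuffles of the *miRNA* is ≤ 0.05
(inclusive). Shuffling the miRNA rather than the transcript is the cheaper
and more common duplex-significance null; it answers "could a random
sequence of this composition hit an equally supported site here". The
shuffle itself is the Altschul–Erickson Eulerian-path construction, so
every draw preserves the dinucleotide multiset exactly (asserted per draw
in the tests). Peak categories follow the five-category PARE convention:
0 unique maximum (> 1 tag), 1 tied maximum, 2 above the mean of occupied
positions, 3 at or below it, 4 singleton; the mean is taken over occupied
positions so empty stretches of long transcripts do not dilute it.

## Synthetic data

The generator exists so that every stage has planted ground truth.

- **Precursors** are perfect inverted repeats (arm 32–43 nt, AU-rich loop
  8–11 nt, total 70–101 nt) rejection-sampled against the pipeline's own
  fold-and-screen contract — the single mechanism that guarantees truth
  and detection criteria cannot drift apart. Decoys are random non-hairpin
  sequences verified to fail the same screen. Both are placed on either
  strand at non-overlapping genomic positions with ≥ 30 nt spacing.
- **Abundances**: base wild-type RPM log-uniform on [100, 2000]; planted
  log₂ fold changes cycle over (+2, −2), (0, 0), (−2, +2) for the two
  contrasts, so both mutants carry up-, down- and unchanged miRNAs. The
  truth table stores abundances and fold changes consistently to 10⁻¹².
- **Counts** are negative-binomial with Var = μ + d·μ², default d = 0:
  a single sequenced library is a sampling draw, for which Poisson is the
  realistic model; the dispersion knob exists to study overdispersion.
  In `counts_only` mode the nominal depth serves as the RPM denominator,
  which keeps fold-change recovery free of the compositional bias that
  genotype-specific abundance shifts would otherwise induce.
- **Read classes**: mature (+ adapter), star reads at 5% of mature
  abundance for a few known precursors, decoy-locus reads, contaminant
  fragments (5% of depth, starts discretised to keep the unique-tag space
  small), adapterless junk (2%), poly(A) reads (1%) and length outliers
  (2%) — one class per cleaning filter. A single configurable TruSeq-style
  3′ adapter is appended; per-cycle error profiles are not simulated.
- **Targets** are planted as reverse-complement sites modified to exact
  penalties {0, 2, 3.5} (mismatch at position 5; mismatch at 16 plus a
  peripheral wobble), or a central mismatch at position 10 for a planted
  translational-repression case. Degradome tags are 20 nt (typical PARE
  length); a configurable fraction (default 0.8) of a cleaved transcript's
  tags start exactly at the planted cleavage position, the rest uniformly
  elsewhere.

What the synthetic universe does **not** emulate: sequencing error,
isomiR heterogeneity, multi-locus miRNA families with divergent members,
expression-dependent folding artifacts, or realistic transcriptome-wide
tag backgrounds. Passing the synthetic-recovery tests therefore
demonstrates correctness of the algorithms under their stated models, not
performance on real libraries.

## Problem sizes and determinism

The recovery benchmark plants 20 catalog + 5 novel miRNAs and 20 decoys
and simulates 10⁵ reads per library end to end; fold-change recovery runs
at the count level with 10⁶ reads per library, where features with
expected RPM ≥ 50 on both sides of a contrast recover their planted log₂
fold change with per-group mean error well inside ±0.15. Null
calibrations use 500 Poisson features (count test) and 200 random
miRNA/transcript pairs (shuffle test), both holding empirical rejection at
nominal α = 0.05 under 7.5%. All randomness flows from explicit seeds
through `numpy.random.default_rng`; reruns with one seed are byte-identical,
including FASTA/FASTQ output.

## Known limitations

- Exact-match genomic mapping only (no mismatched or spliced alignment);
  multi-mappers capped at 20 loci per tag.
- The simplified folding backend is a development aid, not a thermodynamic
  model.
- The count test assumes independent sampling within each library; with
  real biological replication a dispersion-modelling framework would be
  the right tool, and this package deliberately does not provide one.
- Degradome matching is transcript-set based; genome-wide degradome
  mapping and T-plots are out of scope.
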