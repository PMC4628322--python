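"""Predict miRNA target sites and validate cleavage with degradome tags.

Target scanning uses the plant penalty scheme (mismatch 1, G:U wobble 0.5,
bulge 2, positions 2-13 doubled, cutoff 4.0); degradome validation demands
tag signal at the position opposite miRNA position 10 and significance
against 100 dinucleotide-shuffled miRNAs.
"""

from apexmir.degradome import build_profile, validate_interaction
from apexmir.simulate import build_reference, simulate_degradome
from apexmir.targets import classify_mode, find_targets

ref = build_reference(n_known=5, n_novel=3, n_decoys=5, seed=42)
truth = ref.truth
by_name = {p.name: p for p in truth.planted_mirnas}

print("planted site -> prediction:")
for planted in truth.planted_targets:
    mirna = by_name[planted.mirna]
    hits = find_targets(mirna.name, mirna.mature, ref.transcripts, cutoff=4.0)
    hit = next(h for h in hits if h.transcript_id == planted.transcript_id)
    classify_mode(hit)
    print(f"  {mirna.name} x {planted.transcript_id}: site {hit.start}-{hit.end}, "
          f"penalty {hit.penalty:.1f} (planted {planted.penalty:.1f}), {hit.mode}")

tags = simulate_degradome(ref, depth=10_000, signal_fraction=0.8, seed=7)
profiles = build_profile(tags, ref.transcripts)
print("\ndegradome validation (cleavage opposite miRNA position 10):")
for planted in truth.planted_targets:
    mirna = by_name[planted.mirna]
    res = validate_interaction(
        mirna.name, mirna.mature, planted.transcript_id,
        ref.transcripts[planted.transcript_id], profiles, seed=1,
    )
    if isinstance(res, str):
        print(f"  {mirna.name} x {planted.transcript_id}: {res}")
    else:
        print(f"  {mirna.name} x {planted.transcript_id}: cleavage at "
              f"{res.cleavage_position}, peak {res.peak_count} tags, "
              f"category {res.category}, shuffle p = {res.shuffle_p:.3f}")
print("\nCategory 0 means the tag pile-up at the cleavage site is the "
      "transcript's unique maximum — the classic signature of miRNA-guided "
      "cleavage. The translational-repression site carries no planted "
      "cleavage signal: any validation it achieves rides on scattered noise "
      "tags and lands in a weak peak category (2-4), which is how real "
      "degradome analyses down-weight such calls.")
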