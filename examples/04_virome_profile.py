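"""Virome profiling: rarefied abundances and SNV analysis.

Takes a contigs x samples read-count table, rarefies every sample to a
common depth (mean of repeated subsampling without replacement),
length-normalizes into relative abundances, then calls and classifies
single-nucleotide variants from a simulated pileup with planted
variants of known frequency.
"""

import pandas as pd

from characlock import (
    CountTable,
    OrfAnnotation,
    RarefactionConfig,
    call_snvs,
    classify_all,
    normalize_abundance,
    rarefy,
    snv_summary,
)
from characlock.simulate import random_genome, simulate_pileup

# --- abundance ---------------------------------------------------------
counts = pd.DataFrame(
    {"protected1": [5200, 300, 900], "protected2": [2100, 150, 420],
     "urban": [800, 2500, 120]},
    index=["chara_contig", "other_virus", "phage"],
)
table = CountTable(counts, pd.Series([9593, 4200, 1500], index=counts.index))
cfg = RarefactionConfig(depth=int(table.sample_totals.min()),
                        iterations=200, seed=42)
abundance = normalize_abundance(rarefy(table, cfg), table.lengths)
print("rarefied, length-normalized relative abundance:")
print(abundance.round(1))
# Counts are comparable across samples after rarefying to the shallowest
# library; dividing by relative contig size removes the advantage long
# contigs have at recruiting reads.

# --- SNVs --------------------------------------------------------------
genome = random_genome(600, seed=3, genome_id="chara_contig")
orfs = [OrfAnnotation("chara_contig", "Rep", 1, 450)]
variants = []
for pos, freq in ((30, 0.08), (123, 0.35), (310, 0.65), (500, 0.12)):
    ref = genome.seq[pos - 1]
    alt = {"A": "G", "G": "A", "C": "T", "T": "C"}[ref]
    variants.append((pos, alt, freq))
pileup, truth = simulate_pileup(genome, orfs, variants, depth=250, seed=9)

records = classify_all(call_snvs(pileup, min_count=2), orfs, genome)
print(f"\ncalled {len(records)} SNVs (min alt count 2):")
for r in records:
    print(f"  pos {r.pos:>3} {r.ref}->{r.alt} freq {r.frequency:.2f} "
          f"{r.effect}")

summary = snv_summary(records, orfs)
print("\nper-region summary:")
print(summary.per_orf)
print(f"fraction nonsynonymous: {summary.fraction_nonsynonymous:.2f}; "
      f"median frequency {summary.median_frequency:.2f} "
      f"(infrequent: {summary.infrequent})")
# Low-frequency, mostly non-synonymous variants are the signature of a
# diverse, unfixed virus population (a quasispecies-like cloud).
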