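"""Pairwise genome comparison: ORFs, identity, composition.

Builds a synthetic virus genome, derives a diverged sibling by planting
mutations at different rates per ORF, and compares the two the way two
charavirus genomes would be: per-ORF and concatenated nt/aa identity,
base composition, and a sliding-window identity track.
"""

import warnings

import numpy as np

# random synthetic sequence inevitably contains in-frame stops
warnings.filterwarnings("ignore", message="internal stop codon")

from characlock import (
    GenomeRecord,
    OrfAnnotation,
    composition,
    concat_orf_identity,
    extract_orf,
    sliding_identity,
)
from characlock.simulate import random_genome

rng = np.random.default_rng(7)

# A 3.3-kb genome with two ORFs ("Rep"-like and "CP"-like).
genome_a = random_genome(3300, seed=7, genome_id="virusA", gc=0.46)
orfs_a = [OrfAnnotation("virusA", "Rep", 31, 2130),
          OrfAnnotation("virusA", "CP", 2201, 3100)]

# Sibling genome: 12% of Rep sites and 5% of CP sites mutated.
seq_b = list(genome_a.seq)
for orf, rate in zip(orfs_a, (0.12, 0.05)):
    sites = rng.choice(np.arange(orf.start - 1, orf.end),
                       size=round(orf.length * rate), replace=False)
    for i in sites:
        seq_b[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[seq_b[i]]
genome_b = GenomeRecord("virusB", "".join(seq_b))
orfs_b = [OrfAnnotation("virusB", o.name, o.start, o.end) for o in orfs_a]

frac = composition(genome_a)
print(f"virusA: {len(genome_a)} nt, G+C {100 * frac['GC']:.1f}%, "
      f"G {100 * frac['G']:.1f}%")
nt, prot = extract_orf(genome_a, orfs_a[0])
print(f"Rep ORF nt {orfs_a[0].start}-{orfs_a[0].end}: {len(nt)} nt "
      f"-> {len(prot)} aa")

cmp = concat_orf_identity(genome_a, orfs_a, genome_b, orfs_b)
print("\nper-ORF identity (percent):")
print(cmp.per_orf[["nt_identity", "aa_identity", "aa_similarity"]])
print(f"concatenated ORFs: nt {cmp.concat_nt_identity}%, "
      f"aa {cmp.concat_aa_identity}%")
# The CP, mutated least, is the most conserved ORF — the pattern seen
# between real charavirus genomes, where CP identity exceeds Rep/MP.

track = sliding_identity(genome_a, genome_b, window=300, step=150)
print("\nsliding identity (300-nt windows):")
print(track.head(8).to_string(index=False))
# The track dips over the fast-evolving Rep region and recovers over
# the conserved CP — the numeric stand-in for a similarity panel.
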