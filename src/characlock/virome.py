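"""Virome abundance profiling and single-nucleotide-variant analysis.

Read mapping is upstream of this module: it consumes (i) a contigs x
samples table of mapped-read counts with contig lengths, and (ii)
per-position base-count pileups over a reference genome. On those it
performs the two bespoke steps of a freshwater-virome profile:

* rarefied, length-normalized relative abundance — every sample is
  repeatedly subsampled without replacement to a common depth
  (multivariate hypergeometric draws, mean over iterations) and counts
  are scaled by contig size relative to the average contig;
* quality-thresholded SNV calling (minimum alternative-base read count,
  default 2) with synonymous/non-synonymous classification against the
  reference ORF map, and a per-ORF summary with a variant-frequency
  spectrum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .genome import GenomeRecord, OrfAnnotation

__all__ = [
    "CountTable",
    "RarefactionConfig",
    "PileupColumn",
    "SNVRecord",
    "SnvSummary",
    "rarefy",
    "normalize_abundance",
    "call_snvs",
    "classify_snv",
    "classify_all",
    "snv_summary",
    "read_pileup_tsv",
    "write_pileup_tsv",
]

_BASES = ("A", "C", "G", "T")
FREQ_BINS = np.linspace(0.0, 1.0, 11)  # ten equal bins: 0-0.1, ..., 0.9-1.0


# ---------------------------------------------------------------------------
# abundance
# ---------------------------------------------------------------------------

@dataclass
class CountTable:
    """Mapped-read counts (contigs x samples) plus contig lengths (nt)."""

    counts: pd.DataFrame          # index: contig ids, columns: sample ids
    lengths: pd.Series            # index: contig ids

    def __post_init__(self):
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("read counts must be non-negative")
        if not np.array_equal(c.to_numpy(), c.to_numpy().astype(np.int64)):
            raise ValueError("read counts must be integers")
        self.counts = c.astype(np.int64)
        self.lengths = self.lengths.reindex(c.index)
        if self.lengths.isna().any():
            missing = self.lengths[self.lengths.isna()].index.tolist()
            raise ValueError(f"missing lengths for contigs: {missing}")
        if (self.lengths <= 0).any():
            raise ValueError("contig lengths must be positive")

    @property
    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        """TSV layout: contig, length, then one column per sample."""
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(counts=df.drop(columns=df.columns[0]),
                   lengths=df[df.columns[0]])


@dataclass(frozen=True)
class RarefactionConfig:
    """Subsampling depth (reads), iteration count and seed.

    The motivating study rarefied every sample to its smallest library
    (158,376 reads) with 1000 iterations; those are the defaults.
    """

    depth: int = 158_376
    iterations: int = 1000
    seed: int | None = None
    strict: bool = True

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


def rarefy(table: CountTable, cfg: RarefactionConfig,
           return_iterations: bool = False):
    """Rarefy each sample to a common depth without replacement.

    Each iteration draws ``cfg.depth`` reads per sample from its contig
    counts (multivariate hypergeometric), so per-iteration column sums
    equal the depth exactly; the returned table is the per-cell mean
    over iterations. In strict mode a sample with fewer reads than the
    depth raises; otherwise it is dropped with a warning. Reproducible
    under ``cfg.seed``.

    With ``return_iterations=True`` also returns the raw draws as an
    (iterations, contigs, samples) integer array for dispersion work.
    """
    totals = table.sample_totals
    shallow = totals[totals < cfg.depth].index.tolist()
    counts = table.counts
    if shallow:
        if cfg.strict:
            raise ValueError(
                f"samples below rarefaction depth {cfg.depth}: {shallow}"
            )
        warnings.warn(f"dropping samples below depth: {shallow}", stacklevel=2)
        counts = counts.drop(columns=shallow)
    rng = np.random.default_rng(cfg.seed)
    draws = np.empty((cfg.iterations, counts.shape[0], counts.shape[1]),
                     dtype=np.int64)
    for j, sample in enumerate(counts.columns):
        colors = counts[sample].to_numpy()
        for it in range(cfg.iterations):
            draws[it, :, j] = rng.multivariate_hypergeometric(
                colors, cfg.depth)
    mean = pd.DataFrame(draws.mean(axis=0), index=counts.index,
                        columns=counts.columns)
    if return_iterations:
        return mean, draws
    return mean


def normalize_abundance(rarefied: pd.DataFrame, lengths: pd.Series,
                        mode: str = "relative_size") -> pd.DataFrame:
    """Length-normalize rarefied counts into relative abundances.

    ``mode='relative_size'`` (default) divides each contig's counts by
    its length relative to the mean contig length — a contig twice the
    average length gets half the abundance for the same reads.
    ``mode='mean_length'`` instead divides every count uniformly by the
    mean contig length (the alternative reading of "reads divided by
    the average contig size").
    """
    lens = lengths.reindex(rarefied.index)
    if lens.isna().any() or (lens <= 0).any():
        raise ValueError("every contig needs a positive length")
    mean_len = float(lens.mean())
    if mode == "relative_size":
        return rarefied.div(lens / mean_len, axis=0)
    if mode == "mean_length":
        return rarefied / mean_len
    raise ValueError("mode must be 'relative_size' or 'mean_length'")


# ---------------------------------------------------------------------------
# pileups and SNVs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PileupColumn:
    """Base counts at one 1-based reference position."""

    contig: str
    pos: int
    ref: str
    a: int = 0
    c: int = 0
    g: int = 0
    t: int = 0
    deletion: int = 0

    def __post_init__(self):
        if self.ref not in _BASES + ("N",):
            raise ValueError(f"invalid reference base {self.ref!r}")
        if min(self.a, self.c, self.g, self.t, self.deletion) < 0:
            raise ValueError("negative base count")

    @property
    def depth(self) -> int:
        return self.a + self.c + self.g + self.t + self.deletion

    def count(self, base: str) -> int:
        return {"A": self.a, "C": self.c, "G": self.g, "T": self.t,
                "-": self.deletion}[base]


@dataclass(frozen=True)
class SNVRecord:
    """A called variant; ``alt='-'`` marks a deletion (never classified)."""

    contig: str
    pos: int
    ref: str
    alt: str
    alt_count: int
    depth: int
    effect: str | None = None       # synonymous | nonsynonymous | noncoding
    orf_name: str | None = None
    codon_index: int | None = None  # 0-based codon within the ORF

    def __post_init__(self):
        if self.alt == self.ref:
            raise ValueError("alt equals ref")
        if not (0 < self.alt_count <= self.depth):
            raise ValueError("alt count must be in (0, depth]")

    @property
    def frequency(self) -> float:
        return self.alt_count / self.depth

    @property
    def is_deletion(self) -> bool:
        return self.alt == "-"


def call_snvs(pileup, min_count: int = 2) -> list[SNVRecord]:
    """Emit one record per non-reference base with count >= ``min_count``.

    Multiple alternative bases at a position produce multiple records;
    deletions are reported (``alt='-'``) but never classified
    synonymous/non-synonymous. Zero-depth columns are skipped with a
    warning. The default threshold of 2 reads mirrors quality-based
    variant detection with a minimum read count of two.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    out: list[SNVRecord] = []
    for col in pileup:
        if col.depth == 0:
            warnings.warn(
                f"zero-depth pileup column at {col.contig}:{col.pos}",
                stacklevel=2,
            )
            continue
        for base in _BASES + ("-",):
            if base == col.ref:
                continue
            n = col.count(base)
            if n >= min_count:
                out.append(SNVRecord(
                    contig=col.contig, pos=col.pos, ref=col.ref, alt=base,
                    alt_count=n, depth=col.depth,
                ))
    return out


def classify_snv(snv: SNVRecord, orfs, genome: GenomeRecord) -> SNVRecord:
    """Annotate a variant's coding effect against the reference ORFs.

    Inside an ORF, the alternative base is substituted into its codon
    and both codons translated with the standard genetic code: same
    amino acid -> synonymous, different -> nonsynonymous. Positions
    outside every ORF (or in a trailing incomplete codon of a truncated
    ORF) are noncoding. Deletions keep ``effect=None``.
    """
    if snv.pos > len(genome):
        raise ValueError(
            f"position {snv.pos} beyond genome length {len(genome)}"
        )
    if snv.is_deletion:
        return snv
    for orf in orfs:
        if not orf.contains(snv.pos):
            continue
        offset = snv.pos - orf.start
        codon_index = offset // 3
        codon_start = orf.start + 3 * codon_index  # 1-based
        if codon_start + 2 > min(orf.end, len(genome)):
            break  # trailing incomplete codon: treat as noncoding
        codon = genome.seq[codon_start - 1:codon_start + 2]
        within = snv.pos - codon_start
        alt_codon = codon[:within] + snv.alt + codon[within + 1:]
        same = str(Seq(codon).translate()) == str(Seq(alt_codon).translate())
        return replace(snv, effect="synonymous" if same else "nonsynonymous",
                       orf_name=orf.name, codon_index=codon_index)
    return replace(snv, effect="noncoding")


def classify_all(records, orfs, genome: GenomeRecord) -> list[SNVRecord]:
    return [classify_snv(r, orfs, genome) for r in records]


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

@dataclass
class SnvSummary:
    """Per-ORF variant counts, nonsynonymous fractions and spectrum.

    ``infrequent`` is True when the median variant frequency is below
    0.5 — the documented rule for "most variants are not fixed".
    """

    per_orf: pd.DataFrame
    spectrum: pd.DataFrame
    fraction_nonsynonymous: float | None
    median_frequency: float | None

    @property
    def infrequent(self) -> bool | None:
        if self.median_frequency is None:
            return None
        return self.median_frequency < 0.5


def snv_summary(records, orfs) -> SnvSummary:
    """Summarise classified variants per ORF plus a frequency spectrum.

    The spectrum uses ten equal frequency bins (0-0.1 ... 0.9-1.0, the
    last bin closed at 1). Deletions count towards totals but not the
    synonymous/nonsynonymous fractions. Empty input yields empty tables.
    """
    categories = [o.name for o in orfs] + ["noncoding"]
    rows = []
    classified = [r for r in records if r.effect in
                  ("synonymous", "nonsynonymous")]
    for cat in categories:
        if cat == "noncoding":
            sub = [r for r in records if r.effect == "noncoding"]
        else:
            sub = [r for r in records if r.orf_name == cat]
        n_syn = sum(r.effect == "synonymous" for r in sub)
        n_non = sum(r.effect == "nonsynonymous" for r in sub)
        rows.append({
            "region": cat, "n_snvs": len(sub), "n_synonymous": n_syn,
            "n_nonsynonymous": n_non,
            "fraction_nonsynonymous":
                n_non / (n_syn + n_non) if (n_syn + n_non) else np.nan,
        })
    per_orf = pd.DataFrame(rows).set_index("region")
    if per_orf["n_snvs"].sum() == 0 and not records:
        per_orf = per_orf.iloc[0:0]
    freqs = np.array([r.frequency for r in records])
    hist, _ = (np.histogram(freqs, bins=FREQ_BINS) if freqs.size
               else (np.zeros(10, dtype=int), None))
    spectrum = pd.DataFrame({
        "bin_low": FREQ_BINS[:-1], "bin_high": FREQ_BINS[1:], "count": hist,
    })
    frac_non = (sum(r.effect == "nonsynonymous" for r in classified)
                / len(classified)) if classified else None
    med = float(np.median(freqs)) if freqs.size else None
    return SnvSummary(per_orf=per_orf, spectrum=spectrum,
                      fraction_nonsynonymous=frac_non, median_frequency=med)


# ---------------------------------------------------------------------------
# pileup TSV I/O (samtools-style converted upstream)
# ---------------------------------------------------------------------------

def read_pileup_tsv(path) -> list[PileupColumn]:
    """Read a pileup TSV: contig, pos, ref, A, C, G, T, del."""
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    return [
        PileupColumn(contig=str(r[cols[0]]), pos=int(r[cols[1]]),
                     ref=str(r[cols[2]]).upper(), a=int(r[cols[3]]),
                     c=int(r[cols[4]]), g=int(r[cols[5]]),
                     t=int(r[cols[6]]), deletion=int(r[cols[7]]))
        for _, r in df.iterrows()
    ]


def write_pileup_tsv(pileup, path) -> None:
    pd.DataFrame([
        {"contig": p.contig, "pos": p.pos, "ref": p.ref, "A": p.a,
         "C": p.c, "G": p.g, "T": p.t, "del": p.deletion}
        for p in pileup
    ]).to_csv(path, sep="\t", index=False)
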