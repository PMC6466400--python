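"""Genome architecture and pairwise comparison statistics.

Handles the per-genome bookkeeping of a small positive-sense ssRNA virus
genome — ORF extraction and translation, base composition — and the
pairwise statistics used to compare two such genomes: global
Needleman-Wunsch percent identity at the nucleotide and amino-acid
level, per-ORF and concatenated-ORF identity, and a sliding-window
identity track over a single global alignment (a lightweight stand-in
for an mVISTA/LAGAN similarity panel).

Coordinates are 1-based and inclusive throughout, matching the
conventional "nt 276 to 7007" style of virus genome annotations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "GenomeRecord",
    "OrfAnnotation",
    "IdentityReport",
    "AlignmentScoring",
    "extract_orf",
    "pairwise_identity",
    "composition",
    "concat_orf_identity",
    "sliding_identity",
    "read_orf_table",
]

_NT = set("ACGTN")
GAP = "-"


@dataclass(frozen=True)
class GenomeRecord:
    """A positive-strand nucleotide sequence (A/C/G/T/N)."""

    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise ValueError("empty genome sequence")
        bad = set(self.seq) - _NT
        if bad:
            raise ValueError(f"invalid bases in {self.id}: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.seq)

    @classmethod
    def from_fasta(cls, path) -> list["GenomeRecord"]:
        from Bio import SeqIO

        return [cls(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


@dataclass(frozen=True)
class OrfAnnotation:
    """An ORF by 1-based inclusive coordinates on the positive strand.

    ``incomplete`` marks annotated-incomplete ORFs whose span need not
    be a codon multiple (e.g. a coat-protein gene truncated by an
    incomplete assembly 3' terminus).
    """

    genome_id: str
    name: str
    start: int
    end: int
    incomplete: bool = False

    def __post_init__(self):
        if not (1 <= self.start < self.end):
            raise ValueError(f"ORF {self.name}: need 1 <= start < end")
        if (self.end - self.start + 1) % 3 != 0 and not self.incomplete:
            raise ValueError(
                f"ORF {self.name}: span {self.length} nt is not a codon "
                "multiple; set incomplete=True if annotated as partial"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end


def read_orf_table(path) -> list[OrfAnnotation]:
    """Read a BED-like TSV: genome_id, name, start, end[, incomplete]."""
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, row in df.iterrows():
        out.append(OrfAnnotation(
            genome_id=str(row.iloc[0]), name=str(row.iloc[1]),
            start=int(row.iloc[2]), end=int(row.iloc[3]),
            incomplete=bool(row.iloc[4]) if len(row) > 4 else False,
        ))
    return out


def extract_orf(genome: GenomeRecord, orf: OrfAnnotation):
    """Extract an ORF's nucleotides and translation.

    Returns ``(nt_seq, protein)``. Translation uses the standard genetic
    code; a trailing stop is removed and an internal stop triggers a
    warning (it stays in the protein as '*'). An ORF running past the
    genome end raises; an annotated-incomplete ORF may be clamped first
    with :func:`clamp_orf`.
    """
    if orf.end > len(genome):
        raise ValueError(
            f"ORF {orf.name} ({orf.start}-{orf.end}) exceeds genome "
            f"{genome.id} length {len(genome)}"
        )
    nt = genome.seq[orf.start - 1:orf.end]
    trimmed = nt[:len(nt) - len(nt) % 3]
    protein = str(Seq(trimmed).translate())
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        warnings.warn(
            f"internal stop codon in ORF {orf.name} of {genome.id}",
            stacklevel=2,
        )
    return nt, protein


def clamp_orf(orf: OrfAnnotation, genome: GenomeRecord) -> OrfAnnotation:
    """Clamp an incomplete ORF's end to the genome length."""
    if orf.end <= len(genome):
        return orf
    return OrfAnnotation(orf.genome_id, orf.name, orf.start, len(genome),
                         incomplete=True)


# ---------------------------------------------------------------------------
# composition
# ---------------------------------------------------------------------------

def composition(genome: GenomeRecord) -> dict:
    """Base fractions over non-N positions, plus G+C.

    Returns ``{'A':..,'C':..,'G':..,'T':..,'GC':..,'n_used':..}`` with
    A+C+G+T summing to 1 and GC = G + C exactly.
    """
    counts = {b: genome.seq.count(b) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"genome {genome.id} has no unambiguous bases")
    frac = {b: counts[b] / total for b in "ACGT"}
    frac["GC"] = frac["G"] + frac["C"]
    frac["n_used"] = total
    return frac


# ---------------------------------------------------------------------------
# pairwise alignment and identity
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignmentScoring:
    """Global-alignment scoring defaults.

    Nucleotide: match +2 / mismatch -3, first gap position -5, each
    further gap position -2. Amino acid: BLOSUM62, first gap -11,
    extension -1. Documented so published identities, which depend on
    the aligner's conventions, can be reproduced or re-parameterised.
    """

    nt_match: float = 2.0
    nt_mismatch: float = -3.0
    nt_gap_open: float = -5.0
    nt_gap_extend: float = -2.0
    aa_matrix: str = "BLOSUM62"
    aa_gap_open: float = -11.0
    aa_gap_extend: float = -1.0

    def aligner(self, alphabet: str) -> PairwiseAligner:
        al = PairwiseAligner()
        al.mode = "global"
        if alphabet == "nt":
            al.match_score = self.nt_match
            al.mismatch_score = self.nt_mismatch
            al.open_gap_score = self.nt_gap_open
            al.extend_gap_score = self.nt_gap_extend
        elif alphabet == "aa":
            al.substitution_matrix = substitution_matrices.load(self.aa_matrix)
            al.open_gap_score = self.aa_gap_open
            al.extend_gap_score = self.aa_gap_extend
        else:
            raise ValueError("alphabet must be 'nt' or 'aa'")
        return al


DEFAULT_SCORING = AlignmentScoring()


@dataclass(frozen=True)
class IdentityReport:
    """Percent identity/similarity of one pairwise comparison.

    Percentages are reported to one decimal place. ``aa_similarity``
    (identical or positive substitution-matrix score) is only defined
    for amino-acid comparisons and always >= ``aa_identity``.
    ``aligned_length`` counts alignment columns inside the terminal-gap
    -trimmed core; ``gap_columns`` the gapped columns among them.
    """

    nt_identity: float | None = None
    aa_identity: float | None = None
    aa_similarity: float | None = None
    aligned_length: int = 0
    gap_columns: int = 0

    @property
    def identity(self) -> float:
        val = self.nt_identity if self.nt_identity is not None else self.aa_identity
        if val is None:
            raise ValueError("no identity recorded")
        return val


def _align_rows(a: str, b: str, alphabet: str,
                scoring: AlignmentScoring) -> tuple[str, str]:
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aln = scoring.aligner(alphabet).align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _core_range(ra: str, rb: str) -> tuple[int, int]:
    """Columns [first, last] excluding terminal-gap overhangs."""
    ncol = len(ra)
    first = 0
    while first < ncol and (ra[first] == GAP or rb[first] == GAP):
        first += 1
    last = ncol - 1
    while last >= 0 and (ra[last] == GAP or rb[last] == GAP):
        last -= 1
    if first > last:  # no doubly-aligned column; fall back to everything
        return 0, ncol - 1
    return first, last


def _column_identity(ra: str, rb: str, denominator: str,
                     sim_matrix=None) -> tuple[float, float | None, int, int]:
    first, last = _core_range(ra, rb)
    ident = similar = denom = gaps = 0
    for i in range(first, last + 1):
        x, y = ra[i], rb[i]
        if x == GAP and y == GAP:
            continue
        gapped = x == GAP or y == GAP
        if gapped:
            gaps += 1
        if denominator == "ungapped" and gapped:
            continue
        denom += 1
        if not gapped and x == y:
            ident += 1
            similar += 1
        elif not gapped and sim_matrix is not None:
            try:
                if sim_matrix[x, y] > 0:
                    similar += 1
            except (KeyError, IndexError):
                pass
    if denom == 0:
        raise ValueError("alignment has no scorable columns")
    pid = round(100.0 * ident / denom, 1)
    psim = round(100.0 * similar / denom, 1) if sim_matrix is not None else None
    return pid, psim, last - first + 1, gaps


def pairwise_identity(a: str, b: str, alphabet: str = "nt",
                      scoring: AlignmentScoring = DEFAULT_SCORING,
                      denominator: str = "any_nongap") -> IdentityReport:
    """Global-alignment percent identity between two sequences.

    ``denominator='any_nongap'`` (default) counts every core column
    where at least one sequence is non-gap, approximating the BioEdit
    convention; ``'ungapped'`` restricts to columns where both are
    non-gap. Terminal-gap overhangs (e.g. a 3'-truncated coat protein)
    are excluded from the denominator either way.
    """
    if denominator not in ("any_nongap", "ungapped"):
        raise ValueError("denominator must be 'any_nongap' or 'ungapped'")
    ra, rb = _align_rows(a, b, alphabet, scoring)
    sim = (substitution_matrices.load(scoring.aa_matrix)
           if alphabet == "aa" else None)
    pid, psim, ncol, gaps = _column_identity(ra, rb, denominator, sim)
    if alphabet == "nt":
        return IdentityReport(nt_identity=pid, aligned_length=ncol,
                              gap_columns=gaps)
    return IdentityReport(aa_identity=pid, aa_similarity=psim,
                          aligned_length=ncol, gap_columns=gaps)


# ---------------------------------------------------------------------------
# concatenated / per-ORF comparison
# ---------------------------------------------------------------------------

@dataclass
class OrfComparison:
    """Per-ORF and concatenated identity between two annotated genomes."""

    per_orf: pd.DataFrame        # index: ORF name; nt/aa identity columns
    concat_nt_identity: float
    concat_aa_identity: float
    mean_nt_identity: float      # aligned-length-weighted mean over ORFs
    mean_aa_identity: float


def concat_orf_identity(genome_a: GenomeRecord, orfs_a,
                        genome_b: GenomeRecord, orfs_b,
                        scoring: AlignmentScoring = DEFAULT_SCORING,
                        denominator: str = "any_nongap") -> OrfComparison:
    """Compare two genomes ORF by ORF and over their concatenated ORFs.

    Both genomes must carry the same ORF names. The primary summary is
    the identity of the concatenated ORF sequences
    (concatenate-then-align); the aligned-length-weighted mean of the
    per-ORF identities is reported alongside as the breakdown.
    """
    map_a = {o.name: clamp_orf(o, genome_a) for o in orfs_a}
    map_b = {o.name: clamp_orf(o, genome_b) for o in orfs_b}
    if set(map_a) != set(map_b):
        raise ValueError(
            f"ORF sets differ: {sorted(set(map_a) ^ set(map_b))}"
        )
    names = [o.name for o in orfs_a]
    rows, cat_nt_a, cat_nt_b, cat_aa_a, cat_aa_b = [], [], [], [], []
    for name in names:
        nt_a, aa_a = extract_orf(genome_a, map_a[name])
        nt_b, aa_b = extract_orf(genome_b, map_b[name])
        rep_nt = pairwise_identity(nt_a, nt_b, "nt", scoring, denominator)
        rep_aa = pairwise_identity(aa_a, aa_b, "aa", scoring, denominator)
        rows.append({
            "orf": name,
            "nt_identity": rep_nt.nt_identity,
            "aa_identity": rep_aa.aa_identity,
            "aa_similarity": rep_aa.aa_similarity,
            "nt_aligned_length": rep_nt.aligned_length,
            "aa_aligned_length": rep_aa.aligned_length,
        })
        cat_nt_a.append(nt_a); cat_nt_b.append(nt_b)
        cat_aa_a.append(aa_a); cat_aa_b.append(aa_b)
    table = pd.DataFrame(rows).set_index("orf")
    concat_nt = pairwise_identity("".join(cat_nt_a), "".join(cat_nt_b),
                                  "nt", scoring, denominator).nt_identity
    concat_aa = pairwise_identity("".join(cat_aa_a), "".join(cat_aa_b),
                                  "aa", scoring, denominator).aa_identity
    w_nt = table["nt_aligned_length"].to_numpy(float)
    w_aa = table["aa_aligned_length"].to_numpy(float)
    mean_nt = round(float(np.average(table["nt_identity"], weights=w_nt)), 1)
    mean_aa = round(float(np.average(table["aa_identity"], weights=w_aa)), 1)
    return OrfComparison(per_orf=table, concat_nt_identity=concat_nt,
                         concat_aa_identity=concat_aa,
                         mean_nt_identity=mean_nt, mean_aa_identity=mean_aa)


# ---------------------------------------------------------------------------
# sliding-window identity
# ---------------------------------------------------------------------------

def sliding_identity(a: GenomeRecord, b: GenomeRecord, window: int,
                     step: int,
                     scoring: AlignmentScoring = DEFAULT_SCORING) -> pd.DataFrame:
    """Percent identity per window over one global nucleotide alignment.

    Returns a DataFrame with the 1-based start column of each window and
    its percent identity in [0, 100]; the window slides over alignment
    columns, so indels depress identity locally.
    """
    if not (window >= step >= 1):
        raise ValueError("need window >= step >= 1")
    ra, rb = _align_rows(a.seq, b.seq, "nt", scoring)
    ncol = len(ra)
    if window > ncol:
        raise ValueError(f"window {window} exceeds alignment length {ncol}")
    starts, values = [], []
    for s in range(0, ncol - window + 1, step):
        ident = denom = 0
        for i in range(s, s + window):
            if ra[i] == GAP and rb[i] == GAP:
                continue
            denom += 1
            if ra[i] == rb[i]:
                ident += 1
        starts.append(s + 1)
        values.append(100.0 * ident / denom if denom else np.nan)
    return pd.DataFrame({"column_start": starts, "percent_identity": values})
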