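"""K-mer composition profiles and correspondence analysis.

Small RNA virus genomes tend to mirror the oligonucleotide composition
of their hosts (a signature usually attributed to adaptation to the
host tRNA pool), so genes from viruses sharing a host cluster together
when their k-mer count tables are ordinated. This module counts
overlapping k-mers (k = 2..7, tetranucleotides by default) on the
coding strand and runs correspondence analysis (CA) on the resulting
sequences x k-mers contingency table.

CA is computed from first principles — the SVD of the chi-square
standardized residual matrix — so its conventions (axis ordering, sign
fixing, inertia accounting) are explicit and testable.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "KmerProfile",
    "CaResult",
    "kmer_order",
    "count_kmers",
    "profile_table",
    "correspondence_analysis",
    "group_cohesion",
]

_BASES = "ACGT"
MIN_K, MAX_K = 2, 7


def kmer_order(k: int) -> list[str]:
    """Canonical (lexicographic) ordering of the 4^k k-mers."""
    return ["".join(p) for p in itertools.product(_BASES, repeat=k)]


@dataclass(frozen=True)
class KmerProfile:
    """Overlapping k-mer counts of one sequence, canonical order."""

    seq_id: str
    k: int
    counts: np.ndarray

    def __post_init__(self):
        if self.counts.shape != (4 ** self.k,):
            raise ValueError("count vector has wrong length for k")
        if (self.counts < 0).any():
            raise ValueError("negative k-mer count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def as_series(self) -> pd.Series:
        return pd.Series(self.counts, index=kmer_order(self.k),
                         name=self.seq_id)


def count_kmers(seq: str, k: int = 4, seq_id: str = "") -> KmerProfile:
    """Count overlapping k-mers on the given (coding) strand.

    Windows containing N or any other ambiguity code are skipped. For an
    ambiguity-free sequence of length L the counts sum to L - k + 1.
    """
    if not (MIN_K <= k <= MAX_K):
        raise ValueError(f"k must be in {MIN_K}..{MAX_K}, got {k}")
    s = seq.upper()
    if len(s) < k:
        raise ValueError(f"sequence shorter than k={k}")
    index = {km: i for i, km in enumerate(kmer_order(k))}
    counts = np.zeros(4 ** k, dtype=np.int64)
    for i in range(len(s) - k + 1):
        word = s[i:i + k]
        j = index.get(word)
        if j is not None:
            counts[j] += 1
    return KmerProfile(seq_id=seq_id, k=k, counts=counts)


def profile_table(seqs: dict, k: int = 4) -> pd.DataFrame:
    """Sequences x k-mers count table (rows ordered as given)."""
    rows = {sid: count_kmers(s, k, sid).counts for sid, s in seqs.items()}
    return pd.DataFrame.from_dict(rows, orient="index",
                                  columns=kmer_order(k))


# ---------------------------------------------------------------------------
# correspondence analysis
# ---------------------------------------------------------------------------

@dataclass
class CaResult:
    """Principal coordinates and inertia decomposition of a CA.

    ``row_coords``/``col_coords`` are principal coordinates (scaled by
    singular values) on axes ordered by decreasing singular value; the
    sign of each axis is fixed so its first non-zero row loading is
    positive. ``total_inertia`` equals the Pearson chi-square statistic
    of the table divided by its grand total.
    """

    row_ids: list
    col_ids: list
    row_coords: np.ndarray
    col_coords: np.ndarray
    singular_values: np.ndarray
    total_inertia: float

    @property
    def n_axes(self) -> int:
        return len(self.singular_values)

    @property
    def inertia(self) -> np.ndarray:
        return self.singular_values ** 2

    @property
    def inertia_fractions(self) -> np.ndarray:
        if self.total_inertia == 0:
            return np.zeros(0)
        return self.inertia / self.total_inertia

    def row_frame(self) -> pd.DataFrame:
        cols = [f"CA{i+1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.row_coords, index=self.row_ids, columns=cols)

    def col_frame(self) -> pd.DataFrame:
        cols = [f"CA{i+1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.col_coords, index=self.col_ids, columns=cols)


def correspondence_analysis(table: pd.DataFrame,
                            axis_tol: float = 1e-10) -> CaResult:
    """Correspondence analysis of a non-negative count table.

    Rows/columns that are entirely zero are pruned with a warning. A
    rank-1 table (rows proportional to the margins' outer product, i.e.
    perfect independence) yields zero retained axes, not an error.
    Axes with singular value below ``axis_tol`` x the largest (or below
    ``axis_tol`` absolutely for a null table) are dropped.
    """
    N = table.to_numpy(dtype=float)
    if (N < 0).any():
        raise ValueError("count table must be non-negative")
    row_ids, col_ids = list(table.index), list(table.columns)
    keep_r = N.sum(axis=1) > 0
    keep_c = N.sum(axis=0) > 0
    if not keep_r.all() or not keep_c.all():
        warnings.warn(
            f"pruned {int((~keep_r).sum())} all-zero rows and "
            f"{int((~keep_c).sum())} all-zero columns", stacklevel=2,
        )
        N = N[np.ix_(keep_r, keep_c)]
        row_ids = [r for r, k in zip(row_ids, keep_r) if k]
        col_ids = [c for c, k in zip(col_ids, keep_c) if k]
    if N.size == 0:
        raise ValueError("empty table after pruning")

    n = N.sum()
    P = N / n
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    expected = np.outer(r, c)
    S = (P - expected) / np.sqrt(expected)
    U, sv, Vt = np.linalg.svd(S, full_matrices=False)
    total_inertia = float((S ** 2).sum())

    max_axes = min(len(row_ids), len(col_ids)) - 1
    thresh = axis_tol * (sv[0] if sv.size and sv[0] > axis_tol else 1.0)
    keep = (sv > thresh) & (np.arange(sv.size) < max_axes)
    sv = sv[keep]
    U = U[:, keep]
    V = Vt[keep].T

    rowc = (U / np.sqrt(r)[:, None]) * sv[None, :]
    colc = (V / np.sqrt(c)[:, None]) * sv[None, :]
    # deterministic sign: first non-zero column loading of each axis
    # positive (keyed to columns so permuting rows cannot flip an axis)
    for a in range(sv.size):
        load = colc[:, a]
        nz = np.flatnonzero(np.abs(load) > 1e-12)
        if nz.size and load[nz[0]] < 0:
            rowc[:, a] *= -1
            colc[:, a] *= -1
    return CaResult(row_ids=row_ids, col_ids=col_ids, row_coords=rowc,
                    col_coords=colc, singular_values=sv,
                    total_inertia=total_inertia)


# ---------------------------------------------------------------------------
# group cohesion
# ---------------------------------------------------------------------------

def group_cohesion(result: CaResult, groups: dict) -> dict:
    """Mean silhouette score per group on the first two CA axes.

    Quantifies the visual claim that same-host genes cluster in the
    ordination: scores near 1 mean tight, well-separated groups; near 0,
    no structure. Requires at least two groups; members missing from the
    CA rows raise.
    """
    from sklearn.metrics import silhouette_samples

    unknown = set(groups) - set(result.row_ids)
    if unknown:
        raise KeyError(f"ids not in CA result: {sorted(unknown)}")
    ids = [i for i in result.row_ids if i in groups]
    labels = [groups[i] for i in ids]
    if len(set(labels)) < 2:
        raise ValueError("need at least two groups")
    idx = [result.row_ids.index(i) for i in ids]
    X = result.row_coords[idx][:, :2]
    if X.shape[1] < 2:  # a single retained axis: pad with zeros
        X = np.column_stack([X, np.zeros(len(idx))])
    sil = silhouette_samples(X, labels)
    out: dict = {}
    for lab in sorted(set(labels), key=str):
        mask = np.array([l == lab for l in labels])
        out[lab] = float(sil[mask].mean())
    return out
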