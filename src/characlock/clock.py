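"""Patristic-ratio molecular-clock dating.

The dating procedure assumes that patristic distances on a protein tree
are linearly related to evolutionary time. A single calibrated node (for
the charavirus/tobamovirus coat-protein tree, the tobamovirus crown at
130 million years before present, mya) anchors the clock: the date of
any other node is the calibration date multiplied by the ratio of the
two nodes' mean pairwise patristic distances. "The sequences connected
through a node" are formalised as the cross-pairs of the node's
bipartition — for a rooted binary node, all pairs with one tip in each
child clade.

Worked example (coat proteins): the basal tobamovirus node has a mean
cross-pair depth of 2.123 amino-acid substitutions/site (aas/s) and is
dated 130 mya; the charavirus pair sits at 0.468 aas/s, hence
130 x 0.468 / 2.123 = 28.7 mya; the charavirus-tobamovirus split sits at
3.467 aas/s, hence ~212 mya.

Units: distances in substitutions/site; dates in mya.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from skbio import DistanceMatrix

from .phylo import PhyloTree, patristic_matrix

__all__ = [
    "SplitDistance",
    "ClockCalibration",
    "NodeDateEstimate",
    "ProteinAlignment",
    "split_distance",
    "ratio_date",
    "date_all_nodes",
    "gap_partition",
    "protein_distance_matrix",
]

GAP = "-"
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# split distances
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitDistance:
    """Cross-pair patristic distances through a node's bipartition.

    ``mean`` is the arithmetic mean over all ``|A| * |B|`` cross pairs;
    ``sd`` is their sample (n-1) standard deviation, ``None`` when only
    one pair exists. Units: substitutions/site.
    """

    group_a: frozenset
    group_b: frozenset
    distances: tuple

    @property
    def n_pairs(self) -> int:
        return len(self.distances)

    @property
    def mean(self) -> float:
        return float(np.mean(self.distances))

    @property
    def sd(self) -> float | None:
        if self.n_pairs < 2:
            return None
        return float(np.std(self.distances, ddof=1))


def split_distance(dm: DistanceMatrix, group_a, group_b) -> SplitDistance:
    """All cross-pair distances between two disjoint tip sets.

    Raises on overlapping groups or labels absent from the matrix.
    """
    a, b = frozenset(group_a), frozenset(group_b)
    if not a or not b:
        raise ValueError("both groups must be non-empty")
    if a & b:
        raise ValueError(f"groups overlap: {sorted(a & b)}")
    known = set(dm.ids)
    missing = (a | b) - known
    if missing:
        raise KeyError(f"labels not in distance matrix: {sorted(missing)}")
    dists = tuple(
        float(dm[x, y]) for x in sorted(a) for y in sorted(b)
    )
    return SplitDistance(a, b, dists)


@dataclass(frozen=True)
class ClockCalibration:
    """A calibrated node: external date (mya) plus its patristic depth."""

    date_mya: float
    split: SplitDistance | None = None
    _mean: float | None = None
    _sd: float | None = None

    def __post_init__(self):
        if self.date_mya <= 0:
            raise ValueError("calibration date must be positive")
        if self.depth <= 0:
            raise ValueError("calibration depth must be positive")

    @classmethod
    def from_mean(cls, date_mya: float, mean: float, sd: float | None = None):
        """Build a calibration directly from a published mean +/- sd."""
        return cls(date_mya=date_mya, split=None, _mean=mean, _sd=sd)

    @property
    def depth(self) -> float:
        return self.split.mean if self.split is not None else float(self._mean)

    @property
    def sd(self) -> float | None:
        return self.split.sd if self.split is not None else self._sd


@dataclass(frozen=True)
class NodeDateEstimate:
    """A ratio-dated node.

    ``date_mya = T_cal * mean_target / depth_cal``. ``band_mya`` is a
    delta-method propagation of both dispersions (absent when either sd
    is unavailable). ``older_than_parent`` flags a date exceeding the
    parent node's date; ratio dates are not ultrametric so this can
    happen and is reported, never corrected.
    """

    split: SplitDistance
    date_mya: float
    band_mya: float | None = None
    label: str | None = None
    older_than_parent: bool = False

    def rounded(self, ndigits: int = 1) -> float:
        return round(self.date_mya, ndigits)


def ratio_date(target: SplitDistance, cal: ClockCalibration,
               label: str | None = None) -> NodeDateEstimate:
    """Date a node by the ratio of mean patristic depths.

    date = T_cal * mean(target) / depth(cal), in mya. The optional
    uncertainty band is date * sqrt(cv_target^2 + cv_cal^2).
    """
    if cal.depth <= 0:
        raise ValueError("calibration depth must be positive")
    if target.mean < 0:
        raise ValueError("target mean distance must be non-negative")
    date = cal.date_mya * target.mean / cal.depth
    band = None
    if target.sd is not None and cal.sd is not None and target.mean > 0:
        cv_t = target.sd / target.mean
        cv_c = cal.sd / cal.depth
        band = date * math.sqrt(cv_t ** 2 + cv_c ** 2)
    return NodeDateEstimate(split=target, date_mya=date, band_mya=band,
                            label=label)


def date_all_nodes(tree: PhyloTree, cal_group_a, cal_group_b,
                   cal_date: float,
                   strict_calibration: bool = True) -> list[NodeDateEstimate]:
    """Date every internal node of a rooted tree from one calibration.

    By default the calibration bipartition must correspond to a node of
    the tree (its child clades, or its clade versus the rest); with
    ``strict_calibration=False`` the calibration depth is taken from
    the cross-pair distances alone, which is well-defined on any tree —
    useful when an estimated tree fails to recover the calibration
    clade exactly. Each internal node's estimate uses the cross-pairs
    of its child clades. Nodes dated older than their parent are
    flagged via ``older_than_parent``.
    """
    if not tree.rooted:
        raise ValueError("date_all_nodes requires a rooted tree")
    a, b = frozenset(cal_group_a), frozenset(cal_group_b)
    dm = patristic_matrix(tree)
    sets = tree.clade_leafsets()
    all_tips = frozenset(tree.tip_labels)

    internal = [nd for nd in tree.tree.preorder_node_iter() if not nd.is_leaf()]
    if strict_calibration and not any(
            _node_matches(nd, a, b, sets, all_tips) for nd in internal):
        raise ValueError("calibration bipartition not present in the tree")

    cal = ClockCalibration(cal_date, split_distance(dm, a, b))

    estimates: dict[int, NodeDateEstimate] = {}
    out: list[NodeDateEstimate] = []
    for nd in internal:  # preorder: parents before children
        children = nd.child_nodes()
        groups = [sets[id(c)] for c in children]
        if len(groups) == 2:
            sd_node = split_distance(dm, groups[0], groups[1])
        else:  # multifurcation: all pairs whose path passes through nd
            sd_node = _multi_split(dm, groups)
        est = ratio_date(sd_node, cal, label=_clade_label(sets[id(nd)]))
        parent = nd.parent_node
        if parent is not None and id(parent) in estimates:
            pdate = estimates[id(parent)].date_mya
            if est.date_mya > pdate + 1e-9:
                est = NodeDateEstimate(
                    split=est.split, date_mya=est.date_mya,
                    band_mya=est.band_mya, label=est.label,
                    older_than_parent=True,
                )
        estimates[id(nd)] = est
        out.append(est)
    return out


def _node_matches(nd, a, b, sets, all_tips) -> bool:
    if nd.is_leaf():
        return False
    groups = [sets[id(c)] for c in nd.child_nodes()]
    if len(groups) == 2 and {groups[0], groups[1]} == {a, b}:
        return True
    clade = sets[id(nd)]
    return {clade, all_tips - clade} == {a, b}


def _multi_split(dm: DistanceMatrix, groups) -> SplitDistance:
    dists = []
    for ga, gb in itertools.combinations(groups, 2):
        dists.extend(
            float(dm[x, y]) for x in sorted(ga) for y in sorted(gb)
        )
    merged_b = frozenset().union(*groups[1:])
    return SplitDistance(frozenset(groups[0]), merged_b, tuple(dists))


def _clade_label(leafset: frozenset) -> str:
    names = sorted(leafset)
    if len(names) <= 4:
        return "|".join(names)
    return f"{names[0]}|...|{names[-1]}({len(names)} tips)"


# ---------------------------------------------------------------------------
# protein alignments and gap partitioning
# ---------------------------------------------------------------------------

@dataclass
class ProteinAlignment:
    """Equal-length aligned amino-acid sequences with '-' gaps."""

    ids: list
    rows: list

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if not self.rows:
            raise ValueError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")
        allowed = set(AA_ALPHABET + GAP + "X*")
        for sid, row in zip(self.ids, self.rows):
            bad = set(row.upper()) - allowed
            if bad:
                raise ValueError(f"invalid characters in {sid}: {sorted(bad)}")

    @property
    def n_sites(self) -> int:
        return len(self.rows[0])

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def gap_counts(self) -> np.ndarray:
        return np.array([row.count(GAP) for row in self.rows])

    @property
    def mean_gaps_per_sequence(self) -> float:
        return float(self.gap_counts().mean())

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)

    @classmethod
    def from_fasta(cls, path) -> "ProteinAlignment":
        from Bio import SeqIO

        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(ids, rows)

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for sid, row in zip(self.ids, self.rows):
                fh.write(f">{sid}\n{row}\n")


def gap_partition(aln: ProteinAlignment,
                  max_gap_fraction: float = 0.5) -> ProteinAlignment:
    """Drop alignment columns whose gap fraction exceeds the threshold.

    Keeps exactly the columns with gap fraction <= ``max_gap_fraction``,
    in their original order. Raising the threshold never removes a
    retained column. The indel-rich charavirus/tobamovirus coat-protein
    alignment is the motivating case: trimming the gappiest sites is
    expected to leave the ratio dates essentially unchanged.
    """
    if not 0.0 <= max_gap_fraction <= 1.0:
        raise ValueError("max_gap_fraction must lie in [0, 1]")
    nseq = aln.n_sequences
    keep = [
        i for i in range(aln.n_sites)
        if aln.column(i).count(GAP) / nseq <= max_gap_fraction
    ]
    rows = ["".join(row[i] for i in keep) for row in aln.rows]
    return ProteinAlignment(list(aln.ids), rows)


# ---------------------------------------------------------------------------
# distance estimation from alignments (for the simulation-recovery loop)
# ---------------------------------------------------------------------------

def protein_distance_matrix(aln: ProteinAlignment,
                            correction: str = "jc20") -> DistanceMatrix:
    """Pairwise distances from an alignment, in substitutions/site.

    ``correction='p'`` returns raw proportions of differing sites;
    ``'jc20'`` (default) applies the 20-state equal-rates correction
    d = -(19/20) ln(1 - (20/19) p), the closed form matching a Poisson
    substitution process with uniform replacement. Gap/X sites are
    excluded pairwise. A saturated pair (p >= 19/20) raises.
    """
    n = aln.n_sequences
    d = np.zeros((n, n))
    arrs = [np.frombuffer(row.encode(), dtype="S1") for row in aln.rows]
    valid = [np.isin(a, np.frombuffer(AA_ALPHABET.encode(), dtype="S1"))
             for a in arrs]
    for i in range(n):
        for j in range(i + 1, n):
            ok = valid[i] & valid[j]
            nsites = int(ok.sum())
            if nsites == 0:
                raise ValueError(
                    f"no comparable sites between {aln.ids[i]} and {aln.ids[j]}"
                )
            p = float((arrs[i][ok] != arrs[j][ok]).sum()) / nsites
            if correction == "p":
                dij = p
            elif correction == "jc20":
                arg = 1.0 - 20.0 * p / 19.0
                if arg <= 0:
                    raise ValueError(
                        f"saturated distance between {aln.ids[i]} and "
                        f"{aln.ids[j]} (p={p:.3f})"
                    )
                dij = -19.0 / 20.0 * math.log(arg)
            else:
                raise ValueError(f"unknown correction {correction!r}")
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(d, ids=list(aln.ids))
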