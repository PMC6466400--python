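"""Phylogenetic tree model and distance utilities.

Trees carry branch lengths in substitutions per site (amino-acid
substitutions/site for the protein trees this package is built around).
Newick I/O and tree surgery are delegated to :mod:`dendropy`; the
patristic-distance computation, midpoint-root placement and
neighbor-joining are implemented here because their exact semantics
(tie-breaking, negative-branch handling) are part of this package's
contract.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
from skbio import DistanceMatrix

__all__ = [
    "PhyloTree",
    "NewickParseError",
    "parse_newick",
    "patristic_matrix",
    "midpoint_root",
    "neighbor_joining",
    "read_distance_tsv",
    "write_distance_tsv",
]

_LENGTH_TOL = 1e-9


class NewickParseError(ValueError):
    """Raised for malformed newick input (naming the offending token)."""


@dataclass
class PhyloTree:
    """A phylogenetic tree with uniquely labelled tips.

    Thin wrapper around a :class:`dendropy.Tree`. Branch lengths are
    non-negative reals in substitutions/site. ``rooted`` records whether
    the seed node is to be interpreted as a true root (two or more
    children) rather than an arbitrary trifurcation.
    """

    tree: dendropy.Tree
    rooted: bool = False

    def __post_init__(self) -> None:
        labels = self.tip_labels
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise NewickParseError(f"duplicate tip labels: {sorted(dupes)}")
        for nd in self.tree.preorder_node_iter():
            if nd.edge.length is not None and nd.edge.length < 0:
                raise NewickParseError(
                    f"negative branch length {nd.edge.length} on branch above "
                    f"{_node_name(nd)}"
                )
        if self.rooted and len(self.tree.seed_node.child_nodes()) < 2:
            raise ValueError("a rooted tree's root must have >= 2 children")

    # -- basic accessors -------------------------------------------------
    @property
    def tip_labels(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick",
            suppress_rooting=True,
            real_value_format_specifier=".12g",
            unquoted_underscores=True,
        ).strip() + "\n"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self.tree.clone(depth=1), rooted=self.rooted)

    # -- structural helpers ----------------------------------------------
    def _require_lengths(self) -> None:
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is not None and nd.edge.length is None:
                raise ValueError(
                    f"missing branch length on branch above {_node_name(nd)}"
                )

    def clade_leafsets(self) -> dict[int, frozenset[str]]:
        """Map id(node) -> frozenset of tip labels under that node."""
        out: dict[int, frozenset[str]] = {}
        for nd in self.tree.postorder_node_iter():
            if nd.is_leaf():
                out[id(nd)] = frozenset([nd.taxon.label])
            else:
                out[id(nd)] = frozenset().union(
                    *(out[id(c)] for c in nd.child_nodes())
                )
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Unrooted bipartitions, each encoded as its side not containing
        the lexicographically smallest tip."""
        all_tips = frozenset(self.tip_labels)
        ref = min(all_tips)
        sets = self.clade_leafsets()
        out: set[frozenset[str]] = set()
        for nd in self.tree.preorder_node_iter():
            if nd.parent_node is None or nd.is_leaf():
                continue
            side = sets[id(nd)]
            if ref in side:
                side = all_tips - side
            if 0 < len(side) < len(all_tips) - 1:
                out.add(side)
        return out

    def topology_equal(self, other: "PhyloTree", tol: float = _LENGTH_TOL) -> bool:
        """Unrooted topology + branch-length equality (to ``tol``)."""
        if set(self.tip_labels) != set(other.tip_labels):
            return False
        if self.bipartitions() != other.bipartitions():
            return False
        da, db = patristic_matrix(self), patristic_matrix(other)
        db = db.filter(da.ids)
        return bool(np.allclose(da.data, db.data, atol=10 * tol, rtol=0.0))


def _node_name(nd: dendropy.Node) -> str:
    if nd.taxon is not None:
        return nd.taxon.label
    if nd.label:
        return nd.label
    return f"<internal node with tips {sorted(l.taxon.label for l in nd.leaf_iter())[:3]}...>"


def parse_newick(text: str, rooted: bool | None = None) -> PhyloTree:
    """Parse a newick string into a :class:`PhyloTree`.

    Internal node labels (FigTree/PhyML support values) are preserved as
    plain node labels and otherwise unused. Duplicate tip labels and
    negative branch lengths are rejected.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except dendropy.utility.error.DataParseError as exc:  # includes unbalanced parens
        raise NewickParseError(str(exc)) from exc
    if rooted is None:
        rooted = len(tree.seed_node.child_nodes()) == 2
    return PhyloTree(tree, rooted=rooted)


def read_newick(path, rooted: bool | None = None) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read(), rooted=rooted)


# ---------------------------------------------------------------------------
# patristic distances
# ---------------------------------------------------------------------------

def patristic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """All tip-to-tip path-length sums as a symmetric :class:`DistanceMatrix`.

    Computed by a single postorder sweep that merges per-clade
    tip-to-node distance maps; independent of root placement.
    """
    tree._require_lengths()
    labels = sorted(tree.tip_labels)
    idx = {l: i for i, l in enumerate(labels)}
    n = len(labels)
    d = np.zeros((n, n))
    # per node: dict tip-index -> distance from tip up to this node
    below: dict[int, dict[int, float]] = {}
    for nd in tree.tree.postorder_node_iter():
        if nd.is_leaf():
            below[id(nd)] = {idx[nd.taxon.label]: 0.0}
            continue
        children = nd.child_nodes()
        maps = []
        for c in children:
            m = below.pop(id(c))
            blen = c.edge.length
            maps.append({t: dist + blen for t, dist in m.items()})
        for ma, mb in itertools.combinations(maps, 2):
            for ti, di in ma.items():
                for tj, dj in mb.items():
                    d[ti, tj] = d[tj, ti] = di + dj
        merged: dict[int, float] = {}
        for m in maps:
            merged.update(m)
        below[id(nd)] = merged
    return DistanceMatrix(d, ids=labels)


# ---------------------------------------------------------------------------
# midpoint rooting
# ---------------------------------------------------------------------------

def midpoint_root(tree: PhyloTree) -> PhyloTree:
    """Root the tree at the midpoint of its longest tip-to-tip path.

    Ties between equal-length diameter paths are broken by the
    lexicographically smallest tip pair so the output is deterministic.
    The two maximal root-to-tip distances on either side of the new root
    are equal to within 1e-9.
    """
    if tree.n_tips < 2:
        raise ValueError("midpoint rooting requires at least 2 tips")
    dm = patristic_matrix(tree)
    labels = list(dm.ids)
    best = None
    for i, j in itertools.combinations(range(len(labels)), 2):
        pair = tuple(sorted((labels[i], labels[j])))
        key = (-dm.data[i, j], pair)
        if best is None or key < best[0]:
            best = (key, pair, dm.data[i, j])
    _, (tip_a, tip_b), diam = best
    half = diam / 2.0

    work = tree.copy()
    leaf = {l.taxon.label: l for l in work.tree.leaf_node_iter()}
    node_a, node_b = leaf[tip_a], leaf[tip_b]
    path = _tip_path(node_a, node_b)  # list of (edge, head_is_towards_a)
    acc = 0.0  # distance walked from tip_a
    for edge, head_towards_a in path:
        length = edge.length
        if acc + length >= half - _LENGTH_TOL:
            onto = half - acc  # distance from the a-side end of this edge
            if head_towards_a:
                head_part, tail_part = onto, length - onto
            else:
                tail_part, head_part = onto, length - onto
            head_part = max(head_part, 0.0)
            tail_part = max(tail_part, 0.0)
            if tail_part <= _LENGTH_TOL and edge.tail_node is work.tree.seed_node \
                    and len(work.tree.seed_node.child_nodes()) == 2:
                pass  # midpoint coincides with the existing root
            else:
                work.tree.reroot_at_edge(
                    edge, length1=tail_part, length2=head_part,
                    suppress_unifurcations=True,
                )
            break
        acc += length
    else:  # pragma: no cover - midpoint always lies on the path
        raise AssertionError("midpoint not located on diameter path")
    return PhyloTree(work.tree, rooted=True)


def _tip_path(a: dendropy.Node, b: dendropy.Node):
    """Edges on the path from tip ``a`` to tip ``b``.

    Each entry is ``(edge, head_is_towards_a)`` where the edge's head is
    its child-side node.
    """
    anc_a = [a] + [nd for nd in a.ancestor_iter()]
    anc_b_set = {id(nd): nd for nd in [b] + list(b.ancestor_iter())}
    mrca = next(nd for nd in anc_a if id(nd) in anc_b_set)
    path = []
    nd = a
    while nd is not mrca:  # climbing: head (child side) is towards a
        path.append((nd.edge, True))
        nd = nd.parent_node
    down = []
    nd = b
    while nd is not mrca:  # descending towards b: head is away from a
        down.append((nd.edge, False))
        nd = nd.parent_node
    path.extend(reversed(down))
    return path


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def neighbor_joining(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor joining.

    On an additive matrix the generating unrooted topology and branch
    lengths are recovered exactly (to 1e-9). A negative estimated branch
    length is clamped to zero and the deficit transferred to the sibling
    branch of the join, preserving their sum; a warning is issued.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    taxa = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for label in dm.ids:
        nd = dendropy.Node()
        nd.taxon = taxa.new_taxon(label)
        nodes.append(nd)
    d = dm.data.astype(float).copy()
    active = list(range(n))

    def _set_len(node: dendropy.Node, value: float) -> None:
        node.edge.length = value

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # deterministic argmin: smallest Q, ties -> smallest (i, j)
        fi, fj = np.unravel_index(np.argmin(q), q.shape)
        if fi > fj:
            fi, fj = fj, fi
        i, j = active[fi], active[fj]
        dij = d[i, j]
        limb_i = 0.5 * dij + (r[fi] - r[fj]) / (2.0 * (m - 2))
        limb_j = dij - limb_i
        limb_i, limb_j = _clamp_pair(limb_i, limb_j)
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        _set_len(nodes[i], limb_i)
        _set_len(nodes[j], limb_j)
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - dij)
        d = np.vstack([d, new_row])
        new_col = np.append(new_row, 0.0)
        d = np.column_stack([d, new_col])
        nodes.append(parent)
        active = [k for k in active if k not in (i, j)] + [d.shape[0] - 1]

    a, b, c = active
    la = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    lb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    lc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    center = dendropy.Node()
    for k, lk in ((a, la), (b, lb), (c, lc)):
        if lk < -_LENGTH_TOL:
            warnings.warn(
                f"negative NJ branch length {lk:.3g} clamped to 0",
                stacklevel=2,
            )
        center.add_child(nodes[k])
        _set_len(nodes[k], max(lk, 0.0))
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree, rooted=False)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < -_LENGTH_TOL or lj < -_LENGTH_TOL:
        warnings.warn(
            "negative NJ branch length clamped to 0 (deficit moved to sibling)",
            stacklevel=3,
        )
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li = max(li + lj, 0.0)
        lj = 0.0
    return li, lj


# ---------------------------------------------------------------------------
# distance-matrix TSV I/O
# ---------------------------------------------------------------------------

def write_distance_tsv(dm: DistanceMatrix, path) -> None:
    import pandas as pd

    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def read_distance_tsv(path) -> DistanceMatrix:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.values, ids=[str(i) for i in df.index])
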