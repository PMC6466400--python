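"""Synthetic-data generators with known ground truth.

Every pipeline stage gets a no-download test harness here:

* dated ultrametric trees plus a Poisson equal-rates amino-acid
  simulator for the clock-dating recovery loop (a perfect molecular
  clock in expectation: patristic distance = 2 x rate x divergence
  time);
* host-biased coding sequences whose tetranucleotide composition is
  tilted by an order-3 Markov chain, for the k-mer/CA stage;
* read pileups over a reference with variants planted at known
  frequencies, for the SNV caller.

All generators are deterministic under a seed: the same seed yields
byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .clock import AA_ALPHABET, ProteinAlignment
from .genome import GenomeRecord, OrfAnnotation
from .phylo import PhyloTree, patristic_matrix
from .virome import PileupColumn, SNVRecord, classify_snv

__all__ = [
    "DatedTree",
    "HostBiasProfile",
    "random_dated_tree",
    "random_additive_tree",
    "simulate_clock_alignment",
    "gc_biased_profile",
    "uniform_profile",
    "simulate_biased_cds",
    "random_genome",
    "simulate_pileup",
]

_BASES = "ACGT"


# ---------------------------------------------------------------------------
# dated trees and clock-like alignments
# ---------------------------------------------------------------------------

@dataclass
class DatedTree:
    """An ultrametric tree with node heights in mya and a clock rate.

    Branch lengths of ``tree`` are durations (my); all tips sit at
    height 0. ``rate`` is the substitution rate in substitutions per
    site per my. ``calibration`` is the bipartition (two tip-label
    sets) of the calibrated node and ``calibration_date`` its height.
    """

    tree: PhyloTree
    rate: float
    calibration: tuple
    calibration_date: float

    def __post_init__(self):
        if self.rate < 0:
            raise ValueError("rate must be non-negative")

    def node_height(self, tipset) -> float:
        """Height (mya) of the MRCA of the given tips."""
        labels = sorted(tipset)
        mrca = self.tree.tree.mrca(taxon_labels=labels)
        # ultrametric: height = distance down to any descendant tip
        leaf = next(mrca.leaf_iter())
        h, nd = 0.0, leaf
        while nd is not mrca:
            h += nd.edge.length
            nd = nd.parent_node
        return h

    def true_distance_matrix(self) -> DistanceMatrix:
        """Expected distances 2 x rate x TMRCA, in substitutions/site."""
        time_dm = patristic_matrix(self.tree)
        return DistanceMatrix(self.rate * time_dm.data, ids=list(time_dm.ids))


def random_dated_tree(n_tips: int, root_height: float = 100.0,
                      rate: float = 2e-3, seed=None,
                      prefix: str = "t") -> DatedTree:
    """A random ultrametric tree via sequential random joins.

    Internal-node heights are sorted uniforms on (0, root_height) with
    the root pinned at ``root_height``; at each height two uniformly
    chosen lineages coalesce. The calibration node defaults to the
    root split at ``root_height``. Default rate 2e-3 subs/site/my.
    """
    if n_tips < 2:
        raise ValueError("need at least 2 tips")
    rng = np.random.default_rng(seed)
    inner = np.sort(rng.uniform(0.0, root_height, n_tips - 2))
    heights = np.append(inner, root_height)
    taxa = dendropy.TaxonNamespace()
    active: list[tuple[dendropy.Node, float]] = []
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = taxa.new_taxon(f"{prefix}{i + 1}")
        active.append((nd, 0.0))
    for h in heights:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        nb, hb = active.pop(j)
        na, ha = active.pop(i)
        parent = dendropy.Node()
        parent.add_child(na)
        na.edge.length = h - ha
        parent.add_child(nb)
        nb.edge.length = h - hb
        active.append((parent, h))
    root = active[0][0]
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=root)
    tree.is_rooted = True
    ptree = PhyloTree(tree, rooted=True)
    sets = ptree.clade_leafsets()
    c1, c2 = root.child_nodes()
    return DatedTree(tree=ptree, rate=rate,
                     calibration=(sets[id(c1)], sets[id(c2)]),
                     calibration_date=root_height)


def random_additive_tree(n_tips: int, seed=None, min_len: float = 0.1,
                         max_len: float = 1.0,
                         prefix: str = "t") -> PhyloTree:
    """A random binary tree with uniform branch lengths (not clock-like).

    Its patristic matrix is additive by construction, the input for
    exact neighbor-joining recovery checks.
    """
    if n_tips < 3:
        raise ValueError("need at least 3 tips")
    rng = np.random.default_rng(seed)
    taxa = dendropy.TaxonNamespace()
    active = []
    for i in range(n_tips):
        nd = dendropy.Node()
        nd.taxon = taxa.new_taxon(f"{prefix}{i + 1}")
        active.append(nd)
    while len(active) > 3:
        i, j = sorted(rng.choice(len(active), size=2, replace=False))
        nb = active.pop(j)
        na = active.pop(i)
        parent = dendropy.Node()
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = float(rng.uniform(min_len, max_len))
        nb.edge.length = float(rng.uniform(min_len, max_len))
        active.append(parent)
    center = dendropy.Node()
    for nd in active:
        center.add_child(nd)
        nd.edge.length = float(rng.uniform(min_len, max_len))
    tree = dendropy.Tree(taxon_namespace=taxa, seed_node=center)
    tree.is_rooted = False
    return PhyloTree(tree, rooted=False)


def simulate_clock_alignment(dated: DatedTree, n_sites: int, seed=None):
    """Evolve an amino-acid alignment along a dated tree.

    Poisson equal-rates model: each branch of duration t receives
    Poisson(rate x t x n_sites) substitution events, each at a uniform
    random site, replacing the residue with one of the 19 others chosen
    uniformly. Returns ``(ProteinAlignment, true DistanceMatrix)``
    where the truth is the expected distance 2 x rate x TMRCA.
    """
    if n_sites < 1:
        raise ValueError("n_sites must be >= 1")
    rng = np.random.default_rng(seed)
    aa = np.frombuffer(AA_ALPHABET.encode(), dtype="S1")
    root_seq = rng.integers(0, 20, size=n_sites)
    seqs: dict[int, np.ndarray] = {}
    tips: dict[str, np.ndarray] = {}
    for nd in dated.tree.tree.preorder_node_iter():
        if nd.parent_node is None:
            seq = root_seq.copy()
        else:
            seq = seqs[id(nd.parent_node)].copy()
            n_mut = rng.poisson(dated.rate * nd.edge.length * n_sites)
            for _ in range(n_mut):
                site = int(rng.integers(n_sites))
                seq[site] = (seq[site] + 1 + int(rng.integers(19))) % 20
        seqs[id(nd)] = seq
        if nd.is_leaf():
            tips[nd.taxon.label] = seq
    ids = sorted(tips)
    rows = [b"".join(aa[tips[i]]).decode() for i in ids]
    return ProteinAlignment(ids, rows), dated.true_distance_matrix().filter(ids)


# ---------------------------------------------------------------------------
# host-biased coding sequences
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HostBiasProfile:
    """A host signature: positive, normalized tetranucleotide weights."""

    label: str
    weights: np.ndarray

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (256,):
            raise ValueError("weights must have length 256 (4^4)")
        if (w <= 0).any():
            raise ValueError("degenerate profile: all weights must be > 0")
        object.__setattr__(self, "weights", w / w.sum())


def uniform_profile(label: str) -> HostBiasProfile:
    return HostBiasProfile(label, np.full(256, 1.0 / 256))


def gc_biased_profile(label: str, gc_tilt: float) -> HostBiasProfile:
    """Weights exp(gc_tilt x (#G/C in tetramer - 2)); positive tilt
    favours GC-rich tetramers, negative AT-rich."""
    gc_counts = np.array([
        sum(b in "GC" for b in _tetramer(i)) for i in range(256)
    ])
    return HostBiasProfile(label, np.exp(gc_tilt * (gc_counts - 2.0)))


def _tetramer(index: int) -> str:
    out = []
    for shift in (6, 4, 2, 0):
        out.append(_BASES[(index >> shift) & 3])
    return "".join(out)


def simulate_biased_cds(profile: HostBiasProfile, n_genes: int, length: int,
                        seed=None, strength: float = 1.0) -> dict:
    """Generate coding-frame sequences tilted toward a host signature.

    An order-3 Markov chain emits each base with probability
    proportional to ``weights[context + base] ** strength``; at
    strength 0 the output is uniform i.i.d. nucleotides, so the
    empirical tetranucleotide distribution is uniform in expectation.
    ``length`` must be a codon multiple. Gene ids carry the profile
    label.
    """
    if length % 3 != 0:
        raise ValueError("length must be divisible by 3")
    if length < 4:
        raise ValueError("length must be at least one tetramer")
    rng = np.random.default_rng(seed)
    w = profile.weights.reshape(64, 4) ** strength
    trans = w / w.sum(axis=1, keepdims=True)
    genes: dict[str, str] = {}
    for g in range(n_genes):
        seq = list(rng.integers(0, 4, size=3))
        ctx = (seq[0] << 4) | (seq[1] << 2) | seq[2]
        for _ in range(length - 3):
            b = int(rng.choice(4, p=trans[ctx]))
            seq.append(b)
            ctx = ((ctx << 2) | b) & 0x3F
        genes[f"{profile.label}_g{g + 1}"] = "".join(_BASES[b] for b in seq)
    return genes


# ---------------------------------------------------------------------------
# genomes and pileups
# ---------------------------------------------------------------------------

def random_genome(length: int, seed=None, genome_id: str = "synth",
                  gc: float = 0.5) -> GenomeRecord:
    """A random genome with the requested expected G+C fraction."""
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    seq = "".join(_BASES[i] for i in rng.choice(4, size=length, p=p))
    return GenomeRecord(genome_id, seq)


def simulate_pileup(genome: GenomeRecord, orfs, variants, depth: int,
                    seed=None, error_rate: float = 0.0):
    """Pileup columns over a reference with planted variants.

    ``variants`` is a list of ``(pos, alt_base, frequency)``; at each
    such position the alternative count is Binomial(depth, frequency)
    and the remainder stays reference. Frequency-zero entries are
    dropped; two variants at one position are rejected. With
    ``error_rate`` > 0 every remaining reference read independently
    misreads to a uniform other base (default 0: no error model, so
    recall/precision targets against the truth table are exact).

    Returns ``(columns, truth)`` where ``truth`` is a DataFrame with
    one row per planted variant and its synonymous/non-synonymous
    status from the codon table.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    planted: dict[int, tuple[str, float]] = {}
    for pos, alt, freq in variants:
        if not (1 <= pos <= len(genome)):
            raise ValueError(f"variant position {pos} outside genome")
        if not (0.0 <= freq <= 1.0):
            raise ValueError(f"variant frequency {freq} outside [0, 1]")
        alt = alt.upper()
        if alt not in _BASES:
            raise ValueError(f"invalid alternative base {alt!r}")
        if alt == genome.seq[pos - 1]:
            raise ValueError(f"variant at {pos} equals the reference base")
        if pos in planted:
            raise ValueError(f"conflicting variants at position {pos}")
        if freq > 0.0:
            planted[pos] = (alt, freq)
    rng = np.random.default_rng(seed)
    columns: list[PileupColumn] = []
    truth_rows = []
    for pos in range(1, len(genome) + 1):
        ref = genome.seq[pos - 1]
        counts = {b: 0 for b in _BASES}
        alt_n = 0
        if pos in planted:
            alt, freq = planted[pos]
            alt_n = int(rng.binomial(depth, freq))
            counts[alt] += alt_n
        ref_n = depth - alt_n
        if error_rate > 0.0 and ref_n > 0:
            n_err = int(rng.binomial(ref_n, error_rate))
            ref_n -= n_err
            others = [b for b in _BASES if b != ref]
            for b in rng.choice(others, size=n_err):
                counts[b] += 1
        counts[ref] += ref_n
        columns.append(PileupColumn(
            contig=genome.id, pos=pos, ref=ref, a=counts["A"], c=counts["C"],
            g=counts["G"], t=counts["T"],
        ))
        if pos in planted:
            alt, freq = planted[pos]
            probe = SNVRecord(contig=genome.id, pos=pos, ref=ref, alt=alt,
                              alt_count=1, depth=1)
            effect = classify_snv(probe, orfs, genome).effect
            truth_rows.append({
                "contig": genome.id, "pos": pos, "ref": ref, "alt": alt,
                "frequency": freq, "planted_count": alt_n, "effect": effect,
            })
    truth = pd.DataFrame(
        truth_rows,
        columns=["contig", "pos", "ref", "alt", "frequency",
                 "planted_count", "effect"],
    )
    return columns, truth
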