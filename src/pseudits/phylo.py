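"""Distance phylogenetics: K2P distances, neighbor-joining, bootstrap,
cpDNA concatenation and clade labelling.

Trees here are a deliberate distance-based stand-in for likelihood
methods: at the shallow divergences of within-genus ITS/cpDNA data the
clade structure of interest (short-type clades 1–2, long-type clade 3,
the two pseudogroups, maternal clades I/II) is recoverable by
neighbor-joining on Kimura 2-parameter distances, which keeps every
step exactly testable.  Gamma rate heterogeneity is not modelled.
Trees are DendroPy objects; Newick round-trips preserve topology,
branch lengths and support labels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import dendropy
import numpy as np

from .errors import AlignmentError, SaturationError
from .seqio import Alignment, SequenceRecord

TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray

    def __post_init__(self):
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("nonzero diagonal")
        if np.any(self.d < 0) or not np.all(np.isfinite(self.d)):
            raise ValueError("distances must be finite and non-negative")

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.taxa.index(a), self.taxa.index(b)])


@dataclass
class PhyloTree:
    """A tree plus bootstrap supports on internal edges.

    support maps a bipartition (frozenset of leaf labels on the side not
    containing the reference taxon) to a percentage in [0, 100].
    """

    tree: dendropy.Tree
    support: dict[frozenset, float] = field(default_factory=dict)

    @property
    def taxa(self) -> list[str]:
        return sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    def newick(self) -> str:
        t = self.tree.clone(depth=1)
        for node in t.preorder_internal_node_iter():
            bp = frozenset(l.taxon.label for l in node.leaf_iter())
            key = _canonical_split(bp, frozenset(self.taxa))
            if key in self.support:
                node.label = f"{self.support[key]:g}"
        return t.as_string(schema="newick", suppress_rooting=True).strip()


def _canonical_split(side: frozenset, all_taxa: frozenset) -> frozenset:
    """Canonical form of a bipartition: the side without the first taxon."""
    anchor = min(all_taxa)
    return frozenset(all_taxa - side) if anchor in side else frozenset(side)


# ---------------------------------------------------------------------------
# K2P distances


def k2p_distance(a: str | SequenceRecord, b: str | SequenceRecord) -> float:
    """Kimura 2-parameter distance of an aligned pair.

    Sites where either sequence has a gap or N are excluded (pairwise
    deletion).  With transition proportion P and transversion proportion
    Q: d = -1/2 ln((1-2P-Q) sqrt(1-2Q)).  Raises SaturationError when a
    log argument is <= 0.
    """
    ra = a.residues if isinstance(a, SequenceRecord) else a
    rb = b.residues if isinstance(b, SequenceRecord) else b
    if len(ra) != len(rb):
        raise AlignmentError("k2p_distance needs an aligned pair")
    n = ts = tv = 0
    for x, y in zip(ra, rb):
        if x not in "ACGT" or y not in "ACGT":
            continue
        n += 1
        if x == y:
            continue
        if (x, y) in TRANSITIONS:
            ts += 1
        else:
            tv += 1
    if n == 0:
        raise AlignmentError("no comparable sites")
    P, Q = ts / n, tv / n
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        raise SaturationError(
            f"K2P saturated (P={P:.3f}, Q={Q:.3f} over {n} sites)")
    return float(-0.5 * np.log(w1 * np.sqrt(w2)))


def k2p_matrix(aln: Alignment) -> DistanceMatrix:
    """All-pairs K2P matrix with pairwise deletion.

    Saturated pairs are set to 1.05x the maximum finite entry, with a
    warning naming the pair, so neighbor-joining stays runnable.
    """
    taxa = [r.id for r in aln.records]
    n = len(taxa)
    d = np.zeros((n, n))
    saturated = []
    for i in range(n):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = k2p_distance(aln.records[i],
                                                 aln.records[j])
            except SaturationError:
                saturated.append((i, j))
    if saturated:
        cap = d.max() * 1.05 if d.max() > 0 else 1.0
        for i, j in saturated:
            warnings.warn(f"K2P saturated for ({taxa[i]}, {taxa[j]}); "
                          f"using {cap:.4f}")
            d[i, j] = d[j, i] = cap
    return DistanceMatrix(taxa=taxa, d=d)


# ---------------------------------------------------------------------------
# Neighbor-joining


def nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei neighbor-joining with deterministic tie-breaking.

    Ties in the Q criterion are broken by the (sorted) smallest-leaf
    labels of the candidate pair.  Negative branch lengths are clamped
    to zero with the deficit transferred to the sister edge.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("nj_tree needs >= 3 taxa")
    taxon_ns = dendropy.TaxonNamespace(dm.taxa)
    nodes: list[dendropy.Node] = []
    keys: list[str] = []       # min leaf label per active node, for ties
    for label in dm.taxa:
        node = dendropy.Node()
        node.taxon = taxon_ns.get_taxon(label)
        nodes.append(node)
        keys.append(label)
    d = dm.d.astype(float).copy()
    active = list(range(n))
    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((keys[i], keys[j])))
                if best is None or q < best[0] - 1e-12 or \
                        (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            li = max(li, 0.0)
            lj = 0.0
        parent = dendropy.Node()
        nodes[i].edge.length = li
        nodes[j].edge.length = lj
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        new_idx = len(nodes)
        nodes.append(parent)
        keys.append(min(keys[i], keys[j]))
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[new_idx, k] = d[k, new_idx] = \
                0.5 * (d[i, k] + d[j, k] - d[i, j])
        active = [k for k in active if k not in (i, j)] + [new_idx]
    # connect the last three nodes to a central hub
    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    hub = dendropy.Node()
    for idx, ln in ((i, li), (j, lj), (k, lk)):
        nodes[idx].edge.length = max(ln, 0.0)
        hub.add_child(nodes[idx])
    tree = dendropy.Tree(taxon_namespace=taxon_ns, seed_node=hub)
    tree.is_rooted = False
    return PhyloTree(tree=tree)


# ---------------------------------------------------------------------------
# Bootstrap


def _splits(tree: dendropy.Tree, all_taxa: frozenset) -> set[frozenset]:
    out = set()
    for node in tree.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(all_taxa) - 1:
            out.add(_canonical_split(side, all_taxa))
    return out


def bootstrap_support(aln: Alignment, n_reps: int = 1000,
                      seed: int = 0) -> PhyloTree:
    """Site-resampled bootstrap supports mapped onto the full-data NJ tree."""
    if len(aln.records) < 4:
        raise AlignmentError("bootstrap needs >= 4 rows")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    full = nj_tree(k2p_matrix(aln))
    all_taxa = frozenset(full.taxa)
    counts: dict[frozenset, int] = {}
    rng = np.random.default_rng(seed)
    ncol = aln.length
    rows = [r.residues for r in aln.records]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        rep_records = [
            SequenceRecord(id=r.id, residues="".join(row[c] for c in cols))
            for r, row in zip(aln.records, rows)]
        try:
            rep_tree = nj_tree(k2p_matrix(Alignment(records=rep_records)))
        except (SaturationError, AlignmentError):
            continue
        for split in _splits(rep_tree.tree, all_taxa):
            counts[split] = counts.get(split, 0) + 1
    support = {}
    for split in _splits(full.tree, all_taxa):
        support[split] = 100.0 * counts.get(split, 0) / n_reps
    full.support = support
    return full


# ---------------------------------------------------------------------------
# cpDNA concatenation


def concat_cpdna(trnLF: Alignment, trnTL: Alignment) -> Alignment:
    """Column-wise concatenation of the two cpDNA alignments.

    Taxon sets must match; rows are ordered as in the first alignment
    and the partition boundary is recorded.
    """
    taxa_a = {r.id for r in trnLF.records}
    taxa_b = {r.id for r in trnTL.records}
    if taxa_a != taxa_b:
        missing = sorted(taxa_a ^ taxa_b)
        raise AlignmentError(f"taxon sets differ; unmatched: {missing}")
    records = []
    for r in trnLF.records:
        other = trnTL.row(r.id)
        records.append(SequenceRecord(
            id=r.id, residues=r.residues + other.residues,
            taxon=r.taxon, molecule="cpDNA"))
    return Alignment(records=records, partition_boundary=trnLF.length)


# ---------------------------------------------------------------------------
# Rooting and clade assignment


@dataclass
class CladeAssignment:
    label: str
    members: list[str]
    anchor_taxa: list[str]
    clean: bool
    note: str = ""


def root_on_outgroup(ptree: PhyloTree, outgroup: str) -> PhyloTree:
    """Root the tree on the edge above the outgroup leaf."""
    tree = ptree.tree.clone(depth=1)
    leaf = None
    for l in tree.leaf_node_iter():
        if l.taxon.label == outgroup:
            leaf = l
            break
    if leaf is None:
        raise ValueError(f"outgroup {outgroup!r} not in tree")
    length = leaf.edge.length or 0.0
    tree.reroot_at_edge(leaf.edge, length1=length / 2.0,
                        length2=length / 2.0,
                        update_bipartitions=False)
    tree.is_rooted = True
    return PhyloTree(tree=tree, support=dict(ptree.support))


def assign_clades(ptree: PhyloTree, anchors: Mapping[str, Sequence[str]],
                  outgroup: str | None = None) -> list[CladeAssignment]:
    """Label clades as the smallest clade containing each anchor set.

    The tree must be rooted (or an outgroup given to root it here).  An
    assignment is flagged unclean when its clade contains an anchor of
    another label (anti-anchor).
    """
    if outgroup is not None:
        ptree = root_on_outgroup(ptree, outgroup)
    tree = ptree.tree
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    for name, taxa in anchors.items():
        missing = sorted(set(taxa) - labels)
        if missing:
            raise ValueError(f"anchor taxa missing from tree for "
                             f"{name!r}: {missing}")
    assignments = []
    for name, taxa in anchors.items():
        mrca = tree.mrca(taxon_labels=list(taxa))
        members = sorted(l.taxon.label for l in mrca.leaf_iter())
        antis = {t for other, ts in anchors.items() if other != name
                 for t in ts}
        hit = sorted(set(members) & antis)
        clean = not hit
        note = "" if clean else f"contains anti-anchor(s): {hit}"
        assignments.append(CladeAssignment(label=name, members=members,
                                           anchor_taxa=list(taxa),
                                           clean=clean, note=note))
    return assignments


def load_tree(newick: str) -> PhyloTree:
    """Parse a Newick string; internal node labels become supports."""
    tree = dendropy.Tree.get(data=newick, schema="newick")
    all_taxa = frozenset(l.taxon.label for l in tree.leaf_node_iter())
    support = {}
    for node in tree.preorder_internal_node_iter():
        if node.label is not None:
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            support[_canonical_split(side, all_taxa)] = float(node.label)
    return PhyloTree(tree=tree, support=support)
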