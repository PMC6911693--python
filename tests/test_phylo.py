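"""K2P distances, neighbor-joining (with additive-matrix and scikit-bio
oracles), bootstrap supports, concatenation and clade assignment."""

import math

import numpy as np
import pytest

from pseudits.errors import AlignmentError, SaturationError
from pseudits.phylo import (DistanceMatrix, assign_clades, bootstrap_support,
                            concat_cpdna, k2p_distance, k2p_matrix, load_tree,
                            nj_tree, root_on_outgroup)
from pseudits.seqio import Alignment, SequenceRecord


class TestK2P:
    def test_identical(self):
        assert k2p_distance("ACGT" * 25, "ACGT" * 25) == 0.0

    def test_one_transition_in_100(self):
        a = "A" * 100
        b = "G" + "A" * 99
        assert k2p_distance(a, b) == pytest.approx(-0.5 * math.log(0.98))

    def test_two_transversions_in_100(self):
        # P=0, Q=0.02: d = -1/2 ln((1-2P-Q) sqrt(1-2Q))
        a = "A" * 100
        b = "CC" + "A" * 98
        expected = -0.5 * math.log(0.98 * math.sqrt(0.96))
        assert k2p_distance(a, b) == pytest.approx(expected)

    def test_gaps_and_n_excluded(self):
        a = "G" + "N" + "A" * 98
        b = "A" + "C" + "A" * 98
        # N column skipped -> 99 counted sites, 1 transition, 0 transversions
        assert k2p_distance(a, b) == pytest.approx(
            -0.5 * math.log(1 - 2 / 99))

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_distance("A" * 10, "C" * 10)

    def test_symmetry_nonnegativity(self, rng):
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=200))
            b = list(a)
            for i in rng.choice(200, size=10, replace=False):
                b[i] = str(rng.choice(list("ACGT")))
            b = "".join(b)
            d1, d2 = k2p_distance(a, b), k2p_distance(b, a)
            assert d1 == d2 >= 0.0


def _random_additive(rng, labels):
    """Random binary tree over labels -> (path-distance matrix, splits).

    Built bottom-up: each active node carries the distance from every
    leaf below it to its root, so cross-distances at a merge are exact
    path lengths by construction.
    """
    idx = {lbl: i for i, lbl in enumerate(labels)}
    dmat = np.zeros((len(labels), len(labels)))
    nodes = [{lbl: 0.0} for lbl in labels]
    splits = set()
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[i], nodes[j]
        la = float(rng.uniform(0.05, 1.0))
        lb = float(rng.uniform(0.05, 1.0)) if len(nodes) > 2 else 0.0
        for x, dx in a.items():
            for y, dy in b.items():
                dmat[idx[x], idx[y]] = dmat[idx[y], idx[x]] = \
                    dx + la + dy + lb
        merged = {x: dx + la for x, dx in a.items()}
        merged.update({y: dy + lb for y, dy in b.items()})
        if 1 < len(merged) < len(labels) - 1:
            splits.add(frozenset(merged))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(merged)
    return dmat, splits


def _tree_splits(ptree):
    taxa = frozenset(ptree.taxa)
    out = set()
    for node in ptree.tree.preorder_internal_node_iter():
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if 1 < len(side) < len(taxa) - 1:
            canon = side if min(taxa) not in side else taxa - side
            out.add(frozenset(canon))
    return out


def _canon_splits(splits, labels):
    taxa = frozenset(labels)
    return {frozenset(s if min(taxa) not in s else taxa - s) for s in splits}


class TestNeighborJoining:
    def test_three_taxa_branch_lengths(self):
        d = np.array([[0.0, 0.3, 0.5], [0.3, 0.0, 0.6], [0.5, 0.6, 0.0]])
        tree = nj_tree(DistanceMatrix(taxa=["a", "b", "c"], d=d))
        # three-point solution: la=(ab+ac-bc)/2 etc.
        lengths = {l.taxon.label: l.edge.length
                   for l in tree.tree.leaf_node_iter()}
        assert lengths["a"] == pytest.approx(0.1)
        assert lengths["b"] == pytest.approx(0.2)
        assert lengths["c"] == pytest.approx(0.4)

    @pytest.mark.parametrize("n_taxa", [4, 5])
    def test_additive_recovery(self, rng, n_taxa):
        labels = [f"t{i}" for i in range(n_taxa)]
        for _ in range(10):
            dmat, true_splits = _random_additive(rng, labels)
            tree = nj_tree(DistanceMatrix(taxa=list(labels), d=dmat))
            assert _tree_splits(tree) == _canon_splits(true_splits, labels)

    def test_matches_scikit_bio(self, rng):
        skbio = pytest.importorskip("skbio")
        from skbio import DistanceMatrix as SkbioDM
        from skbio.tree import nj as skbio_nj
        labels = [f"t{i}" for i in range(6)]
        dmat, _ = _random_additive(rng, labels)
        ours = nj_tree(DistanceMatrix(taxa=list(labels), d=dmat))
        theirs = skbio_nj(SkbioDM(dmat, ids=labels))
        their_splits = set()
        taxa = frozenset(labels)
        for node in theirs.non_tips():
            side = frozenset(t.name for t in node.tips())
            if 1 < len(side) < len(labels) - 1:
                their_splits.add(frozenset(
                    side if min(taxa) not in side else taxa - side))
        assert _tree_splits(ours) == their_splits

    def test_too_few_taxa(self):
        d = np.zeros((2, 2))
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(taxa=["a", "b"], d=d))

    def test_newick_round_trip(self, rng):
        labels = [f"t{i}" for i in range(6)]
        dmat, _ = _random_additive(rng, labels)
        tree = nj_tree(DistanceMatrix(taxa=list(labels), d=dmat))
        tree.support = {next(iter(_tree_splits(tree))): 87.0}
        back = load_tree(tree.newick())
        assert _tree_splits(back) == _tree_splits(tree)
        assert set(back.support.values()) == {87.0}


class TestBootstrap:
    def _aln(self, rows):
        return Alignment(records=[SequenceRecord(id=k, residues=v)
                                  for k, v in rows.items()])

    def test_congruent_sites_full_support(self):
        # 200 sites, all supporting ((a,b),(c,d))
        a = "A" * 100 + "C" * 100
        b = "A" * 100 + "C" * 100
        c = "G" * 100 + "T" * 100
        d = "G" * 100 + "T" * 100
        # add private noise so distances are nonzero within pairs
        a = "ACGT" * 10 + a
        b = "ACGT" * 10 + b
        c = "ACGA" * 10 + c
        d = "ACGA" * 10 + d
        tree = bootstrap_support(self._aln({"a": a, "b": b, "c": c, "d": d}),
                                 n_reps=50, seed=5)
        assert list(tree.support.values()) == [100.0]

    def test_deterministic(self, rng):
        rows = {f"t{i}": "".join(rng.choice(list("ACGT"), size=120))
                for i in range(5)}
        t1 = bootstrap_support(self._aln(rows), n_reps=30, seed=9)
        t2 = bootstrap_support(self._aln(rows), n_reps=30, seed=9)
        assert t1.support == t2.support


class TestConcat:
    def test_lengths_add(self):
        a = Alignment(records=[SequenceRecord(id="x", residues="ACGT"),
                               SequenceRecord(id="y", residues="AGGT")])
        b = Alignment(records=[SequenceRecord(id="y", residues="TTAACC"),
                               SequenceRecord(id="x", residues="TTAAGG")])
        cat = concat_cpdna(a, b)
        assert cat.length == 10
        assert cat.partition_boundary == 4
        assert cat.row("x").residues == "ACGTTTAAGG"

    def test_taxon_mismatch(self):
        a = Alignment(records=[SequenceRecord(id="x", residues="ACGT")])
        b = Alignment(records=[SequenceRecord(id="z", residues="ACGT")])
        with pytest.raises(AlignmentError, match="x|z"):
            concat_cpdna(a, b)


class TestCladeAssignment:
    def _tree(self):
        return load_tree("((A:1,B:1):1,(C:1,D:1):1,(out:3)):0;")

    def test_clean_clade(self):
        tree = self._tree()
        rooted = root_on_outgroup(tree, "out")
        (got,) = assign_clades(rooted, {"X": ["A", "B"]})
        assert got.members == ["A", "B"] and got.clean

    def test_anti_anchor_reported(self):
        rooted = root_on_outgroup(self._tree(), "out")
        got = {a.label: a for a in assign_clades(
            rooted, {"X": ["A", "C"], "Y": ["D"]})}
        assert not got["X"].clean
        assert "D" in got["X"].note

    def test_missing_anchor_errors(self):
        rooted = root_on_outgroup(self._tree(), "out")
        with pytest.raises(ValueError, match="missing"):
            assign_clades(rooted, {"X": ["A", "nope"]})


def test_k2p_matrix_handles_saturation(recwarn):
    recs = [SequenceRecord(id="a", residues="ACGTACGTAC"),
            SequenceRecord(id="b", residues="ACGTACGTAA"),
            SequenceRecord(id="c", residues="CAGCCAGCCA")]  # saturated vs a/b
    dm = k2p_matrix(Alignment(records=recs))
    assert np.all(np.isfinite(dm.d))
    assert any("saturated" in str(w.message).lower() for w in recwarn.list)
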