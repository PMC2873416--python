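import itertools

import numpy as np
import pytest
from skbio import DistanceMatrix as SkbioDM
from skbio import TreeNode
from skbio.tree import nj as skbio_nj

from conftest import random_alignment
from domestiscan.phylo import (DistanceMatrix, _bipartitions,
                               bootstrap_support, distance_matrix,
                               monophyly_check, neighbor_joining,
                               robinson_foulds)
from domestiscan.seqio import GenotypeMatrix, LocusAlignment
from domestiscan.simulate import SimScenario, simulate_locus


def _aln(seqs, pops=None):
    samples = [chr(ord("A") + i) for i in range(len(seqs))]
    pops = pops or {s: "wild" for s in samples}
    return LocusAlignment("t", samples, pops, seqs)


ADDITIVE = DistanceMatrix(
    ["A", "B", "C", "D"],
    np.array([[0, 3, 5, 6], [3, 0, 6, 7], [5, 6, 0, 7], [6, 7, 7, 0]],
             dtype=float),
    model="p")


class TestDistanceMatrix:
    def test_identical_pair_zero_under_all_models(self):
        aln = _aln(["ACGTACGT", "ACGTACGT"])
        for model in ("p", "jc"):
            assert distance_matrix(aln, model).matrix[0, 1] == 0.0

    def test_p_and_jc_closed_form(self):
        a = "A" * 100
        b = "T" * 10 + "A" * 90
        dm_p = distance_matrix(_aln([a, b]), "p")
        dm_jc = distance_matrix(_aln([a, b]), "jc")
        assert dm_p.matrix[0, 1] == pytest.approx(0.1)
        assert dm_jc.matrix[0, 1] == pytest.approx(0.107326, abs=1e-6)

    def test_jc_saturation_marker(self):
        a, b = "A" * 100, "T" * 80 + "A" * 20
        dm = distance_matrix(_aln([a, b]), "jc")
        assert np.isinf(dm.matrix[0, 1])

    def test_pairwise_deletion(self):
        a, b = "ACGTN", "ACTT-"
        dm = distance_matrix(_aln([a, b]), "p")
        assert dm.matrix[0, 1] == pytest.approx(1 / 4)

    def test_protein_p_uses_translation(self):
        # TTT(F) vs TTC(F): synonymous change invisible at protein level
        dm = distance_matrix(_aln(["TTTAAA", "TTCAAA"]), "protein_p")
        assert dm.matrix[0, 1] == 0.0

    def test_allele_sharing(self):
        gm = GenotypeMatrix(["a", "b", "c"], ["s1", "s2", "s3", "s4"],
                            np.array([[0, 0, 1, 1], [0, 0, 1, 1],
                                      [1, 1, 1, -1]]))
        dm = distance_matrix(gm, "allele_sharing")
        assert dm[("a", "b")] == 0.0
        assert dm[("a", "c")] == pytest.approx(2 / 3)


class TestNeighborJoining:
    def test_three_taxon_closed_form(self):
        dm = DistanceMatrix(["A", "B", "C"],
                            np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0.]]),
                            "p")
        tree = neighbor_joining(dm)
        lens = {leaf.name: leaf.length for leaf in tree.tips()}
        assert lens == pytest.approx({"A": 1.0, "B": 1.0, "C": 3.0})

    def test_additive_four_taxon_exact_recovery(self):
        """((A:1,B:2):1,(C:3,D:4)) distances are reproduced exactly."""
        tree = neighbor_joining(ADDITIVE)
        assert monophyly_check(tree, {"A", "B"})
        assert monophyly_check(tree, {"C", "D"})
        tips = {t.name: t for t in tree.tips()}
        for x, y in itertools.combinations("ABCD", 2):
            assert tips[x].distance(tips[y]) == pytest.approx(
                ADDITIVE[(x, y)], abs=1e-9)

    def test_additivity_consistency_larger_tree(self):
        """NJ reproduces all pairwise path lengths of a random additive
        matrix to 1e-9."""
        rng = np.random.default_rng(17)
        # build a random additive matrix from a random tree
        n = 8
        base = neighbor_joining(DistanceMatrix(
            [f"t{i}" for i in range(n)],
            _random_metric(rng, n), "p"))
        taxa = sorted(leaf.name for leaf in base.tips())
        tips = {t.name: t for t in base.tips()}
        mat = np.zeros((n, n))
        for i, x in enumerate(taxa):
            for j, y in enumerate(taxa):
                if i < j:
                    mat[i, j] = mat[j, i] = tips[x].distance(tips[y])
        rebuilt = neighbor_joining(DistanceMatrix(taxa, mat, "p"))
        rtips = {t.name: t for t in rebuilt.tips()}
        for x, y in itertools.combinations(taxa, 2):
            assert rtips[x].distance(rtips[y]) == pytest.approx(
                mat[taxa.index(x), taxa.index(y)], abs=1e-9)

    def test_taxon_permutation_gives_isomorphic_tree(self):
        rng = np.random.default_rng(23)
        n = 7
        taxa = [f"t{i}" for i in range(n)]
        mat = _random_metric(rng, n)
        t1 = neighbor_joining(DistanceMatrix(taxa, mat, "p"))
        perm = rng.permutation(n)
        t2 = neighbor_joining(DistanceMatrix(
            [taxa[i] for i in perm], mat[np.ix_(perm, perm)], "p"))
        assert robinson_foulds(t1, t2) == 0

    def test_topology_agrees_with_reference_nj(self):
        """Cross-check against the scikit-bio NJ implementation."""
        rng = np.random.default_rng(29)
        aln = random_alignment(rng, n=9, L=600)
        dm = distance_matrix(aln, "p")
        ours = neighbor_joining(dm)
        ref = skbio_nj(SkbioDM(dm.matrix, ids=dm.taxa))
        assert robinson_foulds(ours, ref) == 0

    def test_asymmetric_matrix_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1], [2, 0.]]), "p")


def _random_metric(rng, n):
    x = rng.random((n, 4)) * 2
    m = np.linalg.norm(x[:, None] - x[None, :], axis=2)
    np.fill_diagonal(m, 0.0)
    return m


def _brute_force_rf(t1, t2):
    """Exhaustive split enumeration for small trees."""
    return len(_splits(t1) ^ _splits(t2))


def _splits(tree):
    leaves = {l.name for l in tree.tips()}
    anchor = min(leaves)
    out = set()
    for node in tree.traverse(include_self=False):
        if node.is_tip():
            continue
        side = {l.name for l in node.tips()}
        if 1 < len(side) < len(leaves) - 1:
            out.add(frozenset(side if anchor not in side
                              else leaves - side))
    return out


class TestRobinsonFoulds:
    def test_identical_trees(self):
        t = neighbor_joining(ADDITIVE)
        assert robinson_foulds(t, t.copy()) == 0

    def test_four_taxon_conflicting_splits(self):
        t1 = TreeNode.read(["((A,B),(C,D));"])
        t2 = TreeNode.read(["((A,C),(B,D));"])
        assert robinson_foulds(t1, t2) == 2

    def test_matches_brute_force_on_random_trees(self):
        rng = np.random.default_rng(31)
        for _ in range(10):
            n = int(rng.integers(5, 9))
            t1 = neighbor_joining(DistanceMatrix(
                [f"x{i}" for i in range(n)], _random_metric(rng, n), "p"))
            t2 = neighbor_joining(DistanceMatrix(
                [f"x{i}" for i in range(n)], _random_metric(rng, n), "p"))
            assert robinson_foulds(t1, t2) == _brute_force_rf(t1, t2)

    def test_dendropy_cross_check(self):
        dendropy = pytest.importorskip("dendropy")
        rng = np.random.default_rng(37)
        n = 8
        t1 = neighbor_joining(DistanceMatrix(
            [f"x{i}" for i in range(n)], _random_metric(rng, n), "p"))
        t2 = neighbor_joining(DistanceMatrix(
            [f"x{i}" for i in range(n)], _random_metric(rng, n), "p"))
        tns = dendropy.TaxonNamespace()
        d1 = dendropy.Tree.get(data=str(t1), schema="newick",
                               taxon_namespace=tns)
        d2 = dendropy.Tree.get(data=str(t2), schema="newick",
                               taxon_namespace=tns)
        d1.encode_bipartitions()
        d2.encode_bipartitions()
        expect = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
        assert robinson_foulds(t1, t2) == expect

    def test_leaf_set_mismatch_rejected(self):
        t1 = TreeNode.read(["((A,B),(C,D));"])
        t2 = TreeNode.read(["((A,B),(C,E));"])
        with pytest.raises(ValueError):
            robinson_foulds(t1, t2)


class TestMonophyly:
    def test_single_leaf_always_monophyletic(self):
        t = TreeNode.read(["((A,B),(C,D));"])
        assert monophyly_check(t, {"A"})

    def test_ab_cd_tree(self):
        t = TreeNode.read(["((A,B),(C,D));"])
        assert monophyly_check(t, {"A", "B"})
        assert not monophyly_check(t, {"A", "C"})

    def test_matches_exhaustive_edge_scan(self):
        rng = np.random.default_rng(41)
        for _ in range(5):
            n = 7
            tree = neighbor_joining(DistanceMatrix(
                [f"x{i}" for i in range(n)], _random_metric(rng, n), "p"))
            leaves = sorted(l.name for l in tree.tips())
            splits = _splits(tree)
            anchor = min(leaves)
            for size in (2, 3):
                for subset in itertools.combinations(leaves, size):
                    sub = set(subset)
                    canon = frozenset(sub if anchor not in sub
                                      else set(leaves) - sub)
                    assert monophyly_check(tree, sub) == (canon in splits)


class TestBootstrap:
    def test_single_rep_support_binary(self):
        rng = np.random.default_rng(43)
        aln = random_alignment(rng, n=6, L=300)
        _, support = bootstrap_support(aln, "p", reps=1, seed=5)
        assert set(support.values()) <= {0.0, 1.0}

    def test_same_seed_reproducible(self):
        rng = np.random.default_rng(47)
        aln = random_alignment(rng, n=6, L=300)
        _, s1 = bootstrap_support(aln, "p", reps=20, seed=9)
        _, s2 = bootstrap_support(aln, "p", reps=20, seed=9)
        assert s1 == s2

    def test_deep_split_strongly_supported(self):
        """Two strongly diverged clades get >= 0.95 support."""
        rng = np.random.default_rng(53)
        L = 400
        anc = rng.integers(0, 4, size=L)
        a = anc.copy()
        b = anc.copy()
        b[:L // 3] = (b[:L // 3] + 1) % 4  # deep divergence between clades
        chars = np.array(list("ACGT"))
        seqs = []
        for base in (a, a, a, b, b, b):
            s = base.copy()
            idx = rng.choice(L, size=3, replace=False)  # shallow noise
            s[idx] = (s[idx] + rng.integers(1, 4, size=3)) % 4
            seqs.append("".join(chars[s]))
        aln = _aln(seqs)
        _, support = bootstrap_support(aln, "jc", reps=60, seed=3)
        focal = frozenset({"D", "E", "F"})
        assert support[focal] >= 0.95


class TestGeneVsGenomeTreeDiscordance:
    def test_introgressed_focal_locus_clusters_cultivars(self):
        """Focal-locus tree groups all cultivars; their star ancestry is
        recovered as a monophyletic cluster."""
        scn = SimScenario(seed=101, sweep=True, introgression=True)
        aln, _ = simulate_locus(scn)
        sub = aln.subset(["japonica", "indica", "wild"])
        tree = neighbor_joining(distance_matrix(sub, "jc"))
        cult = {s for s, p in sub.populations.items()
                if p in ("japonica", "indica")}
        assert monophyly_check(tree, cult)
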