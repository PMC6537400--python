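"""K2P distances, neighbor joining, bootstrap, and species demarcation."""

import io
import math

import numpy as np
import pytest

from baculoscan.phylo import (
    DistanceMatrix,
    SaturationError,
    SpeciesThresholds,
    Supermatrix,
    bootstrap_support,
    classify_species,
    concat_core_genes,
    distance_matrix_from_supermatrix,
    k2p_distance,
    nj_tree,
)
from baculoscan.synthetic import evolve_k2p, mutate_sequence, random_dna


def _pair_with_counts(n, n_ts, n_tv):
    """Aligned pair realizing exact transition/transversion counts."""
    a = ("ACGT" * (n // 4 + 1))[:n]
    b = list(a)
    ts_map = {"A": "G", "G": "A", "C": "T", "T": "C"}
    tv_map = {"A": "C", "C": "A", "G": "T", "T": "G"}
    for i in range(n_ts):
        b[i] = ts_map[b[i]]
    for i in range(n_ts, n_ts + n_tv):
        b[i] = tv_map[b[i]]
    return a, "".join(b)


class TestK2P:
    def test_identical(self):
        r = k2p_distance("ACGTACGT", "ACGTACGT")
        assert (r.P, r.Q, r.d) == (0.0, 0.0, 0.0)

    def test_closed_form(self):
        a, b = _pair_with_counts(1000, 100, 50)
        r = k2p_distance(a, b)
        assert r.P == pytest.approx(0.1)
        assert r.Q == pytest.approx(0.05)
        # independent evaluation of d = -1/2 ln[(1-2P-Q) sqrt(1-2Q)]
        assert r.d == pytest.approx(-0.5 * math.log((1 - 0.2 - 0.05) * math.sqrt(0.9)))
        assert r.d == pytest.approx(0.1702, abs=5e-5)

    def test_saturation(self):
        a, b = _pair_with_counts(1000, 500, 200)
        with pytest.raises(SaturationError):
            k2p_distance(a, b)

    def test_pairwise_deletion(self):
        r = k2p_distance("ACGTN-", "ACATNC")
        assert r.n_sites == 4
        assert r.P == pytest.approx(0.25)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            k2p_distance("ACGT", "ACG")

    def test_reduces_to_jc_under_equal_rates(self):
        """With all substitution types equally likely, K2P agrees with the
        Jukes-Cantor correction within Monte-Carlo error."""
        rng = np.random.default_rng(20)
        root = random_dna(20_000, 0.5, rng)
        # equal per-type rates: transitions get 1 share, transversions 2
        mut, realized = evolve_k2p(root, 0.05, 0.10, 42)
        r = k2p_distance(root, mut)
        p = r.P + r.Q
        d_jc = -0.75 * math.log(1 - 4 * p / 3)
        assert r.d == pytest.approx(d_jc, abs=3 * r.se)

    @pytest.mark.parametrize("seed", [21, 4])
    def test_recovers_simulated_divergence(self, seed):
        rng = np.random.default_rng(seed)
        root = random_dna(10_000, 0.4, rng)
        mut, realized = evolve_k2p(root, 0.10, 0.05, seed)
        r = k2p_distance(root, mut)
        assert abs(r.d - realized) <= 3 * r.se

    def test_single_hit_tallies_exact(self):
        """Bookkept P/Q from the single-hit mutator equal an independent
        position-wise diff tally."""
        rng = np.random.default_rng(21)
        root = random_dna(10_000, 0.4, rng)
        mut, P, Q = mutate_sequence(root, 0.10, 0.05, 21)
        ts = {"AG", "GA", "CT", "TC"}
        n_ts = sum(1 for x, y in zip(root, mut) if x != y and x + y in ts)
        n_tv = sum(1 for x, y in zip(root, mut) if x != y and x + y not in ts)
        assert P == pytest.approx(n_ts / len(root))
        assert Q == pytest.approx(n_tv / len(root))
        r = k2p_distance(root, mut)
        assert (r.P, r.Q) == (P, Q)


def random_additive_tree(n_taxa, rng):
    """Random binary tree with random branch lengths; returns (children map,
    leaf names, pairwise path-length matrix)."""
    nodes = [(f"t{i}",) for i in range(n_taxa)]
    lengths = {}
    children = {}
    nid = n_taxa
    items = list(range(n_taxa))
    parent_of = {}
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        a, b = items[i], items[j]
        for child in (a, b):
            parent_of[child] = nid
            lengths[child] = float(rng.uniform(0.05, 1.0))
        children[nid] = (a, b)
        items = [x for x in items if x not in (a, b)] + [nid]
        nid += 1
    root = items[0]

    def leaves_under(x):
        if x < n_taxa:
            return [x]
        a, b = children[x]
        return leaves_under(a) + leaves_under(b)

    def depth_to(x, leaf):
        # sum of branch lengths from node x down to leaf
        if x == leaf:
            return 0.0
        a, b = children[x]
        if leaf in leaves_under(a):
            return lengths[a] + depth_to(a, leaf)
        return lengths[b] + depth_to(b, leaf)

    D = np.zeros((n_taxa, n_taxa))
    for i in range(n_taxa):
        for j in range(i + 1, n_taxa):
            # walk up from i until j is underneath
            x = i
            up = 0.0
            while j not in leaves_under(x):
                up += lengths[x]
                x = parent_of[x]
            D[i, j] = D[j, i] = up + depth_to(x, j)
    return [f"t{i}" for i in range(n_taxa)], D


class TestNJ:
    def test_three_taxon_join(self):
        m = DistanceMatrix(["A", "B", "C"], np.array([[0, 0.2, 0.5], [0.2, 0, 0.5], [0.5, 0.5, 0]]))
        t = nj_tree(m)
        assert t.leaf_path_length("A", "B") == pytest.approx(0.2)
        assert t.leaf_path_length("A", "C") == pytest.approx(0.5)

    def test_zero_distance_cherry(self):
        vals = np.array(
            [[0, 0.0, 0.5, 0.6], [0.0, 0, 0.5, 0.6], [0.5, 0.5, 0, 0.3], [0.6, 0.6, 0.3, 0]]
        )
        t = nj_tree(DistanceMatrix(list("ABCD"), vals))
        assert t.leaf_path_length("A", "B") == pytest.approx(0.0)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError):
            DistanceMatrix(["A", "B"], np.array([[0, 1.0], [2.0, 0]]))

    @pytest.mark.parametrize("seed", range(10))
    def test_additive_recovery(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 9))
        taxa, D = random_additive_tree(n, rng)
        t = nj_tree(DistanceMatrix(taxa, D))
        for i in range(n):
            for j in range(i + 1, n):
                assert t.leaf_path_length(taxa[i], taxa[j]) == pytest.approx(
                    D[i, j], abs=1e-8
                )

    def test_agrees_with_skbio(self):
        skbio = pytest.importorskip("skbio")
        from skbio.tree import nj as sknj

        rng = np.random.default_rng(33)
        taxa, D = random_additive_tree(7, rng)
        mine = skbio.TreeNode.read(io.StringIO(nj_tree(DistanceMatrix(taxa, D)).to_newick()))
        ref = sknj(skbio.DistanceMatrix(D, ids=taxa))
        assert mine.compare_rfd(ref) == 0.0

    def test_negative_branches_clamped(self):
        # non-additive matrix that drives a raw NJ branch negative
        vals = np.array(
            [
                [0, 0.1, 0.4, 0.45],
                [0.1, 0, 0.45, 0.4],
                [0.4, 0.45, 0, 0.05],
                [0.45, 0.4, 0.05, 0],
            ]
        )
        t = nj_tree(DistanceMatrix(list("ABCD"), vals))
        assert "-" not in t.to_newick().replace("):", "):")  # no negative lengths

        def walk(node):
            assert node.length >= 0
            for c in node.children:
                walk(c)

        walk(t.root)


class TestSupermatrix:
    def test_concat_and_boundaries(self):
        gs = {
            "x": {"g1": "A" * 10, "g2": "C" * 20},
            "y": {"g1": "G" * 10, "g2": "T" * 20},
        }
        sm = concat_core_genes(gs, ["g1", "g2"])
        assert sm.width == 30
        assert sm.boundaries == [10]

    def test_canonical_order_invariance(self):
        gs1 = {"x": {"g1": "AAAA", "g2": "CC"}, "y": {"g1": "GGGG", "g2": "TT"}}
        gs2 = {"x": {"g2": "CC", "g1": "AAAA"}, "y": {"g2": "TT", "g1": "GGGG"}}
        assert (
            concat_core_genes(gs1, ["g1", "g2"]).sequences
            == concat_core_genes(gs2, ["g1", "g2"]).sequences
        )

    def test_missing_gene_error_names_taxon(self):
        gs = {"x": {"g1": "AAAA"}, "y": {}}
        with pytest.raises(ValueError, match="y.*g1"):
            concat_core_genes(gs, ["g1"])

    def test_missing_gene_gap_policy(self):
        gs = {"x": {"g1": "AAAA"}, "y": {}}
        sm = concat_core_genes(gs, ["g1"], missing_policy="gap")
        assert sm.sequences["y"] == "----"


def _clade_supermatrix(seed=2, length=600, internal=0.4, tip=0.02):
    """Four taxa in two clearly separated clades: ((A,B),(C,D))."""
    rng = np.random.default_rng(seed)
    root = random_dna(length, 0.5, rng)
    anc1, _ = evolve_k2p(root, internal / 2, internal / 4, rng)
    anc2, _ = evolve_k2p(root, internal / 2, internal / 4, rng)
    taxa = {}
    for name, anc in (("A", anc1), ("B", anc1), ("C", anc2), ("D", anc2)):
        taxa[name], _ = evolve_k2p(anc, tip, tip / 2, rng)
    return concat_core_genes({t: {"gene": s} for t, s in taxa.items()}, ["gene"])


class TestBootstrap:
    def test_strong_clades_get_full_support(self):
        sm = _clade_supermatrix()
        tree = bootstrap_support(sm, n_replicates=50, seed=3, metric="k2p")
        assert tree.support, "expected at least one internal edge"
        assert all(s >= 95.0 for s in tree.support.values())
        assert frozenset({"A", "B"}) in tree.support or frozenset({"C", "D"}) in tree.support

    def test_single_replicate_binary_support(self):
        sm = _clade_supermatrix()
        tree = bootstrap_support(sm, n_replicates=1, seed=5)
        assert set(tree.support.values()) <= {0.0, 100.0}

    def test_seed_determinism(self):
        sm = _clade_supermatrix()
        t1 = bootstrap_support(sm, 20, seed=9)
        t2 = bootstrap_support(sm, 20, seed=9)
        assert t1.to_newick() == t2.to_newick()
        assert t1.support == t2.support

    def test_taxon_order_invariance(self):
        sm = _clade_supermatrix()
        shuffled = Supermatrix(
            taxa=list(reversed(sm.taxa)),
            sequences=dict(sm.sequences),
            gene_names=sm.gene_names,
            boundaries=sm.boundaries,
        )
        t1 = bootstrap_support(sm, 20, seed=9)
        t2 = bootstrap_support(shuffled, 20, seed=9)
        assert t1.support == t2.support

    def test_nj_recovers_simulated_topology(self):
        sm = _clade_supermatrix(seed=2)
        tree = nj_tree(distance_matrix_from_supermatrix(sm, metric="k2p"))
        assert tree.bipartitions() == {frozenset({"A", "B"})} or tree.bipartitions() == {
            frozenset({"C", "D"})
        }


class TestClassifySpecies:
    def _k2p(self, d):
        from baculoscan.phylo import K2PResult

        return K2PResult(P=d / 2, Q=d / 2, d=d, n_sites=1000)

    @pytest.mark.parametrize(
        "d, verdict",
        [(0.0, "same_species"), (0.016, "ambiguous"), (0.08, "distinct_species")],
    )
    def test_thresholds(self, d, verdict):
        res = classify_species({"polh": self._k2p(d)}, self._k2p(d))
        assert res["verdict"] == verdict

    def test_saturated_flag(self):
        res = classify_species({"polh": None}, None, saturated=True)
        assert res["verdict"] == "distinct_species"
        assert res["saturation_flag"] is True
        assert res["per_gene"]["polh"] == "saturated:distinct_species"

    def test_invalid_thresholds(self):
        with pytest.raises(ValueError):
            SpeciesThresholds(0.05, 0.015)
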