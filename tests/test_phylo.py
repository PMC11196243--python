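import itertools

import numpy as np
import pytest

from vernalphylo._util import substream
from vernalphylo.phylo import (
    Dendrogram,
    faith_pd,
    inundation_regression,
    mntd,
    mpd,
    phylo_beta,
    ses,
    upgma,
    zones_monophyletic,
)
from vernalphylo.simulate import simulate_tree
from skbio import DistanceMatrix


def brute_force_pd(community, tree, include_root=True):
    """Independent oracle: sum lengths of edges on tip-to-root paths."""
    paths = []
    for leaf in tree.tree.leaf_node_iter():
        if leaf.taxon.label not in community:
            continue
        path = []
        nd = leaf
        while nd.parent_node is not None:
            path.append(nd)
            nd = nd.parent_node
        paths.append(path)
    edges = set()
    for path in paths:
        edges.update(id(nd) for nd in path)
    lengths = {
        id(nd): nd.edge.length or 0.0
        for nd in tree.tree.preorder_node_iter()
        if nd.parent_node is not None
    }
    total = sum(lengths[e] for e in edges)
    if not include_root:
        shared = set.intersection(*[set(id(nd) for nd in p) for p in paths])
        total -= sum(lengths[e] for e in shared)
    return total


class TestToyTreeOracle:
    def test_cophenetic_path_sums(self, toy_tree):
        d = toy_tree.cophenetic()
        assert d["A", "B"] == 2 and d["A", "C"] == 4 and d["B", "C"] == 4
        assert np.allclose(d.data, d.data.T)
        assert np.all(np.diag(d.data) == 0)

    def test_faith_pd_hand_values(self, toy_tree):
        assert faith_pd({"A", "B"}, toy_tree) == pytest.approx(3.0)
        assert faith_pd({"C"}, toy_tree) == pytest.approx(2.0)
        assert faith_pd({"A", "B", "C"}, toy_tree) == pytest.approx(5.0)
        assert faith_pd({"A", "B"}, toy_tree, include_root=False) == pytest.approx(2.0)
        assert faith_pd({"C"}, toy_tree, include_root=False) == 0.0

    def test_mpd_mntd_hand_values(self, toy_tree):
        d = toy_tree.cophenetic()
        assert mpd({"A", "B", "C"}, d) == pytest.approx(10 / 3)
        assert mntd({"A", "B", "C"}, d) == pytest.approx(8 / 3)
        assert mpd({"A", "C"}, d) == mntd({"A", "C"}, d) == pytest.approx(4.0)

    def test_unknown_species_listed(self, toy_tree):
        with pytest.raises(KeyError, match="ghost"):
            faith_pd({"A", "ghost"}, toy_tree)

    def test_singletons_rejected_for_pairwise_metrics(self, toy_tree):
        with pytest.raises(ValueError, match="at least two"):
            mpd({"A"}, toy_tree.cophenetic())


class TestFaithPdProperties:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("include_root", [True, False])
    def test_agrees_with_spanning_subtree_oracle_on_all_subsets(
        self, seed, include_root
    ):
        tree = simulate_tree(8, seed=seed)
        tips = tree.tip_labels
        for r in range(1, 9):
            for comm in itertools.combinations(tips, r):
                assert faith_pd(set(comm), tree, include_root=include_root) == (
                    pytest.approx(brute_force_pd(set(comm), tree, include_root))
                )

    def test_monotone_under_adding_species_and_full_pool_total(self, tree42, rng):
        tips = list(tree42.tip_labels)
        rng.shuffle(tips)
        prev = 0.0
        for k in range(1, len(tips) + 1):
            cur = faith_pd(tips[:k], tree42)
            assert cur >= prev - 1e-12
            prev = cur
        assert prev == pytest.approx(tree42.total_length)

    def test_cross_check_against_skbio(self, tree42):
        skbio_diversity = pytest.importorskip("skbio.diversity")
        from io import StringIO

        from skbio import TreeNode

        sk_tree = TreeNode.read(StringIO(tree42.to_newick()))
        rng = np.random.default_rng(0)
        tips = tree42.tip_labels
        for _ in range(25):
            k = int(rng.integers(1, 30))
            comm = list(rng.choice(tips, size=k, replace=False))
            counts = [1] * len(comm)
            expected = skbio_diversity.alpha.faith_pd(counts, comm, sk_tree)
            assert faith_pd(comm, tree42) == pytest.approx(expected)


def test_mntd_never_exceeds_mpd_on_random_communities(tree42, rng):
    d = tree42.cophenetic()
    tips = tree42.tip_labels
    for _ in range(1000):
        k = int(rng.integers(2, 42))
        comm = list(rng.choice(tips, size=k, replace=False))
        assert mntd(comm, d) <= mpd(comm, d) + 1e-12


class TestSes:
    def test_reproducible_bit_for_bit(self, tree42):
        comm = tree42.tip_labels[:10]
        a = ses("MPD", comm, tree42, n_perm=199, seed=5)
        b = ses("MPD", comm, tree42, n_perm=199, seed=5)
        assert a == b

    def test_full_pool_is_degenerate(self, tree42):
        res = ses("MPD", tree42.tip_labels, tree42, n_perm=99, seed=1)
        assert res.degenerate and res.verdict is None
        assert res.null_sd == 0.0

    def test_rank_p_within_permutation_grid(self, tree42):
        res = ses("MNTD", tree42.tip_labels[:8], tree42, n_perm=199, seed=2)
        assert 1 / 200 <= res.rank_p <= 1.0
        assert res.ses == pytest.approx(
            (res.observed - res.null_mean) / res.null_sd
        )

    def test_unknown_metric_rejected(self, tree42):
        with pytest.raises(ValueError, match="metric"):
            ses("RICHNESS", tree42.tip_labels[:5], tree42, seed=0)


class TestPhyloBeta:
    def test_singleton_communities_give_pairwise_distance(self, toy_tree):
        dm = phylo_beta({"X": {"A"}, "Y": {"C"}}, toy_tree.cophenetic())
        assert dm["X", "Y"] == pytest.approx(4.0)

    def test_identical_communities_off_diagonal_is_self_mean(self, toy_tree):
        d = toy_tree.cophenetic()
        dm = phylo_beta({"X": {"A", "B"}, "Y": {"A", "B"}}, d)
        # cross-community mean includes the zero self-pairs: (0+2+2+0)/4
        assert dm["X", "Y"] == pytest.approx(1.0)

    def test_empty_community_rejected(self, toy_tree):
        with pytest.raises(ValueError, match="empty"):
            phylo_beta({"X": set(), "Y": {"A"}}, toy_tree.cophenetic())


class TestUpgma:
    def test_hand_computed_merge_heights(self):
        dm = DistanceMatrix(
            [[0, 1, 4], [1, 0, 4], [4, 4, 0]], ids=["a", "b", "c"]
        )
        dend = upgma(dm)
        assert dend.merge_heights == pytest.approx([0.5, 2.0])
        assert frozenset({"a", "b"}) in dend.leaf_sets()

    def test_newick_round_trip_is_ultrametric(self):
        from vernalphylo.phylogeny import Phylogeny

        dm = DistanceMatrix(
            [[0, 1, 4, 5], [1, 0, 4, 5], [4, 4, 0, 5], [5, 5, 5, 0]],
            ids=list("abcd"),
        )
        tree = Phylogeny.from_newick(upgma(dm).to_newick())
        depths = tree.tip_depths()
        assert np.allclose(depths, depths[0])

    def test_zones_monophyletic_calls(self):
        dm = DistanceMatrix(
            [[0, 1, 4, 4], [1, 0, 4, 4], [4, 4, 0, 1], [4, 4, 1, 0]],
            ids=["b1", "b2", "e1", "e2"],
        )
        dend = upgma(dm)
        calls = zones_monophyletic(
            dend, {"b1": "bottom", "b2": "bottom", "e1": "edge", "e2": "edge"}
        )
        assert calls == {"bottom": True, "edge": True}

    def test_interleaved_zone_not_monophyletic(self):
        dm = DistanceMatrix(
            [[0, 4, 1, 4], [4, 0, 4, 1], [1, 4, 0, 4], [4, 1, 4, 0]],
            ids=["b1", "b2", "e1", "e2"],
        )
        calls = zones_monophyletic(
            upgma(dm), {"b1": "bottom", "b2": "bottom", "e1": "edge", "e2": "edge"}
        )
        assert not (calls["bottom"] and calls["edge"])

    def test_unmapped_leaf_rejected(self):
        dm = DistanceMatrix([[0, 1], [1, 0]], ids=["x", "y"])
        with pytest.raises(KeyError):
            zones_monophyletic(upgma(dm), {"x": "bottom"})


class TestInundationRegression:
    def test_exact_linear_fit_recovered(self):
        import pandas as pd

        x = np.arange(10, dtype=float)
        df = pd.DataFrame(
            {"zone": "edge", "inundation": x, "ses": -0.35 * x + 1.0}
        ).rename(columns={"ses": "ses_mntd"})
        out = inundation_regression(df, "ses_mntd")
        assert out.loc[0, "estimate"] == pytest.approx(-0.35)
        assert out.loc[0, "r_squared"] == pytest.approx(1.0)

    def test_constant_response_gives_zero_slope(self):
        import pandas as pd

        df = pd.DataFrame(
            {"zone": "bottom", "inundation": [1.0, 2, 3, 4], "y": [2.0, 2, 2, 2]}
        )
        out = inundation_regression(df, "y")
        assert out.loc[0, "estimate"] == pytest.approx(0.0, abs=1e-10)

    def test_zero_variance_predictor_rejected(self):
        import pandas as pd

        df = pd.DataFrame(
            {"zone": "bottom", "inundation": [2.0, 2, 2], "y": [1.0, 2, 3]}
        )
        with pytest.raises(ValueError, match="zero variance"):
            inundation_regression(df, "y")
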