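import warnings

import numpy as np
import pytest

from vernalphylo._util import substream
from vernalphylo.communities import ZONES, aggregate
from vernalphylo.simulate import (
    SimulationConfig,
    choose_clade,
    simulate_climate,
    simulate_dataset,
    simulate_traits,
    simulate_tree,
)


class TestTree:
    def test_two_species_is_an_ultrametric_cherry(self):
        t = simulate_tree(2, seed=0)
        depths = t.tip_depths()
        assert t.n_tips == 2
        assert depths == pytest.approx([1.0, 1.0])

    def test_determinism_under_seed(self):
        assert simulate_tree(42, seed=9).to_newick() == simulate_tree(42, seed=9).to_newick()
        assert simulate_tree(42, seed=9).to_newick() != simulate_tree(42, seed=10).to_newick()

    def test_binary_tree_node_count(self):
        t = simulate_tree(42, seed=1)
        internal = sum(1 for _ in t.tree.preorder_internal_node_iter())
        assert internal == 41
        assert t.n_polytomies == 0

    def test_depth_scaled_to_one(self):
        depths = simulate_tree(15, seed=3).tip_depths()
        assert np.allclose(depths, 1.0)

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            simulate_tree(1, seed=0)


class TestTraits:
    def test_same_seed_gives_identical_table(self, tree42):
        a = simulate_traits(tree42, seed=4)
        b = simulate_traits(tree42, seed=4)
        assert a.df.equals(b.df)

    def test_small_rate_collapses_tolerance_to_root_value(self, tree42):
        t = simulate_traits(tree42, bm_rate=1e-10, seed=0)
        assert np.allclose(t.df["tolerance"], 0.0, atol=1e-3)

    def test_nonpositive_rate_rejected(self, tree42):
        with pytest.raises(ValueError):
            simulate_traits(tree42, bm_rate=0.0)

    def test_close_relatives_have_smaller_tolerance_differences(self):
        """BM variance grows with path length: siblings diverge less than
        distant tips, on average over many seeds."""
        sib_diffs, far_diffs = [], []
        for seed in range(40):
            tree = simulate_tree(30, rng=substream(seed, "tree"))
            traits = simulate_traits(tree, rng=substream(seed, "traits"),
                                     tolerance_burst=0.0)
            tol = traits.trait("tolerance")
            d = tree.cophenetic()
            labels = tree.tip_labels
            iu = np.triu_indices(len(labels), 1)
            dist = d.data[iu]
            diffs = np.abs(
                tol[np.array(labels)[iu[0]]].to_numpy()
                - tol[np.array(labels)[iu[1]]].to_numpy()
            )
            sib_diffs.append(diffs[dist <= np.quantile(dist, 0.2)].mean())
            far_diffs.append(diffs[dist >= np.quantile(dist, 0.8)].mean())
        assert np.mean(sib_diffs) < np.mean(far_diffs)

    def test_positive_traits_and_invasive_boost(self, tree42):
        inv = frozenset(tree42.tip_labels[:5])
        t = simulate_traits(tree42, seed=2, invasives=inv, invasive_trait_boost=3.0)
        assert (t.df[["height", "leaf_area", "seed_mass"]] > 0).all().all()
        assert t.invasives == inv
        base = simulate_traits(tree42, seed=2, invasives=inv, invasive_trait_boost=1.0)
        ratio = t.df.loc[sorted(inv), "height"] / base.df.loc[sorted(inv), "height"]
        assert np.allclose(ratio, 3.0)


class TestChooseClade:
    def test_choice_is_a_tight_clade_near_requested_size(self, tree42):
        tips = choose_clade(tree42, 6, substream(0, "c"))
        # closest available clade size is used when no 6-tip node exists
        assert 4 <= len(tips) <= 8
        mrca = tree42.tree.mrca(taxon_labels=sorted(tips))
        assert len(list(mrca.leaf_iter())) <= 2 * 6

    def test_exclusion_respected(self, tree42):
        left = choose_clade(tree42, 10, substream(1, "c"))
        right = choose_clade(tree42, 6, substream(2, "c"), exclude=left)
        assert not (left & right)

    def test_zero_size_empty(self, tree42):
        assert choose_clade(tree42, 0, substream(0, "c")) == frozenset()


class TestAssembly:
    def test_same_config_gives_identical_collection(self):
        cfg = SimulationConfig(seed=6)
        a, b = simulate_dataset(cfg), simulate_dataset(cfg)
        assert [o.key() for o in a.communities] == [o.key() for o in b.communities]
        assert [o.species for o in a.communities] == [o.species for o in b.communities]

    def test_zone_richness_in_field_range(self):
        """Zone-pooled richness lands in the 9-25 species band."""
        vals = {z: [] for z in ZONES}
        for seed in range(6):
            ds = simulate_dataset(SimulationConfig(seed=seed))
            for o in aggregate(ds.communities, "zone-pooled"):
                vals[o.zone].append(o.richness)
        for z, v in vals.items():
            assert 5 <= np.mean(v) <= 30, (z, v)

    def test_neutral_config_equalizes_zones(self):
        """Without filtering or bias, per-zone richness differs only by
        sampling noise."""
        means = {z: [] for z in ZONES}
        for seed in range(8):
            ds = simulate_dataset(SimulationConfig.neutral(seed=seed))
            for o in aggregate(ds.communities, "zone-pooled"):
                means[o.zone].append(o.richness)
        grand = np.mean([np.mean(v) for v in means.values()])
        for z, v in means.items():
            assert abs(np.mean(v) - grand) < 3.0

    def test_strong_bottom_filter_narrows_tolerance_band(self):
        cfg = SimulationConfig(
            seed=3, filter_strength={"bottom": 10.0, "edge": 0.0, "upland": 0.0}
        )
        ds = simulate_dataset(cfg)
        tol = ds.traits.trait("tolerance")
        tol = (tol - tol.mean()) / tol.std(ddof=0)
        pooled = {o.zone: o.species for o in aggregate(ds.communities, "zone-pooled")}
        assert tol[sorted(pooled["bottom"])].std() < tol[sorted(pooled["edge"])].std()

    def test_invasives_concentrate_in_upland(self):
        counts = {"bottom": 0, "upland": 0}
        for seed in range(8):
            ds = simulate_dataset(SimulationConfig(seed=seed))
            inv = ds.traits.invasives
            pooled = {o.zone: o.species for o in aggregate(ds.communities, "zone-pooled")}
            counts["bottom"] += len(pooled.get("bottom", frozenset()) & inv)
            counts["upland"] += len(pooled.get("upland", frozenset()) & inv)
        assert counts["upland"] > counts["bottom"]

    def test_weeks_respect_truncated_years(self):
        ds = simulate_dataset(SimulationConfig(seed=2))
        by_year = {}
        for o in ds.communities:
            by_year.setdefault(o.year, set()).add(o.week)
        assert max(by_year[2019]) <= 7
        assert max(by_year[2021]) <= 9


class TestClimate:
    def test_zero_amplitude_zero_noise_is_constant(self):
        cs = simulate_climate(1, seed=0, amplitude=0.0, noise_sd=0.0)
        assert cs.df["tmean"].nunique() == 1
        assert (cs.df["tmin"] <= cs.df["tmean"]).all()
        assert (cs.df["tmean"] <= cs.df["tmax"]).all()

    def test_annual_totals_exact(self):
        cs = simulate_climate(3, seed=1, annual_totals=[100.0, 250.0, 400.0])
        wy = cs.df["date"].dt.year + (cs.df["date"].dt.month >= 10).astype(int)
        sums = cs.df.groupby(wy)["precipitation"].sum()
        assert np.allclose(sums.to_numpy(), [100.0, 250.0, 400.0])

    def test_same_seed_identical(self):
        a = simulate_climate(2, seed=5)
        b = simulate_climate(2, seed=5)
        assert a.df.equals(b.df)

    def test_winter_concentration(self):
        cs = simulate_climate(3, seed=2)
        month = cs.df["date"].dt.month
        winter = cs.df.loc[month.isin([11, 12, 1, 2]), "precipitation"].sum()
        summer = cs.df.loc[month.isin([5, 6, 7, 8]), "precipitation"].sum()
        assert winter > summer
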