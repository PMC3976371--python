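"""Partitioned RAD mechanics: inclusion filters, per-locus tree tables,
favor/disfavor windows, the support regression and island trimming."""

import numpy as np
import pandas as pd
import pytest

from radpartition.locus_matrix import Locus, concatenate
from radpartition.partitioned_rad import (
    FavorTable,
    LocusTreeTable,
    PartitionConfig,
    compute_pool_lls,
    favor_disfavor,
    filter_partition_loci,
    locus_tree_table,
    support_regression,
    trim_likelihood_islands,
)
from radpartition.phylo_engine import (
    SubstModel,
    optimize_branch_lengths,
    site_log_likelihoods,
)
from radpartition.synth_rad import SimConfig, simulate_loci, simulate_tree
from radpartition.tree_ops import PrunedTreeSet, TreePool, build_tree_pool, canonical_id


@pytest.fixture(scope="module")
def small_pool():
    tree = simulate_tree(8, 0.3, 10)
    return tree, build_tree_pool(tree, 12, rng_seed=3)


@pytest.fixture(scope="module")
def small_setup(small_pool):
    tree, pool = small_pool
    model = SubstModel(alpha=1.0)
    cfg = SimConfig(n_taxa=8, n_loci=25, locus_length=70, tree_depth=0.3,
                    rng_seed=10, min_individuals=8, model=model)
    truth, loci = simulate_loci(tree, cfg)
    return tree, pool, model, loci


class TestFilterPartitionLoci:
    def test_drop_reasons(self, small_pool):
        tree, pool = small_pool
        taxa = tree.taxa()
        few = Locus("few", {t: "ACGTACGT" for t in taxa[:3]})
        invariant = Locus("inv", {t: "ACGTACGT" for t in taxa})
        cfg = PartitionConfig(min_trees=5)
        kept, _, dropped = filter_partition_loci([few, invariant], pool, cfg)
        assert kept == []
        assert dict(dropped) == {"few": "min_individuals", "inv": "no_PI"}

    def test_full_taxon_locus_keeps_whole_pool(self, small_setup):
        tree, pool, model, loci = small_setup
        cfg = PartitionConfig(min_trees=len(pool))
        kept, pruned, _ = filter_partition_loci(loci[:5], pool, cfg)
        assert all(len(p) == len(pool) for p in pruned)


class TestLocusTreeTable:
    def test_invariant_locus_excluded(self, small_pool):
        tree, pool = small_pool
        locus = Locus("inv", {t: "A" * 60 for t in tree.taxa()})
        pruned = PrunedTreeSet(trees=[t.copy() for t in pool.trees[:3]],
                               index_map=list(range(3)))
        model = SubstModel(alpha=1.0)
        tab = locus_tree_table(locus, pruned, model)
        assert tab.ll_range == pytest.approx(0.0, abs=1e-6)
        assert tab.excluded

    def test_generating_topology_preferred_with_strong_signal(self, small_pool):
        # long loci leave little gene-tree estimation error: the
        # generating topology's pruned representative wins
        tree, pool = small_pool
        model = SubstModel(alpha=1.0)
        cfg = SimConfig(n_taxa=8, n_loci=3, locus_length=600, tree_depth=0.3,
                        rng_seed=4, min_individuals=8, model=model)
        _, loci = simulate_loci(tree, cfg)
        pcfg = PartitionConfig(min_trees=5)
        kept, pruned, _ = filter_partition_loci(loci, pool, pcfg)
        for locus, p in zip(kept, pruned):
            tab = locus_tree_table(locus, p, model)
            # the generating topology is within the favoring window of the
            # best tree, and the pool is strongly discriminated overall
            assert tab.lls[p.index_map[0]] >= tab.lls.max() - 2.0
            assert tab.ll_range > 20.0

    def test_table_matches_independent_engine_calls(self, small_setup):
        tree, pool, model, loci = small_setup
        cfg = PartitionConfig(min_trees=5)
        kept, pruned, _ = filter_partition_loci(loci[:2], pool, cfg)
        tab = locus_tree_table(kept[0], pruned[0], model, optimize=False)
        for i, ptree in enumerate(pruned[0].trees):
            direct = float(site_log_likelihoods(kept[0].rows, ptree, model).sum())
            assert tab.lls[i] == pytest.approx(direct, abs=1e-6)


class TestFavorDisfavor:
    def _table(self, lid, lls, index_map=None):
        lls = np.asarray(lls, float)
        return LocusTreeTable(
            locus_id=lid, lls=lls,
            index_map=index_map or list(range(len(lls))),
            ll_range=float(lls.max() - lls.min()), excluded=False,
        )

    def _pool(self, n):
        from radpartition.tree_ops import nni_neighbors

        tree = simulate_tree(8, 0.1, 1)
        trees = [tree] + nni_neighbors(tree)[: n - 1]
        return TreePool(trees=trees,
                        origin=["optimal"] + ["nni1"] * (len(trees) - 1),
                        ids=[canonical_id(t) for t in trees])

    def test_window_arithmetic(self):
        pool = self._pool(3)
        cfg = PartitionConfig(min_trees=2)
        tab = self._table("l1", [-100.0, -101.5, -110.0])
        favor = favor_disfavor([tab], pool, cfg)
        assert list(favor.frame["n_favoring"]) == [1, 1, 0]
        assert list(favor.frame["n_disfavoring"]) == [0, 0, 1]

    def test_excluded_table_contributes_nothing(self):
        pool = self._pool(3)
        cfg = PartitionConfig(min_trees=2)
        tab = self._table("l1", [-5.0, -5.0, -5.0])
        tab.excluded = True
        favor = favor_disfavor([tab], pool, cfg)
        assert favor.n_loci == 0
        assert favor.frame["n_favoring"].sum() == 0

    def test_every_locus_favors_at_least_one_tree(self, rng):
        pool = self._pool(8)
        cfg = PartitionConfig(min_trees=2)
        tabs = [self._table(f"l{i}", rng.normal(-100, 5, len(pool)))
                for i in range(30)]
        favor = favor_disfavor(tabs, pool, cfg)
        assert favor.frame["n_favoring"].sum() >= favor.n_loci

    def test_invariant_to_locus_order(self, rng):
        pool = self._pool(6)
        cfg = PartitionConfig(min_trees=2)
        tabs = [self._table(f"l{i}", rng.normal(-100, 5, len(pool)))
                for i in range(20)]
        f1 = favor_disfavor(tabs, pool, cfg)
        f2 = favor_disfavor(list(reversed(tabs)), pool, cfg)
        pd.testing.assert_frame_equal(f1.frame, f2.frame)

    def test_pool_trees_inherit_representative_status(self):
        pool = self._pool(4)
        cfg = PartitionConfig(min_trees=2)
        # two pool trees share pruned representative 0
        tab = self._table("l1", [-100.0, -120.0], index_map=[0, 0, 1, 1])
        favor = favor_disfavor([tab], pool, cfg)
        assert list(favor.frame["n_favoring"]) == [1, 1, 0, 0]
        assert list(favor.frame["n_disfavoring"]) == [0, 0, 1, 1]


class TestSupportRegression:
    def _favor(self, lls, counts, pool=None):
        n = len(lls)
        origin = ["optimal"] + ["nni1"] * (n - 1) if pool is None else pool.origin[:n]
        frame = pd.DataFrame({
            "origin": origin,
            "total_ll": lls,
            "n_favoring": counts,
            "n_disfavoring": 0,
        })
        return FavorTable(frame=frame, n_loci=int(max(counts)))

    def test_exact_linearity_no_outliers(self):
        lls = np.linspace(-1100, -1000, 11)
        counts = 2.0 * (lls + 1100) + 5
        rep = support_regression(self._favor(lls, counts))
        assert rep.residual_sd == pytest.approx(0.0, abs=1e-8)
        assert not rep.frame["outlier"].any()
        assert rep.slope == pytest.approx(2.0)

    def test_nominal_coverage(self):
        """~5% of trees fall outside the 95% interval under a Gaussian
        linear null (200 trees, 1,000 replicates)."""
        rng = np.random.default_rng(0)
        outside = []
        for _ in range(1000):
            x = rng.uniform(-1200, -1000, 200)
            y = 3.0 * (x + 1200) + rng.normal(0, 10, 200)
            favor = self._favor(x, y)
            rep = support_regression(favor, level=0.95)
            out = ((rep.frame["n_favoring"] > rep.frame["pi_upper"])
                   | (rep.frame["n_favoring"] < rep.frame["pi_lower"])).mean()
            outside.append(out)
        assert abs(np.mean(outside) - 0.05) < 0.01

    def test_inflated_count_flagged(self):
        rng = np.random.default_rng(4)
        x = np.linspace(-1100, -1000, 40)
        y = 2.0 * (x + 1100) + rng.normal(0, 5, 40)
        y[7] += 10 * 5.0
        rep = support_regression(self._favor(x, y))
        assert bool(rep.frame.iloc[7]["outlier"])

    def test_degenerate_regressor_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            support_regression(self._favor(np.full(5, -100.0), np.arange(5.0)))


class TestTrimIslands:
    def _favor(self, lls):
        frame = pd.DataFrame({
            "origin": ["optimal"] + ["nni1"] * (len(lls) - 1),
            "total_ll": lls,
            "n_favoring": np.arange(len(lls)),
            "n_disfavoring": 0,
        })
        return FavorTable(frame=frame, n_loci=10)

    def test_cut_below_everything_is_identity(self):
        favor = self._favor(np.linspace(-1100, -1000, 6))
        trimmed = trim_likelihood_islands(favor, -2000)
        assert len(trimmed) == len(favor)

    def test_cut_above_everything_raises(self):
        favor = self._favor(np.linspace(-1100, -1000, 6))
        with pytest.raises(ValueError):
            trim_likelihood_islands(favor, -1.0)

    def test_bimodal_keeps_upper_mode(self):
        lls = np.concatenate([np.linspace(-5000, -4900, 3),
                              np.linspace(-1100, -1000, 3)])
        trimmed = trim_likelihood_islands(self._favor(lls), -2000)
        assert len(trimmed) == 3
        assert (trimmed.frame["total_ll"] > -2000).all()


def test_scatter_plot_written(tmp_path, rng):
    from radpartition.partitioned_rad import plot_partitioned_rad

    x = np.linspace(-1100, -1000, 12)
    y = 2.0 * (x + 1100) + rng.normal(0, 3, 12)
    frame = pd.DataFrame({
        "origin": ["optimal"] + ["nni1"] * 11,
        "total_ll": x, "n_favoring": y, "n_disfavoring": 0,
    })
    favor = FavorTable(frame=frame, n_loci=25)
    report = support_regression(favor)
    out = tmp_path / "favor.png"
    plot_partitioned_rad(favor, report, out)
    assert out.stat().st_size > 0
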