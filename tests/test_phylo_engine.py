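"""Likelihood engine against independent oracles: exhaustive state
enumeration, Jukes-Cantor closed forms, brute-force Fitch, and
parameter-recovery simulations."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from radpartition.phylo_engine import (
    _CODE,
    _Eigen,
    LikelihoodEngine,
    SubstModel,
    bootstrap_support,
    classify_characters,
    consistency_index,
    discrete_gamma_rates,
    estimate_model,
    fitch_steps,
    neighbor_joining_tree,
    nni_hill_climb,
    optimize_branch_lengths,
    site_log_likelihoods,
    total_log_likelihood,
)
from radpartition.synth_rad import SimConfig, simulate_loci, simulate_tree
from radpartition.tree_ops import Tree, canonical_id, robinson_foulds
from radpartition.locus_matrix import concatenate


# ---------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------

def brute_force_site_lls(matrix, tree, model):
    """Likelihood by exhaustive summation over all internal-node state
    assignments, per site and rate category."""
    eig = _Eigen(model)
    rates = discrete_gamma_rates(model.alpha, model.n_categories)
    root = tree.default_root()
    order = tree.postorder(root)
    nodes = [n for n, _, _ in order]
    internal = [n for n in nodes if tree.degree(n) > 1]
    parent = {n: p for n, p, _ in order}
    length = {n: l for n, _, l in order}
    L = len(next(iter(matrix.values())))
    out = []
    for site in range(L):
        site_l = 0.0
        for r in rates:
            P = {n: eig.pmats(length[n], np.array([r]))[0]
                 for n in nodes if parent[n] is not None}
            tot = 0.0
            for assign in itertools.product(range(4), repeat=len(internal)):
                amap = dict(zip(internal, assign))
                p = eig.pi[amap[root]]
                for n in nodes:
                    if parent[n] is None:
                        continue
                    if tree.degree(n) == 1:
                        code = _CODE[matrix[tree.label[n]][site]]
                        p *= sum(P[n][amap[parent[n]], b]
                                 for b in range(4) if code >> b & 1)
                    else:
                        p *= P[n][amap[parent[n]], amap[n]]
                tot += p
            site_l += tot / len(rates)
        out.append(np.log(site_l))
    return np.array(out)


def brute_force_fitch(matrix, tree):
    """Minimum changes over all internal-node labelings, summed over sites."""
    root = tree.default_root()
    order = tree.postorder(root)
    nodes = [n for n, _, _ in order]
    internal = [n for n in nodes if tree.degree(n) > 1]
    parent = {n: p for n, p, _ in order}
    L = len(next(iter(matrix.values())))
    total = 0
    for site in range(L):
        best = np.inf
        leaf_sets = {
            n: [b for b in range(4) if _CODE[matrix[tree.label[n]][site]] >> b & 1]
            for n in nodes if tree.degree(n) == 1
        }
        for assign in itertools.product(range(4), repeat=len(internal)):
            amap = dict(zip(internal, assign))
            cost = 0
            for n in nodes:
                p = parent[n]
                if p is None:
                    continue
                def state_opts(x):
                    return leaf_sets[x] if tree.degree(x) == 1 else [amap[x]]
                cost += min(1 if a != b else 0
                            for a in state_opts(n) for b in state_opts(p))
            best = min(best, cost)
        total += int(best)
    return total


def random_alignment(rng, taxa, n_sites, alphabet="ACGT"):
    return {t: "".join(rng.choice(list(alphabet), n_sites)) for t in taxa}


# ---------------------------------------------------------------------
# likelihood
# ---------------------------------------------------------------------

class TestSiteLogLikelihoods:
    def test_identical_sequences_zero_branches(self, jc_model):
        t = Tree()
        a, b = t.new_node("A"), t.new_node("B")
        t.add_edge(a, b, 1e-8)
        lls = site_log_likelihoods({"A": "ACGT", "B": "ACGT"}, t, jc_model)
        assert np.allclose(lls, np.log(0.25), atol=1e-4)

    def test_two_taxon_jc_closed_form(self, jc_model):
        t = Tree()
        a, b = t.new_node("A"), t.new_node("B")
        d = 0.2
        t.add_edge(a, b, d)
        lls = site_log_likelihoods({"A": "ACGT", "B": "AAGT"}, t, jc_model)
        p_same = 0.25 + 0.75 * np.exp(-4 * d / 3)
        p_diff = 0.25 - 0.25 * np.exp(-4 * d / 3)
        expected = np.log([0.25 * p_same, 0.25 * p_diff, 0.25 * p_same, 0.25 * p_same])
        assert np.allclose(lls, expected, atol=1e-12)

    def test_matches_exhaustive_oracle_five_taxa(self, gtr_model, rng):
        t = simulate_tree(5, 0.3, 7)
        mat = random_alignment(rng, t.taxa(), 4)
        mat["t01"] = mat["t01"][:2] + "N-"
        ours = site_log_likelihoods(mat, t, gtr_model)
        oracle = brute_force_site_lls(mat, t, gtr_model)
        assert np.allclose(ours, oracle, atol=1e-8)

    @settings(max_examples=12, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_matches_exhaustive_oracle_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(4, 7))
        n_sites = int(rng.integers(1, 7))
        t = simulate_tree(n_taxa, 0.4, seed % 100000)
        freqs = rng.dirichlet([5, 5, 5, 5])
        model = SubstModel(
            base_freqs=tuple(freqs),
            exchangeabilities=tuple(rng.uniform(0.3, 3.0, 5)) + (1.0,),
            alpha=float(rng.uniform(0.3, 3.0)),
            n_categories=int(rng.integers(1, 4)),
        )
        mat = random_alignment(rng, t.taxa(), n_sites, alphabet="ACGTN")
        ours = site_log_likelihoods(mat, t, model)
        oracle = brute_force_site_lls(mat, t, model)
        assert np.allclose(ours, oracle, atol=1e-8)

    def test_invariant_under_rerooting(self, gtr_model, rng):
        t = simulate_tree(7, 0.3, 5)
        mat = random_alignment(rng, t.taxa(), 30)
        ref = total_log_likelihood(mat, t, gtr_model)
        for leaf in list(t.leaves())[:4]:
            rerooted = Tree.from_newick(t.to_newick(root=next(iter(t.adj[leaf]))))
            assert total_log_likelihood(mat, rerooted, gtr_model) == pytest.approx(ref, abs=1e-8)

    def test_single_category_equals_plain_gtr(self, rng):
        t = simulate_tree(5, 0.2, 9)
        mat = random_alignment(rng, t.taxa(), 20)
        m1 = SubstModel(alpha=1.0, n_categories=1)
        m2 = SubstModel(alpha=123.0, n_categories=1)  # alpha ignored at k=1
        assert total_log_likelihood(mat, t, m1) == pytest.approx(
            total_log_likelihood(mat, t, m2), abs=1e-10
        )

    def test_empty_alignment(self, jc_model):
        t = simulate_tree(4, 0.1, 1)
        assert site_log_likelihoods({x: "" for x in t.taxa()}, t, jc_model).size == 0


class TestOptimizeBranchLengths:
    def test_two_taxon_recovery(self, jc_model):
        rng = np.random.default_rng(11)
        eig = _Eigen(jc_model)
        seqA = rng.choice(4, 10000)
        P = eig.pmats(0.1, np.ones(1))[0]
        seqB = np.array([rng.choice(4, p=P[s]) for s in seqA])
        mat = {"A": "".join("ACGT"[s] for s in seqA),
               "B": "".join("ACGT"[s] for s in seqB)}
        t = Tree()
        a, b = t.new_node("A"), t.new_node("B")
        t.add_edge(a, b, 0.5)
        opt, _ = optimize_branch_lengths(mat, t, jc_model)
        assert abs(next(iter(opt.edges()))[2] - 0.1) < 0.02

    def test_identical_sequences_hit_lower_clamp(self, jc_model):
        t = simulate_tree(4, 0.2, 3)
        mat = {x: "ACGT" * 20 for x in t.taxa()}
        opt, _ = optimize_branch_lengths(mat, t, jc_model)
        assert all(l < 1e-6 for _, _, l in opt.edges())

    def test_fixed_point(self, gtr_model, strong_signal_dataset):
        truth, loci = strong_signal_dataset
        mat = concatenate(loci, truth.tree.taxa()).matrix
        opt, ll1 = optimize_branch_lengths(mat, truth.tree, gtr_model)
        opt2, ll2 = optimize_branch_lengths(mat, opt, gtr_model)
        assert ll2 - ll1 < 1e-3 + 1e-6
        assert ll2 >= ll1 - 1e-6


class TestEstimateModel:
    def test_rate_ratio_recovery(self):
        true = SubstModel(
            exchangeabilities=(1.0, 2.0, 1.0, 1.0, 2.0, 1.0), alpha=50.0,
            n_categories=1,
        )
        tree = simulate_tree(6, 0.3, 21)
        cfg = SimConfig(n_taxa=6, n_loci=40, locus_length=500, tree_depth=0.3,
                        rng_seed=21, min_individuals=6, model=true)
        truth, loci = simulate_loci(tree, cfg)
        mat = concatenate(loci, tree.taxa()).matrix
        model, _, _ = estimate_model(mat, tree, n_categories=1)
        # AG/AC exchangeability ratio is 2 in truth
        ratio = model.exchangeabilities[1] / model.exchangeabilities[0]
        assert abs(ratio - 2.0) / 2.0 < 0.25

    def test_equal_frequencies_recovered(self, strong_signal_dataset):
        truth, loci = strong_signal_dataset
        mat = concatenate(loci, truth.tree.taxa()).matrix
        model, _, _ = estimate_model(mat, truth.tree, n_outer=1)
        assert np.allclose(model.base_freqs, 0.25, atol=0.02)


# ---------------------------------------------------------------------
# parsimony and census
# ---------------------------------------------------------------------

class TestFitch:
    def test_invariant_column_zero_steps(self):
        t = simulate_tree(5, 0.1, 2)
        assert fitch_steps({x: "AAA" for x in t.taxa()}, t) == 0

    def test_unlike_grouping_quartet(self):
        t = Tree.from_newick("((A1,C1),(A2,C2));")
        mat = {"A1": "A", "C1": "C", "A2": "A", "C2": "C"}
        assert fitch_steps(mat, t) == 2
        assert fitch_steps(mat, t) == brute_force_fitch(mat, t)

    def test_single_observed_taxon_zero_steps(self):
        t = simulate_tree(5, 0.1, 4)
        mat = {x: "N" for x in t.taxa()}
        mat[t.taxa()[0]] = "A"
        assert fitch_steps(mat, t) == 0

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 10 ** 6))
    def test_matches_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_taxa = int(rng.integers(4, 7))
        t = simulate_tree(n_taxa, 0.2, seed % 99991)
        mat = random_alignment(rng, t.taxa(), int(rng.integers(1, 5)), "ACGTNR-")
        assert fitch_steps(mat, t) == brute_force_fitch(mat, t)


class TestCharacterCensus:
    def test_variable_and_informative_classes(self):
        mat = {"a": "AAN", "b": "AAN", "c": "GAN", "d": "GGN"}
        census = classify_characters(mat)
        assert census.n_variable == 2
        assert census.n_parsimony_informative == 1
        assert census.n_all_missing_excluded == 1
        assert census.missing_proportion == pytest.approx(4 / 12)


class TestConsistencyIndex:
    def test_homoplasy_free_matrix(self, strong_signal_dataset):
        truth, loci = strong_signal_dataset
        # like-grouping quartet: single site, no homoplasy
        t = Tree.from_newick("((A1,A2),(C1,C2));")
        mat = {"A1": "A", "A2": "A", "C1": "C", "C2": "C"}
        assert consistency_index(mat, t) == 1.0

    def test_unlike_grouping_ci_half(self):
        t = Tree.from_newick("((A1,C1),(A2,C2));")
        assert consistency_index(
            {"A1": "A", "C1": "C", "A2": "A", "C2": "C"}, t
        ) == pytest.approx(0.5)

    def test_bounded_by_one_and_decreases_with_homoplasy(self, rng):
        t = simulate_tree(6, 0.1, 8)
        taxa = t.taxa()
        clean = {x: "ACGTAC" for x in taxa}
        assert consistency_index(clean, t) == 1.0
        noisy = random_alignment(rng, taxa, 40)
        ci = consistency_index(noisy, t)
        assert 0 < ci <= 1.0


# ---------------------------------------------------------------------
# search and bootstrap
# ---------------------------------------------------------------------

class TestSearchAndBootstrap:
    def test_hill_climb_keeps_true_tree(self, strong_signal_dataset):
        truth, loci = strong_signal_dataset
        model = SubstModel(alpha=1.0)
        mat = concatenate(loci, truth.tree.taxa()).matrix
        found, _ = nni_hill_climb(mat, model, truth.tree)
        assert robinson_foulds(found, truth.tree) == 0

    def test_hill_climb_recovers_from_one_nni_away(self, strong_signal_dataset):
        from radpartition.tree_ops import nni_neighbors

        truth, loci = strong_signal_dataset
        model = SubstModel(alpha=1.0)
        mat = concatenate(loci, truth.tree.taxa()).matrix
        start = nni_neighbors(truth.tree)[0]
        found, _ = nni_hill_climb(mat, model, start)
        assert robinson_foulds(found, truth.tree) == 0

    def test_nj_start_reasonable(self, strong_signal_dataset):
        truth, loci = strong_signal_dataset
        mat = concatenate(loci, truth.tree.taxa()).matrix
        nj = neighbor_joining_tree(mat)
        assert robinson_foulds(nj, truth.tree) <= 4

    def test_bootstrap_strong_signal_high_support(self):
        # balanced tree, every branch 0.1, 5,000 sites: every true clade
        # should be recovered by essentially all replicates
        balanced = Tree.from_newick(
            "(((t1:.1,t2:.1):.1,(t3:.1,t4:.1):.1):.1,((t5:.1,t6:.1):.1,(t7:.1,t8:.1):.1):.1);"
        )
        model = SubstModel(alpha=1.0)
        cfg = SimConfig(n_taxa=8, n_loci=1, locus_length=5000, tree_depth=0.3,
                        rng_seed=77, min_individuals=8, model=model)
        truth, loci = simulate_loci(balanced, cfg)
        mat = loci[0].rows
        res = bootstrap_support(mat, model, reps=10, rng_seed=1,
                                reference=balanced, search=False)
        assert res.mean >= 95.0

    def test_bootstrap_deterministic_given_seed(self, strong_signal_dataset):
        truth, loci = strong_signal_dataset
        model = SubstModel(alpha=1.0)
        mat = concatenate(loci[:10], truth.tree.taxa()).matrix
        r1 = bootstrap_support(mat, model, 5, 3, reference=truth.tree, search=False)
        r2 = bootstrap_support(mat, model, 5, 3, reference=truth.tree, search=False)
        assert r1.support == r2.support

    def test_bootstrap_degenerate_matrix_flagged(self, jc_model):
        t = simulate_tree(5, 0.1, 3)
        mat = {x: "ACGT" * 5 for x in t.taxa()}
        res = bootstrap_support(mat, jc_model, 5, 1, reference=t)
        assert res.degenerate
        assert all(v == 0.0 for v in res.support.values())

    def test_zero_reps_rejected(self, jc_model):
        t = simulate_tree(5, 0.1, 3)
        with pytest.raises(ValueError):
            bootstrap_support({x: "ACGT" for x in t.taxa()}, jc_model, 0, 1)
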