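"""Self-contained simulation experiments exercising the toolkit
end-to-end: the partitioned-RAD conflict-detection scenario, the
rate-contrast informativeness comparison, and the technical-replicate
attachment check.

Each experiment generates its own data with the synthetic generator,
runs the relevant pipeline and returns a small result object, so the
same code serves the test suite and ad-hoc exploration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from .est_informativeness import (
    EngineConfig,
    informativeness_stats,
    matched_subsample,
    resampling_pvalues,
    SubsampleConfig,
)
from .locus_matrix import Locus, concatenate
from .partitioned_rad import (
    PartitionConfig,
    compute_pool_lls,
    favor_disfavor,
    filter_partition_loci,
    locus_tree_table,
    support_regression,
)
from .phylo_engine import SubstModel, neighbor_joining_tree, nni_hill_climb
from .synth_rad import SimConfig, simulate_loci, simulate_tree
from .tree_ops import Tree, build_tree_pool


# ---------------------------------------------------------------------
# partitioned-RAD conflict detection
# ---------------------------------------------------------------------

@dataclass
class ConflictResult:
    alt_index: int
    alt_flagged: bool
    alt_z: float
    top_count_is_optimal: bool
    optimal_flagged: bool
    n_included: int


def _least_penalized_nni2(tree: Tree, pool, model: SubstModel, seed: int,
                          pilot_loci: int, locus_length: int) -> int:
    """Index of the 2-step pool tree with the smallest likelihood penalty
    on concordant pilot data: the 'masked' alternative a hybridization
    event between close relatives would produce."""
    cfg = SimConfig(
        n_taxa=tree.n_taxa(), n_loci=pilot_loci, locus_length=locus_length,
        rng_seed=seed + 7, min_individuals=tree.n_taxa(), model=model,
    )
    _, loci = simulate_loci(tree, cfg)
    mat = concatenate(loci, tree.taxa()).matrix
    lls = compute_pool_lls(mat, pool, model, optimize=False)
    nni2 = [i for i, o in enumerate(pool.origin) if o == "nni2"]
    return max(nni2, key=lambda i: lls[i])


def conflict_detection_experiment(
    seed: int,
    conflict_fraction: float = 0.30,
    n_taxa: int = 10,
    n_permuted: int = 30,
    n_loci: int = 200,
    locus_length: int = 50,
    tree_depth: float = 0.1,
    introgression_branch: float = 0.05,
    optimize_tables: bool = False,
    cfg: Optional[PartitionConfig] = None,
) -> ConflictResult:
    """One partitioned-RAD run on data with (or without) gene-tree
    conflict.

    A species tree is drawn, an NNI pool built, and a 'masked'
    alternative topology selected (the 2-step neighbor the concordant
    data penalize least).  ``conflict_fraction`` of the loci evolve on
    that alternative with its internal branches floored at
    ``introgression_branch`` substitutions/site - the footprint of
    introgressed loci tracing their own history.  The favor/disfavor
    table is regressed on the total-data likelihood and the alternative's
    outlier status recorded.
    """
    model = SubstModel(alpha=1.0)
    tree = simulate_tree(n_taxa, tree_depth, seed)
    pool = build_tree_pool(tree, n_permuted, seed + 1000)
    alt_idx = _least_penalized_nni2(tree, pool, model, seed,
                                    pilot_loci=40, locus_length=locus_length)
    alt = pool.trees[alt_idx].copy()
    for u, v, length in list(alt.internal_edges()):
        alt.set_length(u, v, max(length, introgression_branch))

    sim = SimConfig(
        n_taxa=n_taxa, n_loci=n_loci, locus_length=locus_length,
        tree_depth=tree_depth, rng_seed=seed, min_individuals=n_taxa,
        model=model,
    )
    use_alt = conflict_fraction > 0
    _, loci = simulate_loci(tree, sim, alt_tree=alt if use_alt else None,
                            alt_fraction=conflict_fraction if use_alt else 0.0)

    pcfg = cfg or PartitionConfig(min_trees=20, min_ll_range=4.0)
    kept, pruned, _ = filter_partition_loci(loci, pool, pcfg)
    tables = [
        locus_tree_table(l, p, model, min_ll_range=pcfg.min_ll_range,
                         optimize=optimize_tables, opt_rounds=2)
        for l, p in zip(kept, pruned)
    ]
    mat = concatenate(loci, tree.taxa()).matrix
    total_lls = compute_pool_lls(mat, pool, model, optimize=optimize_tables,
                                 opt_rounds=2)
    favor = favor_disfavor(tables, pool, pcfg, total_lls=total_lls)
    report = support_regression(favor, level=pcfg.pi_level)
    fr = report.frame
    sd = report.residual_sd if report.residual_sd > 0 else 1e-9
    z = float((fr.loc[alt_idx, "n_favoring"] - fr.loc[alt_idx, "predicted"]) / sd)
    return ConflictResult(
        alt_index=alt_idx,
        alt_flagged=bool(fr.loc[alt_idx, "outlier"]),
        alt_z=z,
        top_count_is_optimal=int(favor.frame["n_favoring"].idxmax()) == 0,
        optimal_flagged=bool(fr.loc[0, "outlier"]),
        n_included=favor.n_loci,
    )


# ---------------------------------------------------------------------
# rate-contrast informativeness comparison
# ---------------------------------------------------------------------

@dataclass
class RateContrastResult:
    p_n_pi: float
    p_tip_proportion: float
    observed_n_pi: float
    null_mean_n_pi: float


def rate_contrast_experiment(
    seed: int,
    n_taxa: int = 8,
    n_est: int = 30,
    n_pool: int = 120,
    n_replicates: int = 50,
    locus_length: int = 60,
    tree_depth: float = 0.1,
    rate_factor: float = 0.5,
) -> RateContrastResult:
    """Genic-vs-anonymous informativeness comparison on synthetic data.

    'EST-like' loci evolve at ``rate_factor`` times the rate of the
    anonymous pool (all branch lengths scaled); the resampling test then
    compares the EST set against length-matched subsamples of the pool.
    Reports the two-tailed p-values for the parsimony-informative count
    (expected small) and the tip-branch proportion (expected
    unremarkable: a uniform rate change leaves the tree shape alone).

    Dataset sizes default to 30 loci per compared set: with many fewer,
    the half-rate set's tree is estimated from so few substitutions that
    its branch-length noise exceeds the subsample-null spread, and the
    neutral tip-proportion statistic reads as spuriously extreme.
    """
    model = SubstModel(alpha=1.0)
    tree = simulate_tree(n_taxa, tree_depth, seed)
    slow = tree.copy()
    for u, v, length in list(slow.edges()):
        slow.set_length(u, v, length * rate_factor)

    est_cfg = SimConfig(n_taxa=n_taxa, n_loci=n_est, locus_length=locus_length,
                        rng_seed=seed * 3 + 1, min_individuals=n_taxa, model=model)
    _, est_loci = simulate_loci(slow, est_cfg)
    pool_cfg = SimConfig(n_taxa=n_taxa, n_loci=n_pool, locus_length=locus_length,
                         rng_seed=seed * 3 + 2, min_individuals=n_taxa, model=model)
    _, pool_loci = simulate_loci(tree, pool_cfg)

    engine = EngineConfig(model=model, search=False, bootstrap_reps=0,
                          rng_seed=seed, opt_rounds=3)
    taxa = tree.taxa()
    observed = informativeness_stats(est_loci, taxa, engine)
    sub_cfg = SubsampleConfig(n_replicates=n_replicates,
                              length_window=(locus_length, locus_length),
                              rng_seed=seed)
    nulls = [
        informativeness_stats(
            matched_subsample(pool_loci, n_est, sub_cfg, i), taxa, engine
        )
        for i in range(n_replicates)
    ]
    table = resampling_pvalues(observed, nulls)
    return RateContrastResult(
        p_n_pi=float(table.loc["n_pi", "p"]),
        p_tip_proportion=float(table.loc["tip_proportion", "p"]),
        observed_n_pi=float(table.loc["n_pi", "observed"]),
        null_mean_n_pi=float(table.loc["n_pi", "null_mean"]),
    )


# ---------------------------------------------------------------------
# technical-replicate attachment
# ---------------------------------------------------------------------

@dataclass
class ReplicateResult:
    sister: bool
    replicate_terminal_length: float
    source_terminal_length: float


def replicate_attachment_experiment(
    seed: int,
    n_taxa: int = 8,
    n_loci: int = 40,
    locus_length: int = 60,
    tree_depth: float = 0.2,
    replicate_retention: float = 0.7,
    source_taxon: Optional[str] = None,
) -> ReplicateResult:
    """Add a thinned technical replicate of one individual and re-infer
    the tree.

    The replicate carries the *same* consensus sequences for a random
    subset of the source's loci (independent thinning of both copies,
    as separate sequencing runs would give).  With error-free consensus
    data the replicate should attach sister to its source with a
    negligible terminal branch.
    """
    model = SubstModel(alpha=1.0)
    tree = simulate_tree(n_taxa, tree_depth, seed)
    cfg = SimConfig(n_taxa=n_taxa, n_loci=n_loci, locus_length=locus_length,
                    tree_depth=tree_depth, rng_seed=seed, min_individuals=n_taxa,
                    model=model)
    _, loci = simulate_loci(tree, cfg)
    src = source_taxon or tree.taxa()[0]
    rep = f"{src}_rep"
    rng = np.random.default_rng(seed + 99)
    new_loci: List[Locus] = []
    for locus in loci:
        rows = dict(locus.rows)
        keep_src = rng.random() < replicate_retention
        keep_rep = rng.random() < replicate_retention
        if keep_rep and src in rows:
            rows[rep] = rows[src]
        if not keep_src:
            rows.pop(src, None)
        new_loci.append(Locus(locus.locus_id, rows))
    taxa = sorted(set(tree.taxa()) | {rep})
    mat = concatenate(new_loci, taxa).matrix
    start = neighbor_joining_tree(mat)
    found, _ = nni_hill_climb(mat, model, start, opt_rounds=3)
    a, b = found.leaf_by_label(src), found.leaf_by_label(rep)
    pa, pb = next(iter(found.adj[a])), next(iter(found.adj[b]))
    return ReplicateResult(
        sister=(pa == pb),
        replicate_terminal_length=found.adj[b][pb],
        source_terminal_length=found.adj[a][pa],
    )
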