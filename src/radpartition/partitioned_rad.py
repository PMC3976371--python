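"""Partitioned RAD analysis: map per-locus likelihood support onto a
pool of NNI-permuted candidate trees to expose hidden, strongly
supported alternative topologies.

For every locus that passes the inclusion filters, each unique pruned
candidate tree is scored by its (re-optimized) log-likelihood on that
locus alone.  A locus *favors* the trees within a fixed log-likelihood
window of its best tree and *disfavors* those within the same window of
its worst.  Favoring counts are then regressed on each tree's total-data
log-likelihood: under a single underlying topology signal the relation
is linear, and trees above the upper 95% prediction bound carry more
locus support than their likelihood predicts - candidate footprints of
hybridization or deep coalescence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .locus_matrix import Locus
from .phylo_engine import SubstModel, optimize_branch_lengths, total_log_likelihood
from .tree_ops import PrunedTreeSet, TreePool, prune_and_dedup

__all__ = [
    "PartitionConfig",
    "LocusTreeTable",
    "FavorTable",
    "RegressionReport",
    "filter_partition_loci",
    "locus_tree_table",
    "compute_pool_lls",
    "favor_disfavor",
    "support_regression",
    "trim_likelihood_islands",
    "plot_partitioned_rad",
]


@dataclass
class PartitionConfig:
    """Filters and window for the partitioned analysis: loci must span at
    least ``min_ll_range`` log-likelihood units over at least
    ``min_trees`` unique pruned trees; favoring/disfavoring uses a
    ``ll_window`` band; outliers are judged against a ``pi_level``
    prediction interval."""

    ll_window: float = 2.0
    min_trees: int = 20
    min_ll_range: float = 4.0
    min_individuals: int = 4
    require_pi: bool = True
    pi_level: float = 0.95

    def __post_init__(self) -> None:
        if self.ll_window <= 0:
            raise ValueError("ll_window must be positive")
        if self.min_ll_range < 0:
            raise ValueError("min_ll_range must be >= 0")
        if not (0 < self.pi_level < 1):
            raise ValueError("pi_level must be in (0, 1)")


def filter_partition_loci(
    loci: Sequence[Locus], pool: TreePool, cfg: PartitionConfig
) -> Tuple[List[Locus], List[PrunedTreeSet], List[Tuple[str, str]]]:
    """Inclusion filters before any likelihood work: drop loci with too
    few individuals, without parsimony-informative characters, or whose
    pruned candidate pool retains fewer than ``cfg.min_trees`` unique
    topologies.  Returns (kept loci, their pruned tree sets, dropped
    (locus_id, reason) pairs)."""
    kept: List[Locus] = []
    pruned_sets: List[PrunedTreeSet] = []
    dropped: List[Tuple[str, str]] = []
    cache: Dict[frozenset, PrunedTreeSet] = {}  # loci often share taxon subsets
    for locus in loci:
        if locus.n_individuals < cfg.min_individuals:
            dropped.append((locus.locus_id, "min_individuals"))
            continue
        if cfg.require_pi and locus.n_pi_sites() == 0:
            dropped.append((locus.locus_id, "no_PI"))
            continue
        key = frozenset(locus.individuals)
        if key not in cache:
            cache[key] = prune_and_dedup(pool, locus.individuals)
        pruned = cache[key]
        if len(pruned) < cfg.min_trees:
            dropped.append((locus.locus_id, "min_trees"))
            continue
        kept.append(locus)
        pruned_sets.append(pruned)
    return kept, pruned_sets, dropped


@dataclass
class LocusTreeTable:
    """Per-locus optimized log-likelihoods over the unique pruned trees,
    with the index map back to the global pool."""

    locus_id: str
    lls: np.ndarray
    index_map: List[int]
    ll_range: float
    excluded: bool
    failed: List[int] = field(default_factory=list)


def locus_tree_table(
    locus: Locus,
    pruned: PrunedTreeSet,
    model: SubstModel,
    min_ll_range: float = 4.0,
    optimize: bool = True,
    opt_rounds: int = 6,
) -> LocusTreeTable:
    """Score every unique pruned tree on one locus alignment.

    Branch lengths are re-optimized per tree by default (``optimize=False``
    evaluates at inherited lengths).  A tree whose optimization fails is
    recorded at -inf and excluded from that locus's window logic.  Loci
    whose likelihood range falls below ``min_ll_range`` are flagged
    excluded.
    """
    if len(pruned) < 2:
        raise ValueError("need at least 2 unique pruned trees")
    lls = np.empty(len(pruned))
    failed: List[int] = []
    for i, tree in enumerate(pruned.trees):
        try:
            if optimize:
                _, ll = optimize_branch_lengths(
                    locus.rows, tree, model, tol=1e-2, max_rounds=opt_rounds
                )
            else:
                ll = total_log_likelihood(locus.rows, tree, model)
            lls[i] = ll
        except Exception:
            lls[i] = -np.inf
            failed.append(i)
    finite = lls[np.isfinite(lls)]
    ll_range = float(finite.max() - finite.min()) if finite.size else 0.0
    return LocusTreeTable(
        locus_id=locus.locus_id,
        lls=lls,
        index_map=list(pruned.index_map),
        ll_range=ll_range,
        excluded=ll_range < min_ll_range,
        failed=failed,
    )


@dataclass
class FavorTable:
    """Per pool tree: origin tag, total-data log-likelihood and the
    number of loci favoring/disfavoring it."""

    frame: pd.DataFrame  # index: pool tree index; columns: origin, total_ll, n_favoring, n_disfavoring
    n_loci: int

    def __len__(self) -> int:
        return len(self.frame)


def compute_pool_lls(
    matrix: Mapping[str, str],
    pool: TreePool,
    model: SubstModel,
    optimize: bool = True,
    opt_rounds: int = 6,
) -> np.ndarray:
    """Total-data log-likelihood of every pool tree on the concatenated
    supermatrix (branch lengths re-optimized per tree)."""
    out = np.empty(len(pool))
    for i, tree in enumerate(pool.trees):
        if optimize:
            _, out[i] = optimize_branch_lengths(
                matrix, tree, model, tol=1e-2, max_rounds=opt_rounds
            )
        else:
            out[i] = total_log_likelihood(matrix, tree, model)
    return out


def favor_disfavor(
    tables: Sequence[LocusTreeTable],
    pool: TreePool,
    cfg: PartitionConfig,
    total_lls: Optional[np.ndarray] = None,
) -> FavorTable:
    """Accumulate favoring/disfavoring counts over pool trees.

    Per locus, trees within ``cfg.ll_window`` log-likelihood of the
    locus's best tree are favored and those within the window of its
    worst are disfavored (ties at the window edge included); every pool
    tree inherits the status of its pruned representative.  Tables
    flagged excluded contribute nothing.
    """
    n = len(pool)
    fav = np.zeros(n, dtype=int)
    dis = np.zeros(n, dtype=int)
    n_used = 0
    for tab in tables:
        if tab.excluded:
            continue
        ok = np.isfinite(tab.lls)
        if not ok.any():
            continue
        n_used += 1
        hi = tab.lls[ok].max()
        lo = tab.lls[ok].min()
        favored = ok & (tab.lls >= hi - cfg.ll_window)
        disfavored = ok & (tab.lls <= lo + cfg.ll_window)
        for pool_idx, rep_idx in enumerate(tab.index_map):
            if favored[rep_idx]:
                fav[pool_idx] += 1
            if disfavored[rep_idx]:
                dis[pool_idx] += 1
    frame = pd.DataFrame({
        "origin": pool.origin,
        "total_ll": total_lls if total_lls is not None else np.full(n, np.nan),
        "n_favoring": fav,
        "n_disfavoring": dis,
    })
    return FavorTable(frame=frame, n_loci=n_used)


@dataclass
class RegressionReport:
    """OLS fit of favoring count on total-data log-likelihood, with
    per-tree prediction intervals and outlier flags (above the upper
    bound only)."""

    slope: float
    intercept: float
    residual_sd: float
    level: float
    frame: pd.DataFrame  # predicted, pi_lower, pi_upper, outlier

    @property
    def outliers(self) -> pd.DataFrame:
        return self.frame[self.frame["outlier"]]


def support_regression(favor: FavorTable, level: float = 0.95) -> RegressionReport:
    """Regress favoring counts on total-data log-likelihood, treating
    each tree as an independent point, and flag trees whose count
    exceeds the upper prediction bound at ``level``."""
    import statsmodels.api as sm

    df = favor.frame.dropna(subset=["total_ll"])
    if len(df) < 3:
        raise ValueError("need at least 3 trees for the regression")
    x = df["total_ll"].values
    if np.ptp(x) == 0:
        raise ValueError("degenerate regressor: all total log-likelihoods equal")
    y = df["n_favoring"].values.astype(float)
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    pred = fit.get_prediction(X).summary_frame(alpha=1.0 - level)
    frame = pd.DataFrame(
        {
            "origin": df["origin"].values,
            "total_ll": x,
            "n_favoring": y,
            "predicted": pred["mean"].values,
            "pi_lower": pred["obs_ci_lower"].values,
            "pi_upper": pred["obs_ci_upper"].values,
        },
        index=df.index,
    )
    frame["outlier"] = frame["n_favoring"] > frame["pi_upper"]
    return RegressionReport(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        residual_sd=float(np.sqrt(fit.mse_resid)),
        level=level,
        frame=frame,
    )


def trim_likelihood_islands(favor: FavorTable, ll_cut: float) -> FavorTable:
    """Drop pool trees whose total-data log-likelihood falls below
    ``ll_cut`` (poorly supported likelihood islands) before regression."""
    keep = favor.frame["total_ll"] >= ll_cut
    if not keep.any():
        raise ValueError("ll_cut removes every tree")
    return FavorTable(frame=favor.frame[keep].copy(), n_loci=favor.n_loci)


def plot_partitioned_rad(favor: FavorTable, report: Optional[RegressionReport], path) -> None:
    """Scatter of favoring and disfavoring counts against total-data
    log-likelihood, with the regression line and prediction interval."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(10, 4))
    df = favor.frame
    for ax, col in zip(axes, ("n_favoring", "n_disfavoring")):
        opt = df["origin"] == "optimal"
        ax.plot(df.loc[~opt, "total_ll"], df.loc[~opt, col], "+", color="gray")
        ax.plot(df.loc[opt, "total_ll"], df.loc[opt, col], "o", color="red")
        ax.set_xlabel("total-data log-likelihood")
        ax.set_ylabel(col.replace("_", " "))
    if report is not None:
        order = np.argsort(report.frame["total_ll"].values)
        xs = report.frame["total_ll"].values[order]
        axes[0].plot(xs, report.frame["predicted"].values[order], "-", color="black")
        axes[0].plot(xs, report.frame["pi_lower"].values[order], "--", color="black")
        axes[0].plot(xs, report.frame["pi_upper"].values[order], "--", color="black")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
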