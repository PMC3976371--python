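"""Expressed-sequence (EST) informativeness comparison: split loci by
homology to expressed-sequence targets, draw length-matched random
subsamples of the non-genic loci, compute a bundle of phylogenetic
informativeness statistics per dataset, and derive two-tailed resampling
p-values for the genic set against the subsample null.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io_formats import HitTable
from .locus_matrix import Locus, concatenate
from .phylo_engine import (
    SubstModel,
    bootstrap_support,
    classify_characters,
    consistency_index,
    estimate_model,
    fitch_steps,
    neighbor_joining_tree,
    nni_hill_climb,
    optimize_branch_lengths,
)
from .tree_ops import tip_branch_proportion

__all__ = [
    "SubsampleConfig",
    "EngineConfig",
    "StatBlock",
    "partition_by_est",
    "matched_subsample",
    "informativeness_stats",
    "resampling_pvalues",
]


@dataclass
class SubsampleConfig:
    """Matched-subsampling settings: number of null replicates, the
    inclusive aligned-length window loci are drawn from, the homology
    E-value cutoff, and the base RNG seed."""

    n_replicates: int = 100
    length_window: Tuple[int, int] = (50, 55)
    evalue_cutoff: float = 1e-15
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.length_window[0] > self.length_window[1]:
            raise ValueError("length window inverted")


def partition_by_est(
    loci: Sequence[Locus], hits: HitTable, cutoff: float
) -> Tuple[List[Locus], List[Locus], List[Locus]]:
    """Split loci by expressed-sequence homology.

    Returns (est, non_est, ambiguous): *est* loci have at least one hit
    with E-value strictly below ``cutoff``; *non_est* loci have no hit at
    any E-value; loci whose hits all sit at or above the cutoff belong to
    neither set and are returned separately.  Hits naming unknown loci
    are ignored with a warning.
    """
    known = {l.locus_id for l in loci}
    unknown = hits.loci_with_hits() - known
    if unknown:
        warnings.warn(f"{len(unknown)} hit(s) reference unknown loci; ignored")
    best: Dict[str, float] = {}
    for _, row in hits.rows.iterrows():
        lid = row["locus_id"]
        if lid in known:
            best[lid] = min(best.get(lid, math.inf), float(row["evalue"]))
    est, non_est, ambiguous = [], [], []
    for locus in loci:
        if locus.locus_id not in best:
            non_est.append(locus)
        elif best[locus.locus_id] < cutoff:
            est.append(locus)
        else:
            ambiguous.append(locus)
    return est, non_est, ambiguous


def matched_subsample(
    non_est: Sequence[Locus], n: int, cfg: SubsampleConfig, replicate_index: int
) -> List[Locus]:
    """Uniform sample without replacement of exactly ``n`` loci whose
    aligned length lies within ``cfg.length_window``; deterministic for a
    given (seed, replicate index)."""
    lo, hi = cfg.length_window
    eligible = [l for l in non_est if lo <= l.length <= hi]
    if len(eligible) < n:
        raise ValueError(
            f"need {n} eligible loci, only {len(eligible)} in the {lo}-{hi} bp window"
        )
    rng = np.random.default_rng((cfg.rng_seed, replicate_index))
    idx = rng.choice(len(eligible), size=n, replace=False)
    return [eligible[i] for i in sorted(idx)]


@dataclass
class EngineConfig:
    """How dataset statistics are computed: a fixed substitution model
    (None re-estimates it per dataset), whether an NNI topology search is
    run (otherwise the NJ tree is only branch-length optimized), and the
    number of bootstrap replicates (0 skips the bootstrap and reports
    NaN mean support)."""

    model: Optional[SubstModel] = None
    search: bool = True
    bootstrap_reps: int = 20
    rng_seed: int = 0
    opt_rounds: int = 8


@dataclass
class StatBlock:
    """The informativeness statistic bundle for one dataset, computed on
    the dataset's own ML tree."""

    steps: int
    n_variable: int
    n_pi: int
    ci: float
    aligned_length: int
    missing_proportion: float
    tip_proportion: float
    mean_bootstrap: float

    _FIELDS = (
        "steps", "n_variable", "n_pi", "ci", "aligned_length",
        "missing_proportion", "tip_proportion", "mean_bootstrap",
    )

    def as_dict(self) -> Dict[str, float]:
        return {f: getattr(self, f) for f in self._FIELDS}


def informativeness_stats(
    loci: Sequence[Locus], taxa: Sequence[str], engine: EngineConfig
) -> StatBlock:
    """Concatenate the loci, infer that dataset's ML tree, and compute
    the statistic bundle: parsimony steps, variable and
    parsimony-informative site counts, consistency index, aligned
    length, missing proportion (N or -), proportion of branch length in
    the tips, and mean bootstrap support."""
    if not loci:
        raise ValueError("no loci")
    bundle = concatenate(loci, taxa)
    matrix = bundle.matrix
    census = classify_characters(matrix)

    start = neighbor_joining_tree(matrix)
    if engine.model is None:
        model, tree, _ = estimate_model(matrix, start)
        if engine.search:
            tree, _ = nni_hill_climb(matrix, model, tree, opt_rounds=4)
    else:
        model = engine.model
        if engine.search:
            tree, _ = nni_hill_climb(matrix, model, start, opt_rounds=4)
        else:
            tree, _ = optimize_branch_lengths(
                matrix, start, model, max_rounds=engine.opt_rounds
            )

    if engine.bootstrap_reps > 0:
        boot = bootstrap_support(
            matrix, model, engine.bootstrap_reps, engine.rng_seed,
            reference=tree, search=engine.search,
        )
        mean_boot = boot.mean
    else:
        mean_boot = float("nan")

    return StatBlock(
        steps=fitch_steps(matrix, tree),
        n_variable=census.n_variable,
        n_pi=census.n_parsimony_informative,
        ci=consistency_index(matrix, tree),
        aligned_length=bundle.n_sites,
        missing_proportion=census.missing_proportion,
        tip_proportion=tip_branch_proportion(tree),
        mean_bootstrap=mean_boot,
    )


def resampling_pvalues(
    observed: StatBlock, null_blocks: Sequence[StatBlock]
) -> pd.DataFrame:
    """Two-tailed resampling p-values per statistic.

    ``k`` counts null values strictly more extreme than the observed
    value in the direction away from the null mean; p = min(1, 2k/R).
    When k = 0 the p-value is a bound at the test's resolution and the
    label reads '< 2/R'.  Null mean and SD are reported alongside.
    """
    if len(null_blocks) < 2:
        raise ValueError("need at least 2 null blocks")
    R = len(null_blocks)
    rows = []
    for stat in StatBlock._FIELDS:
        obs = float(getattr(observed, stat))
        null = np.array([float(getattr(b, stat)) for b in null_blocks], dtype=float)
        if np.isnan(obs) or np.isnan(null).any():
            finite = null[~np.isnan(null)]
            nm = float(finite.mean()) if finite.size else float("nan")
            ns = float(finite.std(ddof=1)) if finite.size > 1 else float("nan")
            rows.append((stat, obs, nm, ns, float("nan"), "n/a"))
            continue
        mean, sd = null.mean(), null.std(ddof=1)
        if sd == 0 and obs == mean:
            rows.append((stat, obs, mean, sd, 1.0, "1"))
            continue
        if obs >= mean:
            k = int((null > obs).sum())
        else:
            k = int((null < obs).sum())
        if k == 0:
            p = 2.0 / R
            label = f"< {2.0 / R:g}"
        else:
            p = min(1.0, 2.0 * k / R)
            label = f"{p:g}"
        rows.append((stat, obs, mean, sd, p, label))
    return pd.DataFrame(
        rows, columns=["statistic", "observed", "null_mean", "null_sd", "p", "p_label"]
    ).set_index("statistic")
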