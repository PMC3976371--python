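"""Synthetic RAD-seq data with known truth: a species tree, short loci
evolved under GTR+GAMMA, phylogenetically structured restriction-site
dropout plus random coverage dropout, diploid read stacks with
sequencing error, and technical-replicate locus thinning.

Every other module of the toolkit is testable against these fixtures
without any external download.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io_formats import ReadSet
from .locus_matrix import Locus
from .phylo_engine import SubstModel, _Eigen
from .tree_ops import Tree

__all__ = [
    "SimConfig",
    "SimTruth",
    "expected_cut_sites",
    "simulate_tree",
    "simulate_loci",
    "simulate_replicate_pair",
    "simulate_reads",
]

_BASES = "ACGT"


def expected_cut_sites(genome_length: float, gc_content: float, motif: str) -> float:
    """Expected number of restriction-recognition sites in a genome of
    independent bases: genome length times the motif probability, with
    piC = piG = gc/2 and piA = piT = (1-gc)/2."""
    if not (0 < gc_content < 1):
        raise ValueError("gc_content must be in (0, 1)")
    p = {"A": (1 - gc_content) / 2, "T": (1 - gc_content) / 2,
         "C": gc_content / 2, "G": gc_content / 2}
    prob = 1.0
    for ch in motif.upper():
        if ch not in p:
            raise ValueError(f"ambiguous or invalid motif base {ch!r}")
        prob *= p[ch]
    return genome_length * prob


def simulate_tree(n_taxa: int, tree_depth: float, rng_seed: int) -> Tree:
    """Random unrooted binary tree: topology uniform over labeled
    topologies by sequential addition at a uniformly chosen edge, branch
    lengths iid exponential rescaled so the mean root-to-tip path equals
    ``tree_depth`` substitutions/site."""
    if n_taxa < 4:
        raise ValueError("need at least 4 taxa")
    rng = np.random.default_rng(rng_seed)
    labels = [f"t{i + 1:02d}" for i in range(n_taxa)]
    t = Tree()
    center = t.new_node()
    for lab in labels[:3]:
        leaf = t.new_node(lab)
        t.add_edge(center, leaf, 1.0)
    for lab in labels[3:]:
        edges = list(t.edges())
        u, v, _ = edges[rng.integers(len(edges))]
        t.attach_leaf(u, v, lab, leaf_length=1.0)
    for u, v, _ in list(t.edges()):
        t.set_length(u, v, float(rng.exponential(1.0)))
    root = t.default_root()
    dist = t.path_lengths_from(root)
    mean_tip = float(np.mean([dist[l] for l in t.leaves()]))
    scale = tree_depth / mean_tip if mean_tip > 0 else 1.0
    for u, v, length in list(t.edges()):
        t.set_length(u, v, max(length * scale, 1e-8))
    return t


@dataclass
class SimConfig:
    """Generator settings.

    Defaults emulate a 20-individual short-read RAD study: 50-bp loci, a
    moderate tree depth, dropout from restriction-site mutation
    (probability growing with root-to-tip path length) plus independent
    coverage thinning, ~20x stacks, 0.1% sequencing error and low
    heterozygosity.
    """

    n_taxa: int = 20
    n_loci: int = 100
    locus_length: int = 50
    model: SubstModel = field(default_factory=SubstModel)
    tree_depth: float = 0.05
    site_dropout_rate: float = 0.0
    coverage_retain_prob: float = 1.0
    read_depth_mean: float = 20.0
    epsilon: float = 0.001
    het: float = 0.002
    min_individuals: int = 4
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise ValueError("n_loci must be >= 1")
        if not (0 <= self.coverage_retain_prob <= 1):
            raise ValueError("coverage_retain_prob must be in [0, 1]")


@dataclass
class SimTruth:
    """Ground truth of one simulation: the generating tree, per-locus
    full alignments, the presence matrix actually emitted, which loci
    came from the alternative topology, and the config."""

    tree: Tree
    alignments: Dict[str, Dict[str, str]]
    presence: pd.DataFrame
    alt_loci: List[str]
    config: SimConfig


def _evolve_along(tree: Tree, eig: _Eigen, rates: np.ndarray, rng: np.random.Generator) -> Dict[str, str]:
    """One locus: site-wise GTR evolution with per-site rates along the tree."""
    L = len(rates)
    root = tree.default_root()
    order = tree.postorder(root)
    states: Dict[int, np.ndarray] = {}
    pi = eig.pi
    states[root] = rng.choice(4, size=L, p=pi)
    for node, parent, length in reversed(order):  # preorder
        if parent is None:
            continue
        E = np.exp(np.outer(length * rates, eig.lam))          # (L, 4)
        P = (eig.A[None, :, :] * E[:, None, :]) @ eig.B        # (L, 4, 4)
        np.clip(P, 0.0, None, out=P)
        probs = P[np.arange(L), states[parent]]
        probs /= probs.sum(axis=1, keepdims=True)
        u = rng.random(L)
        states[node] = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    out = {}
    for leaf in tree.leaves():
        out[tree.label[leaf]] = "".join(_BASES[s] for s in states[leaf])
    return out


def simulate_loci(
    tree: Tree,
    cfg: SimConfig,
    alt_tree: Optional[Tree] = None,
    alt_fraction: float = 0.0,
) -> Tuple[SimTruth, List[Locus]]:
    """Simulate ``cfg.n_loci`` loci on ``tree`` (optionally a fraction on
    ``alt_tree``, mimicking gene-tree conflict), then apply dropout.

    Restriction-site loss is phylogenetically structured: a taxon keeps a
    locus with probability exp(-site_dropout_rate * root-to-tip path
    length), independently per locus, then independent coverage thinning
    at ``coverage_retain_prob``.  Loci with fewer than
    ``cfg.min_individuals`` survivors are not emitted.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    eig = _Eigen(cfg.model)
    alt_eig = _Eigen(cfg.model) if alt_tree is not None else None
    taxa = tree.taxa()
    root = tree.default_root()
    dist = tree.path_lengths_from(root)
    tip_dist = {tree.label[l]: dist[l] for l in tree.leaves()}
    keep_site_prob = {
        t: float(np.exp(-cfg.site_dropout_rate * d)) for t, d in tip_dist.items()
    }

    n_alt = int(round(alt_fraction * cfg.n_loci)) if alt_tree is not None else 0
    alt_idx = set(rng.choice(cfg.n_loci, size=n_alt, replace=False)) if n_alt else set()

    alignments: Dict[str, Dict[str, str]] = {}
    presence = pd.DataFrame(
        np.zeros((len(taxa), cfg.n_loci), dtype=int),
        index=taxa,
        columns=[f"locus_{i + 1:06d}" for i in range(cfg.n_loci)],
    )
    loci: List[Locus] = []
    alt_ids: List[str] = []
    alpha = cfg.model.alpha
    for i in range(cfg.n_loci):
        locus_id = f"locus_{i + 1:06d}"
        rates = rng.gamma(alpha, 1.0 / alpha, size=cfg.locus_length)
        if i in alt_idx:
            aln = _evolve_along(alt_tree, alt_eig, rates, rng)
            alt_ids.append(locus_id)
        else:
            aln = _evolve_along(tree, eig, rates, rng)
        alignments[locus_id] = aln
        rows = {}
        for t in taxa:
            keep = (rng.random() < keep_site_prob[t]) and (
                rng.random() < cfg.coverage_retain_prob
            )
            if keep:
                rows[t] = aln[t]
        if len(rows) >= cfg.min_individuals:
            for t in rows:
                presence.loc[t, locus_id] = 1
            loci.append(Locus(locus_id=locus_id, rows=rows))
    truth = SimTruth(
        tree=tree, alignments=alignments, presence=presence,
        alt_loci=alt_ids, config=cfg,
    )
    return truth, loci


def expected_replicate_overlap(retain_a: float, retain_b: float) -> float:
    """Closed-form expected |A & B| / |A | B| when two replicates are
    independent thinnings of one locus set."""
    ab = retain_a * retain_b
    return ab / (retain_a + retain_b - ab)


def simulate_replicate_pair(
    locus_presence_row: np.ndarray,
    retain_a: float,
    retain_b: float,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, np.ndarray]:
    """Two technical replicates: independent Bernoulli thinnings of the
    same underlying presence row."""
    if not (0 < retain_a <= 1 and 0 < retain_b <= 1):
        raise ValueError("retention probabilities must be in (0, 1]")
    base = np.asarray(locus_presence_row).astype(bool)
    a = base & (rng.random(base.size) < retain_a)
    b = base & (rng.random(base.size) < retain_b)
    return a.astype(int), b.astype(int)


def simulate_reads(
    truth_sequence: str,
    depth_mean: float,
    epsilon: float,
    het: float,
    rng: np.random.Generator,
    individual_id: str = "sim",
) -> ReadSet:
    """Read stack for one locus of one diploid individual: heterozygous
    sites arise at rate ``het`` (second allele a uniform other base),
    Poisson(depth_mean) reads each drawn from either allele with
    probability 1/2, and each base flipped to a uniform other base with
    probability ``epsilon``."""
    if not (0 <= epsilon < 0.5):
        raise ValueError("epsilon must be in [0, 0.5)")
    L = len(truth_sequence)
    allele1 = np.array([_BASES.index(c) for c in truth_sequence])
    allele2 = allele1.copy()
    het_sites = rng.random(L) < het
    shift = rng.integers(1, 4, size=L)
    allele2[het_sites] = (allele1[het_sites] + shift[het_sites]) % 4
    n_reads = int(rng.poisson(depth_mean))
    reads = []
    for _ in range(n_reads):
        src = allele1 if rng.random() < 0.5 else allele2
        read = src.copy()
        errs = rng.random(L) < epsilon
        eshift = rng.integers(1, 4, size=L)
        read[errs] = (read[errs] + eshift[errs]) % 4
        reads.append("".join(_BASES[b] for b in read))
    quals = [[40] * L for _ in reads]
    return ReadSet(individual_id=individual_id, reads=reads, qualities=quals)
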