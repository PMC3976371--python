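"""Likelihood and parsimony machinery: GTR+GAMMA site likelihoods by the
pruning algorithm, branch-length optimization, substitution-model
estimation, Fitch parsimony, character census, consistency index, an NNI
hill-climbing ML search and nonparametric bootstrap.

Alignments are plain ``Mapping[str, str]`` (taxon -> sequence).  Columns
are compressed to unique site patterns before any likelihood work, and
ambiguity codes contribute as partial states (the conditional vector is 1
on every compatible base).  'N', '-' and '?' are fully missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammainc
from scipy.stats import gamma as _gamma_dist

from .tree_ops import Tree, TreeError, _split_masks

__all__ = [
    "SubstModel",
    "CharacterCensus",
    "BootstrapResult",
    "site_log_likelihoods",
    "total_log_likelihood",
    "optimize_branch_lengths",
    "estimate_model",
    "fitch_steps",
    "classify_characters",
    "consistency_index",
    "nni_hill_climb",
    "neighbor_joining_tree",
    "bootstrap_support",
    "discrete_gamma_rates",
]

BRLEN_MIN = 1e-8
BRLEN_MAX = 10.0

# IUPAC nucleotide codes as bitmasks over (A, C, G, T)
_CODE = {
    "A": 0b0001, "C": 0b0010, "G": 0b0100, "T": 0b1000,
    "R": 0b0101, "Y": 0b1010, "S": 0b0110, "W": 0b1001,
    "K": 0b1100, "M": 0b0011, "B": 0b1110, "D": 0b1101,
    "H": 0b1011, "V": 0b0111, "N": 0b1111, "-": 0b1111, "?": 0b1111,
}
_MISSING = 0b1111
_MASK_TO_PARTIAL = np.zeros((16, 4))
for _m in range(1, 16):
    for _b in range(4):
        if _m >> _b & 1:
            _MASK_TO_PARTIAL[_m, _b] = 1.0


@dataclass(frozen=True)
class SubstModel:
    """GTR+GAMMA: equilibrium base frequencies (A, C, G, T), the six
    exchangeabilities in order AC, AG, AT, CG, CT, GT (GT conventionally
    1), and a discrete-gamma shape ``alpha`` with ``n_categories``
    equal-weight rate categories."""

    base_freqs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    exchangeabilities: Tuple[float, float, float, float, float, float] = (1.0,) * 6
    alpha: float = 1.0
    n_categories: int = 4

    def __post_init__(self) -> None:
        f = np.asarray(self.base_freqs, float)
        if not (np.all(f > 0) and abs(f.sum() - 1.0) < 1e-6):
            raise ValueError("base frequencies must be positive and sum to 1")
        if not all(r > 0 for r in self.exchangeabilities):
            raise ValueError("exchangeabilities must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")


def jc69(n_categories: int = 1, alpha: float = 1.0) -> SubstModel:
    """Jukes-Cantor special case of the GTR model."""
    return SubstModel(alpha=alpha, n_categories=n_categories)


def discrete_gamma_rates(alpha: float, k: int) -> np.ndarray:
    """Mean-one discrete-gamma category rates, mean-of-quantile method:
    the rate of category i is the conditional mean of a Gamma(alpha,
    1/alpha) variate within the i-th probability-1/k slice."""
    if k == 1:
        return np.ones(1)
    cut = _gamma_dist.ppf(np.arange(1, k) / k, a=alpha, scale=1.0 / alpha)
    upper = np.concatenate([gammainc(alpha + 1.0, cut * alpha), [1.0]])
    lower = np.concatenate([[0.0], upper[:-1]])
    return (upper - lower) * k


class _Eigen:
    """Eigendecomposition of the (reversibility-symmetrized) GTR rate
    matrix, scaled to one expected substitution per unit branch length."""

    def __init__(self, model: SubstModel) -> None:
        pi = np.asarray(model.base_freqs, float)
        ac, ag, at, cg, ct, gt = model.exchangeabilities
        R = np.array([
            [0.0, ac, ag, at],
            [ac, 0.0, cg, ct],
            [ag, cg, 0.0, gt],
            [at, ct, gt, 0.0],
        ])
        Q = R * pi[None, :]
        np.fill_diagonal(Q, -Q.sum(axis=1))
        mu = -(pi * np.diag(Q)).sum()
        Q /= mu
        sq = np.sqrt(pi)
        S = (Q * sq[:, None]) / sq[None, :]
        lam, V = np.linalg.eigh((S + S.T) / 2.0)
        self.lam = lam
        self.A = V / sq[:, None]          # D^{-1/2} V
        self.B = V.T * sq[None, :]        # V^T D^{1/2}
        self.pi = pi

    def pmats(self, t: float, rates: np.ndarray) -> np.ndarray:
        """Transition matrices P(t * r) for each category rate r -> (k, 4, 4)."""
        e = np.exp(np.outer(rates, self.lam) * t)       # (k, 4)
        P = (self.A[None, :, :] * e[:, None, :]) @ self.B
        np.clip(P, 0.0, None, out=P)
        return P


def _encode(matrix: Mapping[str, str], taxa: Sequence[str]) -> np.ndarray:
    rows = []
    for name in taxa:
        seq = matrix[name].upper()
        try:
            rows.append([_CODE[c] for c in seq])
        except KeyError as exc:
            raise ValueError(f"unknown character {exc} in sequence for {name}") from exc
    arr = np.asarray(rows, dtype=np.uint8)
    if arr.ndim != 2 or (arr.size and len({len(matrix[n]) for n in taxa}) != 1):
        raise ValueError("sequences have unequal lengths")
    return arr


def _compress(codes: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unique site patterns, their weights, and the site -> pattern index."""
    if codes.shape[1] == 0:
        return codes, np.zeros(0), np.zeros(0, dtype=int)
    patterns, index, counts = np.unique(
        codes, axis=1, return_inverse=True, return_counts=True
    )
    return patterns, counts.astype(float), index.ravel()


class LikelihoodEngine:
    """Pruning-algorithm workspace bound to one alignment, tree and model.

    The tree is referenced, not copied: branch-length setters mutate it.
    Per-pattern scaling keeps partials in range on deep trees.
    """

    def __init__(self, matrix: Mapping[str, str], tree: Tree, model: SubstModel) -> None:
        taxa = tree.taxa()
        if set(taxa) != set(matrix):
            raise TreeError("alignment taxa and tree taxa differ")
        self.tree = tree
        self.model = model
        self.eig = _Eigen(model)
        self.rates = discrete_gamma_rates(model.alpha, model.n_categories)
        codes = _encode(matrix, taxa)
        self.n_sites = codes.shape[1]
        self.patterns, self.weights, self.site_index = _compress(codes)
        self.npat = self.patterns.shape[1]
        self._leaf_partial = {
            name: _MASK_TO_PARTIAL[self.patterns[i]] for i, name in enumerate(taxa)
        }
        self.root = tree.default_root()
        self._refresh_topology()

    def _refresh_topology(self) -> None:
        self.order = self.tree.postorder(self.root)
        self.children: Dict[int, List[int]] = {}
        self.parent: Dict[int, Optional[int]] = {}
        for node, parent, _ in self.order:
            self.parent[node] = parent
            self.children.setdefault(node, [])
            if parent is not None:
                self.children.setdefault(parent, []).append(node)
        self.edge_nodes = [n for n, p, _ in self.order if p is not None]

    # -- passes --------------------------------------------------------

    def _pmat(self, t: float) -> np.ndarray:
        return self.eig.pmats(max(t, BRLEN_MIN), self.rates)

    def _node_base(self, node: int, k: int, npat: int) -> np.ndarray:
        """A node's own data contribution: its leaf partial if it is a
        tip (the traversal root may be a tip on 2-3 taxon trees), else 1."""
        if self.tree.degree(node) == 1:
            return np.broadcast_to(
                self._leaf_partial[self.tree.label[node]][None, :, :], (k, npat, 4)
            ).copy()
        return np.ones((k, npat, 4))

    def lower_pass(self) -> None:
        k, npat = len(self.rates), self.npat
        self.lower: Dict[int, np.ndarray] = {}
        self.lower_scale: Dict[int, np.ndarray] = {}
        self.lifted: Dict[int, np.ndarray] = {}  # child -> P(t_child) applied to lower
        for node, parent, _ in self.order:
            part = self._node_base(node, k, npat)
            scale = np.zeros(npat)
            if self.children[node]:
                for c in self.children[node]:
                    part = part * self.lifted[c]
                    scale = scale + self.lower_scale[c]
                mx = part.max(axis=(0, 2))
                mx = np.where(mx > 0, mx, 1.0)
                part = part / mx[None, :, None]
                scale = scale + np.log(mx)
            self.lower[node] = part
            self.lower_scale[node] = scale
            if parent is not None:
                P = self._pmat(self.tree.adj[node][parent])
                self.lifted[node] = part @ P.transpose(0, 2, 1)

    def upper_pass(self) -> None:
        """Upper conditionals: for each non-root node v with parent p,
        ``upper[v][., pat, j]`` is the likelihood of all data outside the
        subtree of v given state j at p (root frequencies included,
        excluding the edge p-v itself)."""
        k, npat = len(self.rates), self.npat
        pi = self.eig.pi
        self.upper: Dict[int, np.ndarray] = {}
        self.upper_scale: Dict[int, np.ndarray] = {}
        for node, parent, length in reversed(self.order):  # preorder
            if parent is None:
                continue
            sibs = [c for c in self.children[parent] if c != node]
            if self.parent[parent] is None:
                up = pi[None, None, :] * self._node_base(parent, k, npat)
                scale = np.zeros(npat)
            else:
                Pv = self._pmat(self.tree.adj[parent][self.parent[parent]])
                up = self.upper[parent] @ Pv
                scale = self.upper_scale[parent].copy()
            for s in sibs:
                up = up * self.lifted[s]
                scale = scale + self.lower_scale[s]
            mx = up.max(axis=(0, 2))
            mx = np.where(mx > 0, mx, 1.0)
            up = up / mx[None, :, None]
            scale = scale + np.log(mx)
            self.upper[node] = up
            self.upper_scale[node] = scale

    # -- likelihood ----------------------------------------------------

    def pattern_log_likelihoods(self) -> np.ndarray:
        self.lower_pass()
        root = self.root
        L = np.einsum("kpi,i->kp", self.lower[root], self.eig.pi).mean(axis=0)
        L = np.where(L > 0, L, np.finfo(float).tiny)
        return np.log(L) + self.lower_scale[root]

    def site_log_likelihoods(self) -> np.ndarray:
        return self.pattern_log_likelihoods()[self.site_index]

    def total_ll(self) -> float:
        return float(self.pattern_log_likelihoods() @ self.weights)

    def _edge_ll_vec(self, node: int, ts: np.ndarray) -> np.ndarray:
        """LL of the whole alignment as a function of one edge's length,
        evaluated for every candidate in ``ts`` at once using the cached
        upper/lower conditionals."""
        ts = np.clip(ts, BRLEN_MIN, BRLEN_MAX)
        e = np.exp(self.eig.lam[None, None, :] * (ts[:, None, None] * self.rates[None, :, None]))
        P = (self.eig.A[None, None, :, :] * e[:, :, None, :]) @ self.eig.B  # (T, k, 4, 4)
        np.clip(P, 0.0, None, out=P)
        tmp = np.einsum("kpi,tkij->tkpj", self.upper[node], P)
        L = np.einsum("tkpj,kpj->tp", tmp, self.lower[node]) / len(self.rates)
        np.clip(L, np.finfo(float).tiny, None, out=L)
        ll = np.log(L) + (self.upper_scale[node] + self.lower_scale[node])[None, :]
        return ll @ self.weights

    def _edge_ll(self, node: int, t: float) -> float:
        return float(self._edge_ll_vec(node, np.array([t]))[0])

    _COARSE_GRID = np.geomspace(BRLEN_MIN, BRLEN_MAX, 25)

    def _optimize_edge(self, node: int) -> None:
        """Bracketed derivative-free 1-D maximization over the edge to
        ``node``: a geometric grid scan refined twice around the best
        point, accepted only if it improves on the current length."""
        parent = self.parent[node]
        t0 = float(np.clip(self.tree.adj[node][parent], BRLEN_MIN, BRLEN_MAX))
        grid = np.append(self._COARSE_GRID, t0)
        best_t, best_v = t0, -np.inf
        cur_v = None
        for _ in range(3):
            vals = self._edge_ll_vec(node, grid)
            if cur_v is None:
                cur_v = float(vals[-1])  # value at the current length
            i = int(np.argmax(vals))
            if vals[i] > best_v:
                best_t, best_v = float(grid[i]), float(vals[i])
            lo = max(grid[max(i - 1, 0)], BRLEN_MIN)
            hi = min(grid[min(i + 1, len(grid) - 1)], BRLEN_MAX)
            grid = np.exp(np.linspace(np.log(lo), np.log(hi), 9))
        if best_v > cur_v:
            self.tree.set_length(node, parent, best_t)

    def _edge_lengths(self) -> Dict[int, float]:
        return {n: self.tree.adj[n][self.parent[n]] for n in self.edge_nodes}

    def _restore_lengths(self, lengths: Dict[int, float]) -> None:
        for n, t in lengths.items():
            self.tree.set_length(n, self.parent[n], t)

    def optimize_branch_lengths(self, tol: float = 1e-3, max_rounds: int = 20) -> Tuple[float, bool]:
        """Cyclic per-branch maximization.  Returns (LL, converged).

        Each round refreshes the upper/lower conditionals once and sweeps
        all edges against them; the likelihood is verified at the end of
        the round, and a (rare) non-improving sweep is redone with exact
        per-edge refreshes so the LL never decreases between rounds.
        """
        def exact_sweep() -> float:
            for node in self.edge_nodes:
                self.lower_pass()
                self.upper_pass()
                self._optimize_edge(node)
            return self.total_ll()

        prev = self.total_ll()
        converged = False
        for _ in range(max_rounds):
            saved = self._edge_lengths()
            self.lower_pass()
            self.upper_pass()
            for node in self.edge_nodes:
                self._optimize_edge(node)
            cur = self.total_ll()
            if cur < prev - 1e-9:
                self._restore_lengths(saved)
                cur = exact_sweep()
                if cur < prev - 1e-9:  # numerically flat: keep the old lengths
                    self._restore_lengths(saved)
                    cur = prev
            if cur - prev < tol:
                # a fast sweep can stall on stale conditionals; confirm
                # apparent convergence with one exact per-edge sweep
                confirmed = exact_sweep()
                if confirmed - prev < tol:
                    converged = True
                    prev = max(confirmed, prev)
                    break
                cur = confirmed
            prev = cur
        return self.total_ll(), converged


# ---------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------

def site_log_likelihoods(matrix: Mapping[str, str], tree: Tree, model: SubstModel) -> np.ndarray:
    """Per-site log-likelihoods under GTR+GAMMA by the pruning algorithm."""
    if len(next(iter(matrix.values()), "")) == 0:
        return np.zeros(0)
    return LikelihoodEngine(matrix, tree, model).site_log_likelihoods()


def total_log_likelihood(matrix: Mapping[str, str], tree: Tree, model: SubstModel) -> float:
    return LikelihoodEngine(matrix, tree, model).total_ll()


def optimize_branch_lengths(
    matrix: Mapping[str, str],
    tree: Tree,
    model: SubstModel,
    tol: float = 1e-3,
    max_rounds: int = 20,
) -> Tuple[Tree, float]:
    """Branch lengths maximizing the likelihood (topology fixed).

    Iterates bracketed scalar optimization over every branch until the
    round-to-round improvement falls below ``tol``; lengths are clamped to
    [1e-8, 10] substitutions/site.  Returns an optimized copy and its LL.
    """
    work = tree.copy()
    eng = LikelihoodEngine(matrix, work, model)
    ll, _ = eng.optimize_branch_lengths(tol=tol, max_rounds=max_rounds)
    return work, ll


def estimate_model(
    matrix: Mapping[str, str],
    tree: Tree,
    n_categories: int = 4,
    n_outer: int = 2,
) -> Tuple[SubstModel, Tree, float]:
    """Empirical base frequencies plus ML exchangeabilities and gamma
    shape, interleaved with branch-length optimization.

    Returns (model, optimized tree, LL).  A base absent from the data has
    its frequency floored at 1e-4 before renormalization.  ``alpha``
    hitting its upper bound (effectively rate-homogeneous data) is left
    there; with invariant data the shape is unidentifiable.
    """
    counts = np.zeros(4)
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    for seq in matrix.values():
        for ch in seq.upper():
            if ch in base_idx:
                counts[base_idx[ch]] += 1
    if counts.sum() == 0:
        counts[:] = 1.0
    freqs = np.maximum(counts / counts.sum(), 1e-4)
    freqs = freqs / freqs.sum()

    log_lo = np.log([0.02] * 5 + [0.05])
    log_hi = np.log([50.0] * 5 + [100.0])
    x = np.log(np.array([1.0, 1.0, 1.0, 1.0, 1.0, 1.0]))  # 5 rates + alpha

    def build(xv: np.ndarray) -> SubstModel:
        r = np.exp(xv[:5])
        return SubstModel(
            base_freqs=tuple(freqs),
            exchangeabilities=(r[0], r[1], r[2], r[3], r[4], 1.0),
            alpha=float(np.exp(xv[5])),
            n_categories=n_categories,
        )

    work = tree.copy()
    ll = -np.inf
    for _ in range(n_outer):
        model = build(x)
        eng = LikelihoodEngine(matrix, work, model)
        ll, _ = eng.optimize_branch_lengths(tol=1e-2, max_rounds=8)

        def neg(xv: np.ndarray) -> float:
            try:
                return -total_log_likelihood(matrix, work, build(xv))
            except (ValueError, np.linalg.LinAlgError):
                return 1e12

        res = minimize(
            neg, x, method="L-BFGS-B",
            bounds=list(zip(log_lo, log_hi)),
            options={"maxiter": 60},
        )
        if -res.fun >= ll - 1e-9:
            x = res.x
            ll = max(ll, -res.fun)
    model = build(x)
    eng = LikelihoodEngine(matrix, work, model)
    ll, _ = eng.optimize_branch_lengths(tol=1e-3, max_rounds=10)
    return model, work, ll


# ---------------------------------------------------------------------
# parsimony and character census
# ---------------------------------------------------------------------

def fitch_steps(matrix: Mapping[str, str], tree: Tree) -> int:
    """Total Fitch parsimony length over all sites.

    Ambiguity codes enter as state sets; fully missing characters are the
    full state set, so all-missing sites contribute zero steps.
    """
    taxa = tree.taxa()
    if set(taxa) != set(matrix):
        raise TreeError("alignment taxa and tree taxa differ")
    codes = _encode(matrix, taxa)
    patterns, weights, _ = _compress(codes)
    if patterns.shape[1] == 0:
        return 0
    leaf_sets = {name: patterns[i].astype(np.int64) for i, name in enumerate(taxa)}
    root = tree.leaf_by_label(taxa[0])  # root at a leaf: all internals binary
    steps = np.zeros(patterns.shape[1], dtype=np.int64)
    state: Dict[int, np.ndarray] = {}
    children: Dict[int, List[int]] = {}
    order = tree.postorder(root)
    for node, parent, _ in order:
        children.setdefault(node, [])
        if parent is not None:
            children.setdefault(parent, []).append(node)
    for node, parent, _ in order:
        if tree.degree(node) == 1:
            s = leaf_sets[tree.label[node]].copy()
            for c in children[node]:  # the root leaf
                inter = s & state[c]
                empty = inter == 0
                steps += empty
                s = np.where(empty, s | state[c], inter)
        else:
            s = None
            for c in children[node]:
                if s is None:
                    s = state[c].copy()
                    continue
                inter = s & state[c]
                empty = inter == 0
                steps += empty
                s = np.where(empty, s | state[c], inter)
        state[node] = s
    return int(steps @ weights.astype(np.int64))


@dataclass
class CharacterCensus:
    """Alignment-wide character bookkeeping (variable and
    parsimony-informative sites, all-missing columns, missingness)."""

    n_sites: int
    n_variable: int
    n_parsimony_informative: int
    n_all_missing_excluded: int
    missing_proportion: float


def _base_presence(patterns: np.ndarray) -> np.ndarray:
    """(4, npat) count of taxa whose state set includes each base."""
    out = np.zeros((4, patterns.shape[1]), dtype=np.int64)
    miss = (patterns == _MISSING)  # fully missing cells count toward no base
    for b in range(4):
        out[b] = (((patterns >> b) & 1).astype(bool) & ~miss).sum(axis=0)
    return out


def classify_characters(matrix: Mapping[str, str]) -> CharacterCensus:
    """Census of sites: variable (two or more constituent bases observed
    among non-missing cells), parsimony-informative (two or more bases
    each backed by two or more taxa, ambiguity codes expanded), columns
    that are entirely missing, and the overall missing-cell fraction."""
    taxa = sorted(matrix)
    if not taxa:
        return CharacterCensus(0, 0, 0, 0, 0.0)
    codes = _encode(matrix, taxa)
    n_taxa, n_sites = codes.shape
    if n_sites == 0:
        return CharacterCensus(0, 0, 0, 0, 0.0)
    patterns, weights, _ = _compress(codes)
    w = weights.astype(np.int64)
    presence = _base_presence(patterns)
    all_missing = (patterns == _MISSING).all(axis=0)
    variable = ((presence >= 1).sum(axis=0) >= 2) & ~all_missing
    informative = ((presence >= 2).sum(axis=0) >= 2) & ~all_missing
    n_missing_cells = int(((codes == _MISSING)).sum())
    return CharacterCensus(
        n_sites=n_sites,
        n_variable=int(variable @ w),
        n_parsimony_informative=int(informative @ w),
        n_all_missing_excluded=int(all_missing @ w),
        missing_proportion=n_missing_cells / (n_taxa * n_sites),
    )


def _min_steps(patterns: np.ndarray, weights: np.ndarray) -> int:
    """Minimum conceivable changes: per column, the smallest number of
    bases covering every taxon's state set, minus one (exact by
    enumeration over the 15 base subsets)."""
    npat = patterns.shape[1]
    best = np.full(npat, 4, dtype=np.int64)
    miss = (patterns == _MISSING)
    for subset in range(1, 16):
        size = bin(subset).count("1")
        covers = ((patterns & subset) != 0) | miss
        ok = covers.all(axis=0)
        best = np.where(ok & (size < best), size, best)
    all_missing = miss.all(axis=0)
    per_col = np.where(all_missing, 0, best - 1)
    return int(per_col @ weights.astype(np.int64))


def consistency_index(matrix: Mapping[str, str], tree: Tree) -> float:
    """Ensemble consistency index: minimum conceivable steps divided by
    observed Fitch steps; 1.0 (with no homoplasy possible) when the tree
    requires zero steps."""
    steps = fitch_steps(matrix, tree)
    if steps == 0:
        return 1.0
    taxa = sorted(matrix)
    patterns, weights, _ = _compress(_encode(matrix, taxa))
    return _min_steps(patterns, weights) / steps


# ---------------------------------------------------------------------
# tree search and bootstrap
# ---------------------------------------------------------------------

def neighbor_joining_tree(matrix: Mapping[str, str]) -> Tree:
    """Neighbor-joining starting tree from Jukes-Cantor distances
    (scikit-bio's NJ); zero/negative branch lengths floored at 1e-6."""
    import skbio

    taxa = sorted(matrix)
    n = len(taxa)
    codes = _encode(matrix, taxa)
    resolved = np.isin(codes, (1, 2, 4, 8))
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = resolved[i] & resolved[j]
            nb = int(both.sum())
            if nb == 0:
                p = 0.5
            else:
                p = float((codes[i][both] != codes[j][both]).sum()) / nb
            p = min(p, 0.74)
            dist = -0.75 * np.log(1.0 - 4.0 * p / 3.0)
            d[i, j] = d[j, i] = dist
    dm = skbio.DistanceMatrix(d, ids=taxa)
    newick = skbio.tree.nj(dm, result_constructor=str)
    t = Tree.from_newick(newick)
    for u, v, length in list(t.edges()):
        if length < 1e-6:
            t.set_length(u, v, 1e-6)
    return t


def nni_hill_climb(
    matrix: Mapping[str, str],
    model: SubstModel,
    start: Tree,
    tol: float = 1e-3,
    max_iter: int = 50,
    opt_rounds: int = 5,
) -> Tuple[Tree, float]:
    """Greedy ML search: from ``start``, repeatedly re-optimize branch
    lengths, score every 1-step NNI neighbor, and move to the best
    strictly improving one; stops at a local optimum.  Deterministic."""
    from .tree_ops import nni_neighbors

    current, cur_ll = optimize_branch_lengths(matrix, start, model, tol=tol, max_rounds=opt_rounds)
    for _ in range(max_iter):
        best_tree, best_ll = None, cur_ll
        for nb in nni_neighbors(current):
            cand, ll = optimize_branch_lengths(matrix, nb, model, tol=tol, max_rounds=opt_rounds)
            if ll > best_ll + 1e-6:
                best_tree, best_ll = cand, ll
        if best_tree is None:
            break
        current, cur_ll = best_tree, best_ll
    return current, cur_ll


@dataclass
class BootstrapResult:
    """Bipartition supports (%) for the reference tree's internal splits."""

    reference: Tree
    support: Dict[int, float]  # normalized split mask -> percent
    mean: float
    degenerate: bool = False

    def annotate(self) -> Dict[frozenset, float]:
        taxa, _ = _split_masks(self.reference)
        out = {}
        for mask, pct in self.support.items():
            side = frozenset(t for i, t in enumerate(taxa) if mask >> i & 1)
            out[side] = pct
        return out


def bootstrap_support(
    matrix: Mapping[str, str],
    model: SubstModel,
    reps: int,
    rng_seed: int,
    reference: Optional[Tree] = None,
    search: bool = True,
) -> BootstrapResult:
    """Nonparametric bootstrap: resample sites with replacement, re-infer
    a tree per replicate (NJ start + NNI hill climb), and report for each
    internal bipartition of the reference tree the percentage of
    replicate trees containing it; ``mean`` is the unweighted mean over
    internal bipartitions."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    taxa = sorted(matrix)
    n_sites = len(next(iter(matrix.values())))
    census = classify_characters(matrix)
    if census.n_variable == 0:
        ref = reference if reference is not None else neighbor_joining_tree(matrix)
        _, masks = _split_masks(ref)
        return BootstrapResult(ref, {m: 0.0 for m in masks}, 0.0, degenerate=True)
    if reference is None:
        start = neighbor_joining_tree(matrix)
        if search:
            reference, _ = nni_hill_climb(matrix, model, start)
        else:
            reference, _ = optimize_branch_lengths(matrix, start, model)
    _, ref_masks = _split_masks(reference)
    hits = {m: 0 for m in ref_masks}
    rng = np.random.default_rng(rng_seed)
    for _ in range(reps):
        cols = rng.integers(0, n_sites, size=n_sites)
        res = {t: "".join(matrix[t][c] for c in cols) for t in taxa}
        try:
            start = neighbor_joining_tree(res)
            if search:
                rep_tree, _ = nni_hill_climb(res, model, start, opt_rounds=3)
            else:
                rep_tree = start
        except Exception:
            continue
        _, rep_masks = _split_masks(rep_tree)
        rep_set = set(rep_masks)
        for m in ref_masks:
            if m in rep_set:
                hits[m] += 1
    support = {m: 100.0 * h / reps for m, h in hits.items()}
    mean = float(np.mean(list(support.values()))) if support else 0.0
    return BootstrapResult(reference, support, mean)
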