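"""Unrooted phylogenetic trees: canonical topology identifiers, NNI
neighborhoods, candidate tree pools, per-locus pruning and branch-length
summaries.

The central object is :class:`Tree`, a mutable unrooted tree stored as an
adjacency map with branch lengths in substitutions/site.  Topologies are
compared through :func:`canonical_id`, a hash of the tree's non-trivial
bipartition set, which makes deduplication of NNI-permuted pools exact.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Optional, Sequence, Set, Tuple

import dendropy
import numpy as np

__all__ = [
    "Tree",
    "TopologyID",
    "TreePool",
    "PrunedTreeSet",
    "canonical_id",
    "nni_neighbors",
    "build_tree_pool",
    "prune_and_dedup",
    "tip_branch_proportion",
    "basal_terminal_ratio",
    "robinson_foulds",
]

# A TopologyID is (sorted taxon tuple, sha1 hex of the sorted normalized
# bipartition masks).  Two trees share an ID iff they share taxa and
# unrooted topology.
TopologyID = Tuple[Tuple[str, ...], str]


class TreeError(ValueError):
    pass


class Tree:
    """Unrooted tree over labelled tips with branch lengths.

    Nodes are integer ids; ``adj[u][v]`` is the length of edge (u, v)
    (stored symmetrically).  Leaves carry taxon labels in ``label``.
    """

    def __init__(self) -> None:
        self.adj: Dict[int, Dict[int, float]] = {}
        self.label: Dict[int, str] = {}
        self._next_id = 0

    # -- construction -------------------------------------------------

    def new_node(self, label: Optional[str] = None) -> int:
        nid = self._next_id
        self._next_id += 1
        self.adj[nid] = {}
        if label is not None:
            self.label[nid] = label
        return nid

    def add_edge(self, u: int, v: int, length: float) -> None:
        if v in self.adj[u]:
            raise TreeError(f"edge ({u},{v}) already exists")
        self.adj[u][v] = float(length)
        self.adj[v][u] = float(length)

    def remove_edge(self, u: int, v: int) -> float:
        length = self.adj[u].pop(v)
        self.adj[v].pop(u)
        return length

    def remove_node(self, u: int) -> None:
        for v in list(self.adj[u]):
            self.remove_edge(u, v)
        del self.adj[u]
        self.label.pop(u, None)

    def copy(self) -> "Tree":
        t = Tree()
        t.adj = {u: dict(nbrs) for u, nbrs in self.adj.items()}
        t.label = dict(self.label)
        t._next_id = self._next_id
        return t

    # -- basic queries -------------------------------------------------

    def nodes(self) -> Iterable[int]:
        return self.adj.keys()

    def degree(self, u: int) -> int:
        return len(self.adj[u])

    def leaves(self) -> List[int]:
        return [u for u in self.adj if self.degree(u) == 1]

    def taxa(self) -> List[str]:
        return sorted(self.label[u] for u in self.leaves())

    def leaf_by_label(self, name: str) -> int:
        for u in self.leaves():
            if self.label.get(u) == name:
                return u
        raise KeyError(name)

    def n_taxa(self) -> int:
        return len(self.leaves())

    def edges(self) -> Iterator[Tuple[int, int, float]]:
        for u, nbrs in self.adj.items():
            for v, length in nbrs.items():
                if u < v:
                    yield u, v, length

    def internal_edges(self) -> Iterator[Tuple[int, int, float]]:
        for u, v, length in self.edges():
            if self.degree(u) > 1 and self.degree(v) > 1:
                yield u, v, length

    def set_length(self, u: int, v: int, length: float) -> None:
        self.adj[u][v] = float(length)
        self.adj[v][u] = float(length)

    def total_length(self) -> float:
        return sum(length for _, _, length in self.edges())

    def is_binary(self) -> bool:
        return all(self.degree(u) in (1, 3) for u in self.adj)

    # -- traversal -----------------------------------------------------

    def default_root(self) -> int:
        """An internal node if one exists, else an arbitrary node."""
        for u in self.adj:
            if self.degree(u) > 1:
                return u
        return next(iter(self.adj))

    def postorder(self, root: Optional[int] = None) -> List[Tuple[int, Optional[int], float]]:
        """(node, parent, length of edge to parent) in postorder from root."""
        if not self.adj:
            return []
        if root is None:
            root = self.default_root()
        out: List[Tuple[int, Optional[int], float]] = []
        stack: List[Tuple[int, Optional[int], float]] = [(root, None, 0.0)]
        seen = set()
        order = []
        while stack:
            node, parent, length = stack.pop()
            seen.add(node)
            order.append((node, parent, length))
            for v, l in self.adj[node].items():
                if v != parent:
                    stack.append((v, node, l))
        order.reverse()
        return order

    def path_lengths_from(self, node: int) -> Dict[int, float]:
        dist = {node: 0.0}
        stack = [node]
        while stack:
            u = stack.pop()
            for v, l in self.adj[u].items():
                if v not in dist:
                    dist[v] = dist[u] + l
                    stack.append(v)
        return dist

    # -- newick --------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, default_length: float = 0.1) -> "Tree":
        """Parse a Newick string (rooted or unrooted; root suppressed)."""
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        t = cls()
        ids: Dict[int, int] = {}
        for nd in dtree.preorder_node_iter():
            lab = nd.taxon.label if nd.taxon is not None else None
            ids[id(nd)] = t.new_node(lab)
        for nd in dtree.preorder_node_iter():
            if nd.parent_node is not None:
                length = nd.edge.length if nd.edge.length is not None else default_length
                t.add_edge(ids[id(nd.parent_node)], ids[id(nd)], length)
        # suppress degree-2 vertices (e.g. the root of a rooted newick)
        t._suppress_degree_two()
        return t

    def _suppress_degree_two(self) -> None:
        changed = True
        while changed:
            changed = False
            for u in list(self.adj):
                if self.degree(u) == 2 and u not in self.label:
                    (a, la), (b, lb) = self.adj[u].items()
                    self.remove_node(u)
                    self.add_edge(a, b, la + lb)
                    changed = True

    def to_newick(self, root: Optional[int] = None, include_lengths: bool = True) -> str:
        if not self.adj:
            return ";"
        if root is None:
            root = self.default_root()

        def rec(node: int, parent: Optional[int]) -> str:
            children = [v for v in self.adj[node] if v != parent]
            if not children:
                name = self.label.get(node, "")
                return name
            inner = ",".join(
                rec(c, node)
                + (f":{self.adj[node][c]:.10g}" if include_lengths else "")
                for c in sorted(children, key=lambda c: min(self._subtree_taxa(c, node)))
            )
            return f"({inner})"

        return rec(root, None) + ";"

    def _subtree_taxa(self, node: int, parent: int) -> Set[str]:
        out: Set[str] = set()
        stack = [(node, parent)]
        while stack:
            u, p = stack.pop()
            if self.degree(u) == 1:
                out.add(self.label[u])
            for v in self.adj[u]:
                if v != p:
                    stack.append((v, u))
        return out

    def to_dendropy(self, taxon_namespace: Optional[dendropy.TaxonNamespace] = None) -> dendropy.Tree:
        return dendropy.Tree.get(
            data=self.to_newick(),
            schema="newick",
            taxon_namespace=taxon_namespace or dendropy.TaxonNamespace(),
        )

    # -- editing used by simulation and pruning ------------------------

    def attach_leaf(self, u: int, v: int, label: str, leaf_length: float,
                    split_at: float = 0.5) -> int:
        """Split edge (u, v) with a new internal node and hang a new leaf."""
        length = self.remove_edge(u, v)
        mid = self.new_node()
        self.add_edge(u, mid, length * split_at)
        self.add_edge(mid, v, length * (1.0 - split_at))
        leaf = self.new_node(label)
        self.add_edge(mid, leaf, leaf_length)
        return leaf

    def prune_to(self, keep_taxa: Iterable[str]) -> "Tree":
        """Restriction to ``keep_taxa``; degree-2 vertices suppressed with
        incident branch lengths summed."""
        keep = set(keep_taxa)
        missing = keep - set(self.taxa())
        if missing:
            raise TreeError(f"taxa not in tree: {sorted(missing)}")
        t = self.copy()
        # iteratively strip leaves not kept
        changed = True
        while changed:
            changed = False
            for u in list(t.adj):
                if t.degree(u) == 1 and t.label.get(u) not in keep:
                    t.remove_node(u)
                    changed = True
                elif t.degree(u) == 0 and len(t.adj) > 1:
                    t.remove_node(u)
                    changed = True
        t._suppress_degree_two()
        return t


# ---------------------------------------------------------------------
# canonical topology identity
# ---------------------------------------------------------------------

def _split_masks(tree: Tree) -> Tuple[List[str], List[int]]:
    """Taxa (sorted) and the normalized non-trivial bipartition masks.

    Each internal edge is represented by the bitmask of the side *not*
    containing the first taxon, so the representation is rotation- and
    rooting-invariant.
    """
    taxa = tree.taxa()
    index = {name: i for i, name in enumerate(taxa)}
    full = (1 << len(taxa)) - 1
    below: Dict[int, int] = {}
    masks: List[int] = []
    for node, parent, _ in tree.postorder():
        if tree.degree(node) == 1:
            m = 1 << index[tree.label[node]]
        else:
            m = 0
            for v in tree.adj[node]:
                if v != parent:
                    m |= below[v]
        below[node] = m
        if parent is not None:
            size = bin(m).count("1")
            if 2 <= size <= len(taxa) - 2:
                masks.append(m if not (m & 1) else (full ^ m))
    return taxa, sorted(set(masks))


def canonical_id(tree: Tree) -> TopologyID:
    """Canonical identifier of the unrooted topology.

    Invariant under re-rooting, child rotation and ladderization; trees
    with fewer than 4 taxa all map to a single degenerate identifier for
    their taxon set.
    """
    taxa, masks = _split_masks(tree)
    if len(taxa) < 4:
        return tuple(taxa), "degenerate"
    h = hashlib.sha1()
    for m in masks:
        h.update(m.to_bytes((m.bit_length() + 7) // 8 or 1, "little"))
        h.update(b"|")
    return tuple(taxa), h.hexdigest()


def robinson_foulds(a: Tree, b: Tree) -> int:
    """Unweighted Robinson-Foulds distance (symmetric difference of
    non-trivial bipartition sets); trees must share a taxon set."""
    ta, ma = _split_masks(a)
    tb, mb = _split_masks(b)
    if ta != tb:
        raise TreeError("trees have different taxon sets")
    return len(set(ma) ^ set(mb))


# ---------------------------------------------------------------------
# NNI neighborhood
# ---------------------------------------------------------------------

def _nni_swap(tree: Tree, v: int, a: int, u: int, c: int) -> Tree:
    """Return a copy with subtree a (attached at v) and subtree c
    (attached at u) exchanged across internal edge (u, v).  Moved
    subtrees carry their branch lengths."""
    t = tree.copy()
    la = t.remove_edge(v, a)
    lc = t.remove_edge(u, c)
    t.add_edge(u, a, la)
    t.add_edge(v, c, lc)
    return t


def nni_neighbors(tree: Tree) -> List[Tree]:
    """All topologies one nearest-neighbor interchange away.

    For an unrooted binary tree on n taxa there are exactly 2(n-3)
    distinct neighbor topologies (two per internal edge); the list is
    deduplicated by :func:`canonical_id` and excludes the input topology.
    """
    if not tree.is_binary():
        raise TreeError("NNI requires an unrooted binary tree; resolve polytomies first")
    own = canonical_id(tree)
    seen = {own}
    out: List[Tree] = []
    for u, v, _ in tree.internal_edges():
        a, b = [x for x in tree.adj[v] if x != u]
        c = next(x for x in tree.adj[u] if x != v)
        for moved in (a, b):
            cand = _nni_swap(tree, v, moved, u, c)
            cid = canonical_id(cand)
            if cid not in seen:
                seen.add(cid)
                out.append(cand)
    return out


# ---------------------------------------------------------------------
# candidate tree pool
# ---------------------------------------------------------------------

@dataclass
class TreePool:
    """Ordered pool of unique topologies: the optimal tree plus NNI-permuted
    suboptimal candidates, tagged by origin (``optimal``/``nni1``/``nni2``)."""

    trees: List[Tree]
    origin: List[str]
    ids: List[TopologyID]

    def __post_init__(self) -> None:
        if len(set(self.ids)) != len(self.ids):
            raise TreeError("pool contains duplicate topologies")
        if self.origin.count("optimal") != 1:
            raise TreeError("pool must contain exactly one optimal tree")

    def __len__(self) -> int:
        return len(self.trees)

    @property
    def optimal(self) -> Tree:
        return self.trees[self.origin.index("optimal")]


def _sort_key(tree: Tree) -> str:
    return canonical_id(tree)[1]


def build_tree_pool(optimal: Tree, n_permuted: int, rng_seed: int) -> TreePool:
    """Candidate pool: the optimal tree, all unique 1-step NNI neighbors,
    then uniformly sampled unique 2-step neighbors until ``n_permuted``
    permuted trees are collected (pool size ``n_permuted + 1``).

    2-step neighbors are topologies reached by two successive NNI moves
    that are distinct from the optimal tree and from every 1-step
    neighbor.  Sampling is without replacement and deterministic for a
    given seed.
    """
    one_step = nni_neighbors(optimal)
    if n_permuted < len(one_step):
        raise TreeError(
            f"n_permuted={n_permuted} is below the 1-step neighborhood size {len(one_step)}"
        )
    excluded = {canonical_id(optimal)} | {canonical_id(t) for t in one_step}
    two_step: Dict[TopologyID, Tree] = {}
    for t1 in one_step:
        for t2 in nni_neighbors(t1):
            cid = canonical_id(t2)
            if cid not in excluded and cid not in two_step:
                two_step[cid] = t2
    n_two = n_permuted - len(one_step)
    if n_two > len(two_step):
        raise TreeError(
            f"requested {n_two} unique 2-step topologies but only {len(two_step)} exist"
        )
    candidates = sorted(two_step.values(), key=_sort_key)
    rng = np.random.default_rng(rng_seed)
    chosen_idx = rng.choice(len(candidates), size=n_two, replace=False)
    chosen = [candidates[i] for i in chosen_idx]

    trees = [optimal] + one_step + chosen
    origin = ["optimal"] + ["nni1"] * len(one_step) + ["nni2"] * len(chosen)
    ids = [canonical_id(t) for t in trees]
    return TreePool(trees=trees, origin=origin, ids=ids)


# ---------------------------------------------------------------------
# per-locus pruning
# ---------------------------------------------------------------------

@dataclass
class PrunedTreeSet:
    """Unique pruned topologies plus, for each pool tree, the index of its
    pruned representative."""

    trees: List[Tree]
    index_map: List[int]  # pool index -> representative index

    def __len__(self) -> int:
        return len(self.trees)


def prune_and_dedup(pool: TreePool, keep_taxa: Iterable[str]) -> PrunedTreeSet:
    """Restrict every pool tree to ``keep_taxa`` and deduplicate the
    results, recording which unique pruned tree represents each pool tree."""
    keep = set(keep_taxa)
    if len(keep) < 4:
        raise TreeError(f"need at least 4 taxa to prune to, got {len(keep)}")
    reps: List[Tree] = []
    rep_ids: Dict[TopologyID, int] = {}
    index_map: List[int] = []
    for t in pool.trees:
        pruned = t.prune_to(keep)
        cid = canonical_id(pruned)
        if cid not in rep_ids:
            rep_ids[cid] = len(reps)
            reps.append(pruned)
        index_map.append(rep_ids[cid])
    return PrunedTreeSet(trees=reps, index_map=index_map)


# ---------------------------------------------------------------------
# branch-length summaries
# ---------------------------------------------------------------------

def tip_branch_proportion(tree: Tree) -> float:
    """Fraction of total branch length held in terminal branches."""
    total = tree.total_length()
    if total <= 0:
        raise TreeError("tree has zero total branch length")
    tip = sum(
        length for u, v, length in tree.edges()
        if tree.degree(u) == 1 or tree.degree(v) == 1
    )
    return tip / total


def basal_terminal_ratio(
    tree: Tree,
    replicate_pairs: Sequence[Tuple[str, str]],
    outgroup: str,
    n_basal: int = 3,
) -> float:
    """Ratio of the basalmost internal branch lengths to the terminal
    branches subtending technical-replicate pairs.

    "Basalmost" means the ``n_basal`` internal edges nearest the outgroup
    attachment point in breadth-first order.  Each replicate pair must be
    sister in the tree.  A zero denominator returns +inf.
    """
    og = tree.leaf_by_label(outgroup)
    start = next(iter(tree.adj[og]))
    # BFS over internal edges from the outgroup attachment node
    basal_sum = 0.0
    n_found = 0
    visited = {og, start}
    frontier = [start]
    while frontier and n_found < n_basal:
        nxt = []
        for u in frontier:
            for v, length in sorted(tree.adj[u].items()):
                if v in visited or tree.degree(v) == 1:
                    continue
                visited.add(v)
                basal_sum += length
                n_found += 1
                nxt.append(v)
                if n_found == n_basal:
                    break
            if n_found == n_basal:
                break
        frontier = nxt

    term_sum = 0.0
    for a, b in replicate_pairs:
        na, nb = tree.leaf_by_label(a), tree.leaf_by_label(b)
        pa, pb = next(iter(tree.adj[na])), next(iter(tree.adj[nb]))
        if pa != pb:
            raise TreeError(f"replicate pair ({a}, {b}) is not sister in the tree")
        term_sum += tree.adj[na][pa] + tree.adj[nb][pb]
    if term_sum == 0.0:
        return float("inf")
    return basal_sum / term_sum
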