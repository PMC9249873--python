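"""Quartet-frequency internode certainty (IC).

For every internal edge of a reference tree, quartets are drawn with
one leaf from each of the four subtrees incident to the edge.  Each
evaluation tree that contains all four leaves votes for one of the
three resolved quartet topologies (or abstains when its induced
quartet is unresolved).  Trees missing a leaf simply do not vote on
that quartet, which is what corrects IC for missing taxa.  The score
is the entropy-based internode certainty over pooled counts:

    IC = 1 + sum_i p_i log3 p_i,   p_i = q_i / (q_ref + q_alt1 + q_alt2)

with the sign flipped to negative when the reference topology is not
the strict plurality.  IC = 1 means unanimous support, 0 maximal
conflict, negative values a dominant conflicting resolution.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

import numpy as np

from .trees import Node, PhyloTree

EXHAUSTIVE_LIMIT = 10_000


@dataclass
class QuartetSupport:
    """Pooled quartet tallies around one internal edge."""

    bipartition: frozenset
    q_ref: float
    q_alt1: float
    q_alt2: float
    n_evaluated: int
    mode: str = "exhaustive"

    @property
    def total(self) -> float:
        return self.q_ref + self.q_alt1 + self.q_alt2


@dataclass
class EdgeIC:
    bipartition: frozenset
    support: QuartetSupport
    ic: float


@dataclass
class ICResult:
    edges: list
    mode: str
    m: Optional[int]
    seed: Optional[int]
    annotated_tree: PhyloTree = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# Edge geometry
# ---------------------------------------------------------------------------

def _edge_subtree_groups(tree: PhyloTree, child: Node):
    """The four (or more, under polytomy) leaf groups incident to the
    edge above *child*, split into the child side and the parent side."""
    sets = tree.leafsets()
    all_leaves = frozenset(tree.leaf_names())
    child_groups = [sorted(sets[c]) for c in child.children]
    parent = child.parent
    parent_groups = []
    for sib in parent.children:
        if sib is not child:
            parent_groups.append(sorted(sets[sib]))
    if parent.parent is not None:
        above = all_leaves - sets[parent]
        if above:
            parent_groups.append(sorted(above))
    if len(child_groups) < 2 or len(parent_groups) < 2:
        raise ValueError("edge is not internal")
    return child_groups, parent_groups


def internal_edges(tree: PhyloTree) -> list[Node]:
    """Child nodes of internal edges, on the unrooted view of *tree*."""
    t = tree.unrooted() if len(tree.root.children) == 2 else tree
    out = []
    for node in t.preorder():
        if node.is_leaf or node.parent is None:
            continue
        if len(node.children) >= 2:
            out.append(node)
    return out


# ---------------------------------------------------------------------------
# Quartet evaluation against an evaluation-tree set
# ---------------------------------------------------------------------------

class _EvalTreeIndex:
    """Topological leaf-distance matrix; O(1) quartet resolution."""

    def __init__(self, tree: PhyloTree):
        D, labels = tree.distance_matrix(topological=True)
        self.index = {name: i for i, name in enumerate(labels)}
        self.D = D

    def quartet_vote(self, a, b, c, d) -> Optional[int]:
        """0 = ab|cd, 1 = ac|bd, 2 = ad|bc, None = missing leaf or
        unresolved (polytomy)."""
        ix = self.index
        if a not in ix or b not in ix or c not in ix or d not in ix:
            return None
        ia, ib, ic_, id_ = ix[a], ix[b], ix[c], ix[d]
        D = self.D
        s = (
            D[ia, ib] + D[ic_, id_],
            D[ia, ic_] + D[ib, id_],
            D[ia, id_] + D[ib, ic_],
        )
        m = min(s)
        winners = [i for i, v in enumerate(s) if v == m]
        return winners[0] if len(winners) == 1 else None

    def has(self, *names) -> bool:
        return all(n in self.index for n in names)


def _count_quartets(child_groups, parent_groups) -> int:
    def pair_total(groups):
        sizes = [len(g) for g in groups]
        return sum(si * sj for si, sj in combinations(sizes, 2))

    return pair_total(child_groups) * pair_total(parent_groups)


def _iter_all_quartets(child_groups, parent_groups):
    for g1, g2 in combinations(child_groups, 2):
        for h1, h2 in combinations(parent_groups, 2):
            for a in g1:
                for b in g2:
                    for c in h1:
                        for d in h2:
                            yield a, b, c, d


def _sample_quartets(child_groups, parent_groups, m, rng):
    def side_pairs(groups):
        pairs = list(combinations(range(len(groups)), 2))
        weights = np.array(
            [len(groups[i]) * len(groups[j]) for i, j in pairs], dtype=float
        )
        return pairs, weights / weights.sum()

    cpairs, cw = side_pairs(child_groups)
    ppairs, pw = side_pairs(parent_groups)
    for _ in range(m):
        i, j = cpairs[rng.choice(len(cpairs), p=cw)]
        k, l = ppairs[rng.choice(len(ppairs), p=pw)]
        a = child_groups[i][rng.integers(len(child_groups[i]))]
        b = child_groups[j][rng.integers(len(child_groups[j]))]
        c = parent_groups[k][rng.integers(len(parent_groups[k]))]
        d = parent_groups[l][rng.integers(len(parent_groups[l]))]
        yield a, b, c, d


def quartet_counts(
    ref_tree: PhyloTree,
    edge,
    eval_trees: Sequence[PhyloTree],
    mode: str = "auto",
    m: int = 1000,
    seed: int = 0,
    _indices: Optional[list] = None,
) -> QuartetSupport:
    """Tally the three quartet topologies around one internal edge.

    *edge* is either a child :class:`Node` of the reference tree or a
    bipartition (frozenset of leaf names identifying one side).  In
    ``sampled`` mode, *m* quartets are drawn uniformly with a fixed
    seed; ``auto`` enumerates exhaustively up to 10,000 quartets.
    """
    tree = ref_tree.unrooted() if len(ref_tree.root.children) == 2 else ref_tree
    if isinstance(edge, Node):
        if edge.parent is None or edge.is_leaf:
            raise ValueError("edge is not internal")
        # the node may come from another copy of the tree: resolve by its
        # below-leafset
        stack, below_names = [edge], []
        while stack:
            n = stack.pop()
            if n.is_leaf:
                below_names.append(n.name)
            stack.extend(n.children)
        want = frozenset(below_names)
    else:
        want = frozenset(edge)
    all_leaves = frozenset(tree.leaf_names())
    sets = tree.leafsets()
    child = None
    for node, below in sets.items():
        if node.is_leaf or node.parent is None:
            continue
        if below == want or all_leaves - below == want:
            child = node
            break
    if child is None:
        raise ValueError(f"no internal edge with bipartition {sorted(want)}")

    child_groups, parent_groups = _edge_subtree_groups(tree, child)
    total = _count_quartets(child_groups, parent_groups)
    if mode == "auto":
        mode = "exhaustive" if total <= EXHAUSTIVE_LIMIT else "sampled"
    if mode == "sampled" and m <= 0:
        raise ValueError("m must be > 0 in sampled mode")

    indices = (
        _indices
        if _indices is not None
        else [_EvalTreeIndex(t) for t in eval_trees]
    )
    if mode == "exhaustive":
        quartets = _iter_all_quartets(child_groups, parent_groups)
    else:
        rng = np.random.default_rng(seed)
        quartets = _sample_quartets(child_groups, parent_groups, m, rng)

    counts = [0, 0, 0]
    n_eval = 0
    for a, b, c, d in quartets:
        for idx in indices:
            if not idx.has(a, b, c, d):
                continue
            n_eval += 1
            vote = idx.quartet_vote(a, b, c, d)
            if vote is not None:
                counts[vote] += 1

    sets = tree.leafsets()
    all_leaves = frozenset(tree.leaf_names())
    below = sets[child]
    ref_leaf = min(all_leaves)
    bip = below if ref_leaf not in below else all_leaves - below
    return QuartetSupport(
        bipartition=frozenset(bip),
        q_ref=counts[0],
        q_alt1=counts[1],
        q_alt2=counts[2],
        n_evaluated=n_eval,
        mode=mode,
    )


def ic_score(support: QuartetSupport) -> float:
    """Entropy-based internode certainty of pooled quartet counts.

    Undefined when no quartet was resolved (returns NaN with warning).
    """
    total = support.total
    if total <= 0:
        warnings.warn("no resolved quartets; IC undefined")
        return float("nan")
    ps = [support.q_ref / total, support.q_alt1 / total, support.q_alt2 / total]
    ic = 1.0 + sum(p * math.log(p, 3) for p in ps if p > 0)
    ic = max(min(ic, 1.0), 0.0)
    strict_max = support.q_ref > max(support.q_alt1, support.q_alt2)
    if not strict_max and ic > 0:
        ic = -ic
    return ic


def ic_all_edges(
    ref_tree: PhyloTree,
    eval_trees: Sequence[PhyloTree],
    mode: str = "auto",
    m: int = 1000,
    seed: int = 0,
) -> ICResult:
    """IC for every internal edge; also returns a copy of the reference
    tree with IC values written as internal-node labels."""
    tree = ref_tree.unrooted() if len(ref_tree.root.children) == 2 else ref_tree
    edges = internal_edges(tree)
    if not edges:
        raise ValueError("reference tree has no internal edge")
    indices = [_EvalTreeIndex(t) for t in eval_trees]
    results = []
    by_node = {}
    for i, child in enumerate(edges):
        support = quartet_counts(
            tree, child, eval_trees, mode=mode, m=m, seed=seed + i,
            _indices=indices,
        )
        ic = ic_score(support)
        results.append(EdgeIC(support.bipartition, support, ic))
        by_node[id(child)] = ic
    annotated = tree.copy()
    for orig, copy_node in zip(tree.preorder(), annotated.preorder()):
        if id(orig) in by_node:
            copy_node.support = round(by_node[id(orig)], 4)
    return ICResult(
        edges=results,
        mode=results[0].support.mode if results else mode,
        m=m,
        seed=seed,
        annotated_tree=annotated,
    )
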