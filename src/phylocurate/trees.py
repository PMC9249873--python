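"""Light phylogenetic tree structure used throughout the pipeline.

Carries gene trees, species trees and bootstrap sets.  Branch lengths are
in expected substitutions/site; internal edges may carry support values
(bootstrap percentages in [0, 100]) or internode-certainty annotations.
Parsing is delegated to dendropy (see :mod:`phylocurate.io`); this module
owns the in-memory representation and tree arithmetic.
"""

from __future__ import annotations

from collections import deque
from typing import Iterator, Optional

import numpy as np


class Node:
    __slots__ = ("children", "parent", "length", "support", "name")

    def __init__(
        self,
        name: Optional[str] = None,
        length: float = 0.0,
        support: Optional[float] = None,
    ):
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.length = length
        self.support = support
        self.name = name

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover
        return f"Node({self.name!r}, L={self.length}, sup={self.support})"


class PhyloTree:
    """(Un)rooted tree over uniquely labeled leaves.

    An unrooted tree is stored rooted at an arbitrary internal node with
    three or more children; a rooted tree has a bifurcating root.
    """

    def __init__(self, root: Node, rooted: Optional[bool] = None):
        self.root = root
        if rooted is None:
            rooted = len(root.children) == 2
        self.rooted = rooted
        self._validate()

    def _validate(self) -> None:
        names = self.leaf_names()
        if len(set(names)) != len(names):
            dups = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate leaf label(s): {', '.join(dups)}")
        for node in self.preorder():
            if node.length < 0:
                raise ValueError(f"negative branch length at {node.name or 'internal'}")

    # -- traversal -------------------------------------------------------
    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[Node]:
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [n for n in self.preorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def find_leaf(self, name: str) -> Node:
        for n in self.leaves():
            if n.name == name:
                return n
        raise KeyError(name)

    # -- editing ---------------------------------------------------------
    def suppress_unifurcations(self) -> None:
        """Remove degree-2 internal nodes, summing branch lengths."""
        changed = True
        while changed:
            changed = False
            for node in list(self.preorder()):
                if node.is_leaf or node is self.root:
                    continue
                if len(node.children) == 1:
                    child = node.children[0]
                    child.length += node.length
                    parent = node.parent
                    i = parent.children.index(node)
                    parent.children[i] = child
                    child.parent = parent
                    changed = True
            if len(self.root.children) == 1 and not self.root.children[0].is_leaf:
                new_root = self.root.children[0]
                new_root.parent = None
                new_root.length = 0.0
                self.root = new_root
                changed = True

    def unrooted(self) -> "PhyloTree":
        """Copy with a bifurcating root collapsed into a trifurcation.

        Support/length of the collapsed root edge is preserved on the
        surviving child edge (sum of the two root-child lengths).
        """
        t = self.copy()
        if len(t.root.children) == 2:
            a, b = t.root.children
            keep, merge = (a, b) if not a.is_leaf else (b, a)
            if keep.is_leaf:  # two-leaf tree: nothing to collapse
                t.rooted = False
                return t
            merge.length += keep.length
            if merge.support is None:
                merge.support = keep.support
            keep.parent = None
            # re-root at `keep`, attaching `merge` as an extra child
            keep.add_child(merge)
            keep.length = 0.0
            keep.support = None
            t.root = keep
            t.rooted = False
        return t

    def copy(self) -> "PhyloTree":
        def _clone(node: Node) -> Node:
            c = Node(node.name, node.length, node.support)
            for ch in node.children:
                c.add_child(_clone(ch))
            return c

        return PhyloTree(_clone(self.root), rooted=self.rooted)

    def scale_branches(self, factor: float) -> None:
        for node in self.preorder():
            node.length *= factor

    # -- measures ----------------------------------------------------------
    def total_length(self) -> float:
        return sum(n.length for n in self.preorder() if n.parent is not None)

    def node_depths(self) -> dict[Node, float]:
        depths: dict[Node, float] = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                depths[node] = depths[node.parent] + node.length
        return depths

    def height(self) -> float:
        """Maximum root-to-leaf path length."""
        depths = self.node_depths()
        return max(depths[leaf] for leaf in self.leaves())

    def terminal_branch_lengths(self) -> dict[str, float]:
        return {n.name: n.length for n in self.leaves()}

    # -- bipartitions ------------------------------------------------------
    def leafsets(self) -> dict[Node, frozenset]:
        """Leaf-name set below each node (rooted view)."""
        sets: dict[Node, frozenset] = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[node] = frozenset([node.name])
            else:
                s: set = set()
                for ch in node.children:
                    s |= sets[ch]
                sets[node] = frozenset(s)
        return sets

    def bipartitions(self, with_support: bool = False):
        """Non-trivial bipartitions as canonical frozensets.

        Canonical form: the side NOT containing the lexicographically
        smallest leaf.  Returns a set, or a dict ``{bipart: support}``
        when *with_support* is set (duplicate edges around a bifurcating
        root collapse to one entry, keeping the defined support).
        """
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        sets = self.leafsets()
        out: dict[frozenset, Optional[float]] = {}
        for node, below in sets.items():
            if node is self.root or node.is_leaf:
                continue
            side = below if ref not in below else all_leaves - below
            if len(side) < 2 or len(all_leaves - side) < 2:
                continue
            if side not in out or out[side] is None:
                out[side] = node.support
        return out if with_support else set(out)

    def robinson_foulds(self, other: "PhyloTree") -> int:
        """Unweighted RF distance (symmetric difference of bipartitions).

        Requires identical leaf sets.
        """
        if set(self.leaf_names()) != set(other.leaf_names()):
            raise ValueError("leaf sets differ")
        return len(self.bipartitions() ^ other.bipartitions())

    # -- distances ---------------------------------------------------------
    def adjacency(self):
        """Undirected adjacency: node -> list of (neighbor, branch length)."""
        adj: dict[Node, list[tuple[Node, float]]] = {n: [] for n in self.preorder()}
        for node in self.preorder():
            if node.parent is not None:
                adj[node].append((node.parent, node.length))
                adj[node.parent].append((node, node.length))
        return adj

    def distance_matrix(
        self, labels: Optional[list[str]] = None, topological: bool = False
    ) -> tuple[np.ndarray, list[str]]:
        """All-pairs leaf path distances (patristic, or edge counts)."""
        leaves = self.leaves()
        if labels is None:
            labels = [n.name for n in leaves]
        by_name = {n.name: n for n in leaves}
        adj = self.adjacency()
        n = len(labels)
        D = np.zeros((n, n))
        for i, name in enumerate(labels):
            start = by_name[name]
            dist: dict[Node, float] = {start: 0.0}
            q = deque([start])
            while q:
                u = q.popleft()
                for v, w in adj[u]:
                    if v not in dist:
                        dist[v] = dist[u] + (1.0 if topological else w)
                        q.append(v)
            for j, other_name in enumerate(labels):
                D[i, j] = dist[by_name[other_name]]
        return D, labels

    # -- serialization -----------------------------------------------------
    def to_newick(self, support_as_label: bool = True, precision: int = 10) -> str:
        def fmt_len(x: float) -> str:
            return f"{x:.{precision}g}"

        def _write(node: Node, at_root: bool) -> str:
            if node.is_leaf:
                s = node.name or ""
            else:
                inner = ",".join(_write(ch, False) for ch in node.children)
                label = ""
                if (
                    support_as_label
                    and node.support is not None
                    and not at_root
                ):
                    label = fmt_len(node.support)
                elif node.name:
                    label = node.name
                s = f"({inner}){label}"
            if not at_root:
                s += f":{fmt_len(node.length)}"
            return s

        return _write(self.root, True) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree({self.n_leaves()} leaves, rooted={self.rooted})"
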