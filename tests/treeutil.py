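"""Toy unrooted trees with an independent brute-force ancestry oracle.

Trees are held as a plain adjacency map with per-edge supports, so they
can be serialised to Newick rooted at any internal node (the same
unrooted tree, different rootings) and classified by exhaustive edge
removal + set comparison — a path entirely separate from the package's
dendropy-based implementation.
"""

from __future__ import annotations

import numpy as np


class ToyTree:
    """Unrooted binary tree: leaves are labelled strings, internal nodes
    integers; ``adj[u][v]`` is the support of edge (u, v) (None on
    terminal edges)."""

    def __init__(self):
        self.adj: dict[object, dict[object, int | None]] = {}

    def add_edge(self, u, v, support=None):
        self.adj.setdefault(u, {})[v] = support
        self.adj.setdefault(v, {})[u] = support

    def remove_edge(self, u, v):
        del self.adj[u][v]
        del self.adj[v][u]

    @property
    def leaves(self) -> list[str]:
        return sorted(n for n in self.adj if isinstance(n, str))

    @property
    def internal(self) -> list[int]:
        return sorted(n for n in self.adj if not isinstance(n, str))

    def side_leaves(self, start, blocked) -> frozenset[str]:
        """Leaves reachable from ``start`` without crossing ``blocked``."""
        seen, stack, out = {blocked, start}, [start], set()
        while stack:
            n = stack.pop()
            if isinstance(n, str):
                out.add(n)
            for m in self.adj[n]:
                if m not in seen:
                    seen.add(m)
                    stack.append(m)
        return frozenset(out)


def random_toy_tree(rng: np.random.Generator, labels: list[str]) -> ToyTree:
    """Random unrooted binary tree over the given leaf labels (>= 3),
    grown by repeatedly splitting a random edge; internal edges get
    integer supports in [0, 100]."""
    t = ToyTree()
    nxt = [0]

    def new_internal():
        nxt[0] += 1
        return nxt[0]

    c = new_internal()
    for lab in labels[:3]:
        t.add_edge(c, lab)
    for lab in labels[3:]:
        edges = [(u, v) for u in t.adj for v in t.adj[u] if str(u) < str(v)]
        u, v = edges[int(rng.integers(len(edges)))]
        sup = t.adj[u][v]
        t.remove_edge(u, v)
        m = new_internal()
        t.add_edge(u, m, sup)
        t.add_edge(m, v)
        t.add_edge(m, lab)
    for u in t.internal:
        for v in t.adj[u]:
            if not isinstance(v, str) and u < v:
                s = int(rng.integers(0, 101))
                t.adj[u][v] = s
                t.adj[v][u] = s
    return t


def toy_newick(tree: ToyTree, root: int | None = None) -> str:
    """Newick string rooted at ``root`` (an internal node; default the
    smallest); supports written as internal-node labels."""
    if root is None:
        root = tree.internal[0]

    def render(node, parent) -> str:
        if isinstance(node, str):
            return node
        parts = [render(ch, node) for ch in sorted(tree.adj[node], key=str)
                 if ch != parent]
        sup = tree.adj[node].get(parent)
        label = "" if parent is None or sup is None else str(sup)
        return "(" + ",".join(parts) + ")" + label

    return render(root, None) + ";"


def oracle_classify(tree: ToyTree, taxmap, support_min: float) -> set[str]:
    """Brute-force bins: remove every internal edge, split the leaves by
    traversal, and test the clan-composition rule by set comparison."""
    focal = {l for l in tree.leaves if l.split("_")[0] == taxmap.focal_taxon}
    bins: set[str] = set()
    for u in tree.internal:
        for v in tree.adj[u]:
            if isinstance(v, str) or u > v:
                continue
            sup = tree.adj[u][v]
            if sup is None or sup < support_min:
                continue
            for side in (tree.side_leaves(u, v), tree.side_leaves(v, u)):
                if not side & focal:
                    continue
                rest = side - focal
                if not rest:
                    continue
                groups = {taxmap.group_of(l.split("_")[0]) for l in rest}
                if None not in groups and len(groups) == 1:
                    bins.add(next(iter(groups)))
    return bins
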