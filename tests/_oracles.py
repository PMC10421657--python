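"""Independent brute-force oracles used to validate the implementations.

Each oracle takes a deliberately different route from the library code:
path-climbing instead of postorder accumulation, exhaustive recursion
instead of dynamic programming, etc.
"""

from __future__ import annotations

import numpy as np

from ighrep.tree import PhyloTree, TreeNode


# --- random trees ----------------------------------------------------------

def random_tree(rng: np.random.Generator, n_leaves: int) -> PhyloTree:
    """Random rooted binary-ish topology with uniform branch lengths."""
    nodes = [TreeNode(name=f"L{i}", length=float(rng.uniform(0.1, 2.0))) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = TreeNode(length=float(rng.uniform(0.1, 2.0)))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)] + [parent]
    root = nodes[0]
    root.length = 0.0
    return PhyloTree(root)


def _paths_to_root(tree: PhyloTree) -> dict:
    """leaf name -> list of edge-carrying nodes from the leaf up to the root."""
    out = {}
    for leaf in tree.leaves():
        path = []
        node = leaf
        while node is not tree.root:
            path.append(node)
            node = node.parent
        out[leaf.name] = path
    return out


def brute_faith_pd(tree: PhyloTree, observed) -> float:
    """Union of root-to-leaf edge sets over the observed leaves."""
    paths = _paths_to_root(tree)
    edges = set()
    for name in observed:
        edges.update(id(n) for n in paths[name])
    lengths = {id(n): n.length for n in tree.preorder()}
    return sum(lengths[e] for e in edges)


def brute_weighted_unifrac(tree: PhyloTree, abund_a: dict, abund_b: dict) -> float:
    """Branch-wise enumeration with descendant sets built from leaf paths."""
    paths = _paths_to_root(tree)
    branches = [n for n in tree.preorder() if n is not tree.root]
    numerator = 0.0
    for br in branches:
        below_a = sum(v for leaf, v in abund_a.items() if br in paths[leaf])
        below_b = sum(v for leaf, v in abund_b.items() if br in paths[leaf])
        numerator += br.length * abs(below_a - below_b)
    scale = 0.0
    for leaf, path in paths.items():
        depth = sum(n.length for n in path)
        scale += depth * (abund_a.get(leaf, 0.0) + abund_b.get(leaf, 0.0))
    return numerator / scale if scale else 0.0


# --- edit distance ---------------------------------------------------------

def brute_edit_distance(a: str, b: str) -> int:
    """Exhaustive recursion over the three edit moves (memoized)."""
    seen = {}

    def rec(x: str, y: str) -> int:
        if not x:
            return len(y)
        if not y:
            return len(x)
        key = (x, y)
        if key not in seen:
            seen[key] = min(
                rec(x[1:], y[1:]) + (x[0] != y[0]),
                rec(x[1:], y) + 1,
                rec(x, y[1:]) + 1,
            )
        return seen[key]

    return rec(a, b)


# --- misc ------------------------------------------------------------------

def brute_ks_statistic(x, y) -> float:
    """Maximum ECDF gap scanned over all observed values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    best = 0.0
    for v in np.concatenate([x, y]):
        gap = abs((x <= v).mean() - (y <= v).mean())
        best = max(best, gap)
    return best
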