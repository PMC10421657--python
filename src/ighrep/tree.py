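"""Rooted phylogenetic trees with branch lengths over clonotype leaves.

A minimal tree substrate for Faith's PD and weighted UniFrac: rooted,
every edge carries a non-negative length, leaf labels unique. Newick text
is parsed with dendropy; serialization, traversal and midpoint rooting are
implemented here.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional

import dendropy


class TreeError(ValueError):
    pass


class TreeNode:
    __slots__ = ("name", "length", "children", "parent")

    def __init__(self, name: Optional[str] = None, length: float = 0.0):
        self.name = name
        self.length = float(length)  # length of the edge to the parent
        self.children: List["TreeNode"] = []
        self.parent: Optional["TreeNode"] = None

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, {self.length})"


class PhyloTree:
    """A rooted tree; the root's ``length`` is ignored throughout."""

    def __init__(self, root: TreeNode):
        self.root = root
        names = [leaf.name for leaf in self.leaves()]
        if any(n is None for n in names):
            raise TreeError("every leaf must be labeled")
        if len(set(names)) != len(names):
            raise TreeError("leaf labels must be unique")
        for node in self.preorder():
            if node is not self.root and node.length < 0:
                raise TreeError(f"negative branch length on {node.name!r}")

    # -- traversal ----------------------------------------------------
    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> List[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_names(self) -> List[str]:
        return [n.name for n in self.leaves()]

    @property
    def total_branch_length(self) -> float:
        return sum(n.length for n in self.preorder() if n is not self.root)

    def leaf_depths(self) -> Dict[str, float]:
        """Root-to-leaf path lengths."""
        depth = {id(self.root): 0.0}
        out = {}
        for node in self.preorder():
            if node is not self.root:
                depth[id(node)] = depth[id(node.parent)] + node.length
            if node.is_leaf:
                out[node.name] = depth[id(node)]
        return out

    def leaf_distances(self) -> Dict[tuple, float]:
        """All pairwise leaf-to-leaf path lengths (small trees only)."""
        depths = {}
        paths: Dict[str, list] = {}
        for leaf in self.leaves():
            path = []
            node = leaf
            while node is not None:
                path.append(id(node))
                node = node.parent
            paths[leaf.name] = path
        lengths = {id(n): n.length for n in self.preorder()}
        out = {}
        names = list(paths)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                pa, pb = set(paths[a]), set(paths[b])
                d = sum(lengths[x] for x in pa ^ pb)
                out[(a, b)] = out[(b, a)] = d
        return out

    # -- newick -------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.12g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = node.name or ""
            if node is self.root:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.12g}"

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        dtree = dendropy.Tree.get(data=text, schema="newick")

        def convert(dnode) -> TreeNode:
            name = dnode.taxon.label if dnode.taxon else dnode.label
            node = TreeNode(name=name, length=dnode.edge.length or 0.0)
            for child in dnode.child_nodes():
                node.add_child(convert(child))
            return node

        return cls(convert(dtree.seed_node))

    def copy(self) -> "PhyloTree":
        return PhyloTree.from_newick(self.to_newick())


def midpoint_root(unrooted_edges: List[tuple], leaf_names: List[str]) -> PhyloTree:
    """Root an unrooted tree at the midpoint of the longest leaf-leaf path.

    ``unrooted_edges`` is a list of ``(u, v, length)`` over hashable node
    ids; leaves are the ids appearing in ``leaf_names``. If the midpoint
    falls inside an edge a new root node splits it; if it lands exactly on
    a node that node becomes the root.
    """
    adj: Dict[object, list] = {}
    for u, v, w in unrooted_edges:
        adj.setdefault(u, []).append((v, w))
        adj.setdefault(v, []).append((u, w))

    def farthest(start):
        dist = {start: 0.0}
        prev = {start: None}
        stack = [start]
        while stack:
            node = stack.pop()
            for nxt, w in adj[node]:
                if nxt not in dist:
                    dist[nxt] = dist[node] + w
                    prev[nxt] = node
                    stack.append(nxt)
        # farthest leaf, deterministic tie-break by label string
        best = max(
            (n for n in dist if n in leaf_set),
            key=lambda n: (dist[n], str(n)),
        )
        return best, dist, prev

    leaf_set = set(leaf_names)
    a, _, _ = farthest(min(leaf_set, key=str))
    b, dist_a, prev_a = farthest(a)
    diameter = dist_a[b]

    # walk back from b toward a to find where the midpoint lies
    path = [b]
    while prev_a[path[-1]] is not None:
        path.append(prev_a[path[-1]])
    # path runs b -> ... -> a; distances measured from a
    target = diameter / 2.0
    root_at_node = None
    split_edge = None
    for i in range(len(path) - 1):
        lo_node, hi_node = path[i + 1], path[i]  # lo closer to a
        lo, hi = dist_a[lo_node], dist_a[hi_node]
        if abs(lo - target) < 1e-12:
            root_at_node = lo_node
            break
        if lo < target < hi:
            split_edge = (lo_node, hi_node, target - lo)
            break
    else:
        root_at_node = a

    def build(node, blocked, length) -> TreeNode:
        t = TreeNode(name=node if node in leaf_set else None, length=length)
        for nxt, w in adj[node]:
            if nxt != blocked:
                t.add_child(build(nxt, node, w))
        return t

    if root_at_node is not None:
        root = build(root_at_node, None, 0.0)
        # guard: a leaf as root would be degenerate; push root to its neighbor
        if root.is_leaf and adj[root_at_node]:
            nxt, w = adj[root_at_node][0]
            root = TreeNode()
            root.add_child(build(root_at_node, nxt, w / 2.0))
            root.add_child(build(nxt, root_at_node, w / 2.0))
    else:
        lo_node, hi_node, offset = split_edge
        total = dict(
            (frozenset((u, v)), w) for u, v, w in unrooted_edges
        )[frozenset((lo_node, hi_node))]
        root = TreeNode()
        root.add_child(build(lo_node, hi_node, offset))
        root.add_child(build(hi_node, lo_node, total - offset))
    return PhyloTree(root)
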