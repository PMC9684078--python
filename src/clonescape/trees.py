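"""Rooted clone trees with region-labelled tips and per-edge mutation sets.

The tree container used across the package: a rooted tree whose tips are
sequenced samples (or simulated glands), whose edge lengths count somatic
mutations acquired on that edge, and whose edges optionally carry the set of
mutation identifiers uniquely acquired there (``muts``).  Newick round-trips
go through :mod:`dendropy`; region labels and mutation sets are carried in
tip/edge annotations.
"""

from __future__ import annotations

import itertools
from typing import Iterator, Optional

import dendropy
import numpy as np

__all__ = ["CloneNode", "CloneTree"]


class CloneNode:
    """A node of a :class:`CloneTree`.

    Attributes
    ----------
    name : str or None
        Tip name (sample/gland id); internal nodes may be unnamed.
    length : float
        Length of the edge above this node (mutation count); 0 for the root.
    label : str or None
        Region label for tips.
    muts : set or None
        Mutation ids uniquely acquired on the edge above this node.
    """

    __slots__ = ("name", "length", "label", "muts", "children", "parent")

    def __init__(self, name=None, length=0.0, label=None, muts=None):
        self.name = name
        self.length = float(length)
        self.label = label
        self.muts = muts
        self.children: list[CloneNode] = []
        self.parent: Optional[CloneNode] = None

    def add_child(self, child: "CloneNode") -> "CloneNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_tip(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = "tip" if self.is_tip else "internal"
        return f"<CloneNode {kind} name={self.name!r} length={self.length}>"


class CloneTree:
    """Rooted tree over samples with mutation-count edge lengths."""

    def __init__(self, root: CloneNode):
        self.root = root

    # ------------------------------------------------------------------ #
    # traversal
    # ------------------------------------------------------------------ #
    def preorder(self) -> Iterator[CloneNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[CloneNode]:
        out = list(self.preorder())
        return iter(reversed(out))

    def tips(self) -> list[CloneNode]:
        return [n for n in self.preorder() if n.is_tip]

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def edges(self) -> list[CloneNode]:
        """Edges as their child nodes (every node except the root)."""
        return [n for n in self.preorder() if n.parent is not None]

    def find(self, name: str) -> CloneNode:
        for n in self.preorder():
            if n.name == name:
                return n
        raise KeyError(name)

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tips())

    def total_length(self) -> float:
        return sum(e.length for e in self.edges())

    # ------------------------------------------------------------------ #
    # manipulation
    # ------------------------------------------------------------------ #
    def copy(self) -> "CloneTree":
        def clone(node):
            new = CloneNode(node.name, node.length, node.label,
                            None if node.muts is None else set(node.muts))
            for c in node.children:
                new.add_child(clone(c))
            return new

        return CloneTree(clone(self.root))

    def drop_tips(self, names) -> "CloneTree":
        """Return a copy with the named tips removed and unary nodes collapsed."""
        names = set(names)
        tree = self.copy()
        changed = True
        while changed:
            changed = False
            for node in list(tree.preorder()):
                if node.is_tip and node.name in names and node.parent is not None:
                    node.parent.children.remove(node)
                    changed = True
        tree.suppress_unifurcations()
        return tree

    def reroot_above(self, edge_child: CloneNode) -> None:
        """Re-root the tree on the edge above ``edge_child`` (in place).

        A fresh root is created on that edge (the germline attachment
        point); parent-child links above are reversed, edge lengths
        staying on their edges.  The old root is suppressed if it becomes
        unary.
        """
        if edge_child.parent is None:
            return
        chain = []
        cur = edge_child
        while cur.parent is not None:
            chain.append(cur.parent)
            cur = cur.parent
        lengths = [n.length for n in chain]
        muts = [n.muts for n in chain]
        old_parent = edge_child.parent
        old_parent.children.remove(edge_child)
        edge_child.parent = None
        for i in range(len(chain) - 1):
            chain[i + 1].children.remove(chain[i])
            chain[i].parent = None
        for i in range(len(chain) - 1):
            chain[i].add_child(chain[i + 1])
            chain[i + 1].length = lengths[i]
            chain[i + 1].muts = muts[i]
        old_parent.length = 0.0
        old_parent.muts = None
        new_root = CloneNode()
        new_root.add_child(edge_child)
        new_root.add_child(old_parent)
        self.root = new_root
        # the old root may end up childless and unnamed after the flip
        changed = True
        while changed:
            changed = False
            for node in list(self.preorder()):
                if not node.children and node.name is None and \
                        node.parent is not None:
                    node.parent.children.remove(node)
                    changed = True
        self.suppress_unifurcations()

    def suppress_unifurcations(self) -> None:
        """Collapse unary internal nodes, summing edge lengths and mutation sets."""
        changed = True
        while changed:
            changed = False
            for node in list(self.preorder()):
                if node.is_tip or node.parent is None:
                    continue
                if len(node.children) == 1:
                    child = node.children[0]
                    child.length += node.length
                    if child.muts is not None and node.muts is not None:
                        child.muts = set(child.muts) | set(node.muts)
                    parent = node.parent
                    idx = parent.children.index(node)
                    child.parent = parent
                    parent.children[idx] = child
                    changed = True
        # a unary root is kept: it represents the germline/founder

    # ------------------------------------------------------------------ #
    # metrics
    # ------------------------------------------------------------------ #
    def depths(self) -> dict[CloneNode, float]:
        """Root-to-node path lengths."""
        out = {self.root: 0.0}
        for node in self.preorder():
            if node.parent is not None:
                out[node] = out[node.parent] + node.length
        return out

    def tip_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        """Patristic (path-length) distances between tips."""
        tips = self.tips()
        names = [t.name for t in tips]
        depth = self.depths()
        # shared path length = depth of MRCA
        anc: dict[CloneNode, list[CloneNode]] = {}
        for t in tips:
            path = []
            node = t
            while node is not None:
                path.append(node)
                node = node.parent
            anc[t] = path
        index = {t: set(anc[t]) for t in tips}
        k = len(tips)
        d = np.zeros((k, k))
        for i, j in itertools.combinations(range(k), 2):
            shared = index[tips[i]] & index[tips[j]]
            mrca_depth = max(depth[n] for n in shared)
            d[i, j] = d[j, i] = depth[tips[i]] + depth[tips[j]] - 2 * mrca_depth
        return names, d

    def vcv(self) -> tuple[list[str], np.ndarray]:
        """Phylogenetic covariance: C[i, j] = shared root-to-MRCA path length.

        Filled in one postorder sweep: tip pairs split across different
        child subtrees of a node have that node as their MRCA.
        """
        tips = self.tips()
        names = [t.name for t in tips]
        index = {t: i for i, t in enumerate(tips)}
        depth = self.depths()
        k = len(tips)
        c = np.zeros((k, k))
        below: dict[CloneNode, list[int]] = {}
        for node in self.postorder():
            if node.is_tip:
                i = index[node]
                c[i, i] = depth[node]
                below[node] = [i]
            else:
                groups = [below[ch] for ch in node.children]
                d = depth[node]
                for a in range(len(groups)):
                    for b in range(a + 1, len(groups)):
                        c[np.ix_(groups[a], groups[b])] = d
                        c[np.ix_(groups[b], groups[a])] = d
                below[node] = [i for g in groups for i in g]
        return names, c

    # ------------------------------------------------------------------ #
    # I/O
    # ------------------------------------------------------------------ #
    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)

        def build(node, dnode):
            dnode.edge.length = node.length
            if node.is_tip:
                dnode.taxon = taxa.new_taxon(str(node.name))
                if node.label is not None:
                    dnode.taxon.annotations.add_new("region", node.label)
            else:
                if node.name is not None:
                    dnode.label = str(node.name)
                for c in node.children:
                    build(c, dnode.new_child())

        build(self.root, dtree.seed_node)
        return dtree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree,
                      labels: Optional[dict[str, str]] = None) -> "CloneTree":
        def build(dnode):
            name = dnode.taxon.label if dnode.taxon is not None else dnode.label
            node = CloneNode(name=name,
                             length=dnode.edge.length or 0.0)
            if labels and name in labels:
                node.label = labels[name]
            for dc in dnode.child_nodes():
                node.add_child(build(dc))
            return node

        return cls(build(dtree.seed_node))

    @classmethod
    def from_newick(cls, newick: str,
                    labels: Optional[dict[str, str]] = None) -> "CloneTree":
        dtree = dendropy.Tree.get(data=newick, schema="newick")
        return cls.from_dendropy(dtree, labels=labels)

    def __repr__(self):  # pragma: no cover
        return f"<CloneTree with {self.n_tips} tips, total length {self.total_length():g}>"
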