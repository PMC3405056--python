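"""Minimal phylogenetic tree container with Newick round-tripping.

Trees are stored rooted; an unrooted binary tree is represented with a
trifurcating root.  Branch lengths are expected substitutions per site.
Newick parsing is delegated to dendropy; writing is direct.
"""

from __future__ import annotations

from typing import Iterator

import dendropy


class TreeError(ValueError):
    """Raised for malformed trees or tip-set mismatches."""


class Node:
    __slots__ = ("name", "length", "children", "parent", "support")

    def __init__(self, name: str | None = None, length: float = 0.0):
        self.name = name
        self.length = float(length)
        self.children: list["Node"] = []
        self.parent: "Node" | None = None
        self.support: float | None = None

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["Node"]:
        for child in self.children:
            yield from child.postorder()
        yield self

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, n_children={len(self.children)})"


class PhyloTree:
    """A rooted (possibly trifurcating-root) phylogeny with named tips."""

    def __init__(self, root: Node):
        self.root = root
        names = self.tip_names()
        if len(names) != len(set(names)):
            raise TreeError("duplicate tip labels")
        for node in self.postorder():
            if not (node.length >= 0.0 and node.length < float("inf")):
                raise TreeError(f"invalid branch length on {node.name!r}")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "PhyloTree":
        try:
            dtree = dendropy.Tree.get(data=newick, schema="newick",
                                      preserve_underscores=True)
        except Exception as exc:  # dendropy parse errors become TreeError
            raise TreeError(f"invalid newick: {exc}") from exc
        return cls(_from_dendropy(dtree.seed_node))

    @classmethod
    def read(cls, path) -> "PhyloTree":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    # -- traversal ---------------------------------------------------------
    def postorder(self) -> Iterator[Node]:
        return self.root.postorder()

    def tips(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def tip_names(self) -> list[str]:
        return [n.name for n in self.tips()]

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def find(self, name: str) -> Node:
        for node in self.postorder():
            if node.name == name:
                return node
        raise TreeError(f"no node named {name!r}")

    # -- editing -----------------------------------------------------------
    def copy(self) -> "PhyloTree":
        def clone(node: Node) -> Node:
            new = Node(node.name, node.length)
            new.support = node.support
            for child in node.children:
                new.add_child(clone(child))
            return new

        return PhyloTree(clone(self.root))

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.parent is not None)

    def branches(self) -> list[Node]:
        """All nodes carrying a branch (everything except the root)."""
        return [n for n in self.postorder() if n.parent is not None]

    def reroot_at(self, name: str) -> "PhyloTree":
        """Reroot on the branch leading to tip ``name`` (pulley move).

        The tip's branch is split in half; under a reversible model the
        likelihood is invariant to this operation.
        """
        tree = self.copy()
        tip = tree.find(name)
        if tip.parent is None:
            return tree
        half = tip.length / 2.0
        new_root = Node(None, 0.0)
        node = tip.parent
        node.children.remove(tip)
        tip.parent = None
        tip.length = half
        new_root.add_child(tip)
        # walk from the tip's old parent up to the old root, re-hanging each
        # node from its former child; each reversed edge keeps its length
        prev, carry = new_root, half
        while node is not None:
            parent = node.parent
            if parent is not None:
                parent.children.remove(node)
            node.parent = None
            next_carry = node.length
            node.length = carry
            prev.add_child(node)
            prev, carry, node = node, next_carry, parent
        _suppress_unifurcations(new_root)
        return PhyloTree(new_root)

    # -- output ------------------------------------------------------------
    def to_newick(self, include_support: bool = False) -> str:
        def fmt(node: Node) -> str:
            if node.is_leaf:
                return f"{node.name}:{node.length:.10g}"
            inner = ",".join(fmt(c) for c in node.children)
            label = ""
            if include_support and node.support is not None:
                label = f"{node.support:g}"
            if node.parent is None:
                return f"({inner}){label}"
            return f"({inner}){label}:{node.length:.10g}"

        return fmt(self.root) + ";"

    def write(self, path, include_support: bool = False) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick(include_support=include_support) + "\n")

    def __repr__(self) -> str:  # pragma: no cover
        return f"PhyloTree(n_tips={self.n_tips})"


def _from_dendropy(seed) -> Node:
    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label, dnode.edge.length or 0.0)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return convert(seed)


def _suppress_unifurcations(root: Node) -> None:
    """Collapse internal nodes with a single child (in place), merging lengths."""
    changed = True
    while changed:
        changed = False
        for node in list(root.postorder()):
            if node.parent is not None and not node.is_leaf and len(node.children) == 1:
                child = node.children[0]
                child.length += node.length
                parent = node.parent
                idx = parent.children.index(node)
                parent.children[idx] = child
                child.parent = parent
                changed = True


def bipartitions(tree: PhyloTree) -> set[frozenset]:
    """Non-trivial tip bipartitions of a tree, as canonical frozensets.

    Each internal edge splits the tips in two; the split is represented by the
    side NOT containing the lexicographically smallest tip name, so the
    representation is invariant to rooting and tip order.  Trivial splits
    (single tip or all-but-one) are excluded.
    """
    all_tips = frozenset(tree.tip_names())
    anchor = min(all_tips)
    splits: set[frozenset] = set()
    below: dict[int, frozenset] = {}
    for node in tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(*(below[id(c)] for c in node.children))
        if node.parent is None:
            continue
        side = below[id(node)]
        if anchor in side:
            side = all_tips - side
        if 1 < len(side) < len(all_tips) - 1:
            splits.add(side)
    return splits


def robinson_foulds(a: PhyloTree, b: PhyloTree) -> int:
    """Unweighted Robinson–Foulds distance (symmetric difference of splits)."""
    if set(a.tip_names()) != set(b.tip_names()):
        raise TreeError("trees have different tip sets")
    return len(bipartitions(a) ^ bipartitions(b))
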