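"""Rooted, time-calibrated trees with node ages in years BP.

The container is deliberately small: trees in this package have a handful of
tips (one per language), so clarity beats asymptotics.  Ages increase
root-ward; tips carry their sampling date (0 for extant languages).
"""

from __future__ import annotations

import io
from typing import Iterator

import dendropy


class TreeNode:
    __slots__ = ("name", "age", "children", "parent", "rate")

    def __init__(self, name: str | None = None, age: float = 0.0):
        self.name = name
        self.age = float(age)
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.rate: float = 1.0  # branch-rate multiplier of the edge above

    def add_child(self, child: "TreeNode") -> None:
        child.parent = self
        self.children.append(child)

    def is_tip(self) -> bool:
        return not self.children


class DatedTree:
    """A rooted binary tree whose node ages are years before present."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._validate()

    # -- structure -----------------------------------------------------------

    def _validate(self) -> None:
        for node in self.postorder():
            for child in node.children:
                if child.age >= node.age and not (child.age == node.age == 0.0):
                    raise ValueError(
                        f"node age must exceed child age (parent {node.age}, "
                        f"child {child.age})"
                    )
            if node.children and len(node.children) != 2:
                raise ValueError("tree must be binary")

    def postorder(self) -> Iterator[TreeNode]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_tip()]

    def internals(self) -> list[TreeNode]:
        return [n for n in self.postorder() if not n.is_tip()]

    def branches(self) -> list[tuple[TreeNode, TreeNode]]:
        """(parent, child) pairs; durations are parent.age - child.age years."""
        return [(n, c) for n in self.postorder() for c in n.children]

    def tip_names(self) -> list[str]:
        return [t.name for t in self.tips()]

    def tip_ages(self) -> dict[str, float]:
        return {t.name: t.age for t in self.tips()}

    @property
    def n_tips(self) -> int:
        return len(self.tips())

    def height(self) -> float:
        return self.root.age

    def total_branch_time(self) -> float:
        return sum(p.age - c.age for p, c in self.branches())

    # -- queries -------------------------------------------------------------

    def find_tip(self, name: str) -> TreeNode:
        for t in self.tips():
            if t.name == name:
                return t
        raise KeyError(name)

    def mrca(self, names: list[str]) -> TreeNode:
        paths = []
        for name in names:
            node, path = self.find_tip(name), []
            while node is not None:
                path.append(node)
                node = node.parent
            paths.append(path[::-1])
        mrca = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return mrca

    def clade_tips(self, node: TreeNode) -> frozenset[str]:
        stack, out = [node], []
        while stack:
            n = stack.pop()
            if n.is_tip():
                out.append(n.name)
            stack.extend(n.children)
        return frozenset(out)

    def clades(self) -> set[frozenset[str]]:
        """Tip sets of all internal nodes (including the root)."""
        return {self.clade_tips(n) for n in self.internals()}

    # -- copying / serialization --------------------------------------------

    def copy(self) -> "DatedTree":
        def rec(node: TreeNode) -> TreeNode:
            clone = TreeNode(node.name, node.age)
            clone.rate = node.rate
            for c in node.children:
                clone.add_child(rec(c))
            return clone

        return DatedTree(rec(self.root))

    def newick(self, precision: int = 6) -> str:
        def rec(node: TreeNode) -> str:
            if node.is_tip():
                label = node.name
            else:
                label = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.parent is None:
                return label
            length = node.parent.age - node.age
            return f"{label}:{length:.{precision}f}"

        return rec(self.root) + ";"


def parse_newick(text: str, tip_ages: dict[str, float] | None = None) -> DatedTree:
    """Parse a Newick string into a DatedTree.

    Node ages are reconstructed from branch lengths; the deepest tip is
    anchored at the youngest supplied tip age (default 0 BP).
    """
    dtree = dendropy.Tree.get(file=io.StringIO(text), schema="newick")

    def rec(dnode) -> TreeNode:
        node = TreeNode(name=dnode.taxon.label if dnode.taxon else None)
        for dchild in dnode.child_nodes():
            child = rec(dchild)
            child.age = -(dchild.edge.length or 0.0)  # placeholder: depth delta
            node.add_child(child)
        return node

    root = rec(dtree.seed_node)

    # Convert edge lengths (stored as negative deltas on child.age) to depths.
    def set_depth(node: TreeNode, depth: float) -> None:
        edge = -node.age if node.parent is not None else 0.0
        node.age = depth + edge  # temporarily store depth from root
        for c in node.children:
            set_depth(c, node.age)

    set_depth(root, 0.0)
    max_depth = max(n.age for n in _iter_nodes(root))
    offset = 0.0
    for n in _iter_nodes(root):
        n.age = max_depth - n.age  # age above the deepest tip
    if tip_ages:
        # anchor: shift so that named tips match their given ages
        tips = {n.name: n for n in _iter_nodes(root) if n.is_tip()}
        name, want = next(iter(tip_ages.items()))
        offset = want - tips[name].age
        for n in _iter_nodes(root):
            n.age += offset
    for n in _iter_nodes(root):
        if n.is_tip() and abs(n.age) < 1e-9:
            n.age = 0.0
    return DatedTree(root)


def _iter_nodes(root: TreeNode) -> Iterator[TreeNode]:
    stack = [root]
    while stack:
        n = stack.pop()
        yield n
        stack.extend(n.children)
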