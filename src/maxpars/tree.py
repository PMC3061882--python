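"""Rooted phylogenetic trees with polytomies.

The package's tree is a deliberately small structure: labelled leaves,
unlabelled internal nodes with any number (>= 2) of children, an optional
age (Ma, larger = older) per node, and no branch lengths.  Parsimony and
stratigraphic calculations only ever need the topology and the leaf labels,
so equality between trees is defined on clade / bipartition sets rather
than on child order.

Newick interchange is delegated to :mod:`dendropy`.
"""

from __future__ import annotations

from typing import Iterable, Iterator, Optional

import dendropy

__all__ = ["Node", "Tree", "read_tree", "write_tree", "parse_newick"]


class TreeError(ValueError):
    """Raised for structurally invalid trees or tree files."""


class Node:
    __slots__ = ("label", "children", "parent", "age")

    def __init__(self, label: Optional[str] = None, age: Optional[float] = None):
        self.label = label
        self.children: list["Node"] = []
        self.parent: Optional["Node"] = None
        self.age = age

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Node {self.label or '*'} children={len(self.children)}>"


class Tree:
    """A rooted tree over uniquely labelled leaves."""

    def __init__(self, root: Node):
        self.root = root
        labels = [leaf.label for leaf in self.leaves()]
        if any(lab is None for lab in labels):
            raise TreeError("every leaf must carry a label")
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str, taxa: Optional[Iterable[str]] = None) -> "Tree":
        return parse_newick(newick, taxa=taxa)

    # -- traversal ---------------------------------------------------------

    def postorder(self) -> Iterator[Node]:
        stack, out = [self.root], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def internal_nodes(self, include_root: bool = True) -> list[Node]:
        nodes = [n for n in self.postorder() if not n.is_leaf]
        if not include_root:
            nodes = [n for n in nodes if n is not self.root]
        return nodes

    def n_leaves(self) -> int:
        return len(self.leaves())

    # -- identity ----------------------------------------------------------

    def clades(self, trivial: bool = False) -> set[frozenset[str]]:
        """Leaf-label sets of internal nodes (rooted clades).

        The root clade and single-leaf clades are omitted unless
        ``trivial=True``.
        """
        out: set[frozenset[str]] = set()
        below: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.label])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
                if trivial or node is not self.root:
                    out.add(below[node])
        if trivial:
            out.update(frozenset([lab]) for lab in self.leaf_labels())
        return out

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial splits of the unrooted shape.

        Each split is represented by the side that excludes the
        alphabetically first leaf, making the set rooting-invariant.
        """
        labels = set(self.leaf_labels())
        anchor = min(labels)
        out = set()
        for clade in self.clades():
            side = clade if anchor not in clade else labels - clade
            if 1 < len(side) < len(labels) - 1:
                out.add(frozenset(side))
        return out

    def same_topology(self, other: "Tree", rooted: bool = True) -> bool:
        if set(self.leaf_labels()) != set(other.leaf_labels()):
            return False
        if rooted:
            return self.clades() == other.clades()
        return self.bipartitions() == other.bipartitions()

    # -- manipulation ------------------------------------------------------

    def copy(self) -> "Tree":
        def rec(node: Node) -> Node:
            new = Node(node.label, node.age)
            for child in node.children:
                new.add_child(rec(child))
            return new

        return Tree(rec(self.root))

    def find_clade(self, labels: Iterable[str]) -> Optional[Node]:
        """Return the node whose leaf set equals ``labels``, if monophyletic."""
        want = frozenset(labels)
        below: dict[Node, frozenset[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = frozenset([node.label])
            else:
                below[node] = frozenset().union(*(below[c] for c in node.children))
            if below[node] == want:
                return node
        return None

    def suppress_unifurcations(self) -> None:
        changed = True
        while changed:
            changed = False
            for node in list(self.postorder()):
                if not node.is_leaf and len(node.children) == 1:
                    child = node.children[0]
                    if node is self.root:
                        child.parent = None
                        self.root = child
                    else:
                        parent = node.parent
                        idx = parent.children.index(node)
                        parent.children[idx] = child
                        child.parent = parent
                    changed = True
                    break

    # -- serialisation -----------------------------------------------------

    def to_newick(self, ages: bool = False) -> str:
        def rec(node: Node) -> str:
            if node.is_leaf:
                s = _quote(node.label)
            else:
                s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if ages and node.age is not None:
                s += f":{node.age:g}" if node.is_leaf else f"{node.age:g}"
            return s

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<Tree n_leaves={self.n_leaves()}>"


def _quote(label: str) -> str:
    if any(ch in label for ch in " ()[]{}:;,'"):
        return "'" + label.replace("'", "''") + "'"
    return label


# ---------------------------------------------------------------------------
# Newick I/O (dendropy-backed)
# ---------------------------------------------------------------------------


def _from_dendropy(dtree: dendropy.Tree) -> Tree:
    def rec(dnode) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None:
                raise TreeError("unlabelled leaf in Newick input")
            return Node(dnode.taxon.label)
        node = Node()
        for child in dnode.child_nodes():
            node.add_child(rec(child))
        return node

    return Tree(rec(dtree.seed_node))


def parse_newick(newick: str, taxa: Optional[Iterable[str]] = None) -> Tree:
    """Parse a single Newick string into a rooted :class:`Tree`.

    If ``taxa`` is given, leaves must be drawn from that universe.
    """
    try:
        dtree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise TreeError(f"malformed Newick: {exc}") from exc
    tree = _from_dendropy(dtree)
    if taxa is not None:
        universe = set(taxa)
        unknown = set(tree.leaf_labels()) - universe
        if unknown:
            raise TreeError(f"unknown taxa in tree: {sorted(unknown)}")
    tree.suppress_unifurcations()
    return tree


def read_tree(path, taxa: Optional[Iterable[str]] = None) -> Tree:
    """Read the first Newick tree in a file."""
    with open(path) as fh:
        text = fh.read()
    return parse_newick(text, taxa=taxa)


def read_trees(path, taxa: Optional[Iterable[str]] = None) -> list[Tree]:
    """Read one Newick tree per line (blank lines ignored)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                out.append(parse_newick(line, taxa=taxa))
    return out


def write_tree(tree: Tree, path, ages: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick(ages=ages) + "\n")
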