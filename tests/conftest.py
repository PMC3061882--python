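"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the package's own dynamic programmes: tree
lengths are found by enumerating every internal-node state assignment, and
topology-wide extremes by enumerating every rooted binary shape.
"""

from __future__ import annotations

from itertools import product

import pytest

from maxpars.matrix import CharacterMatrix
from maxpars.tree import Node, Tree


# ---------------------------------------------------------------------------
# assignment-enumeration length oracle
# ---------------------------------------------------------------------------


def oracle_character_steps(tree: Tree, matrix: CharacterMatrix, c: int) -> int:
    """Minimum steps of character c by exhaustive internal assignment."""
    ordered = matrix.ordering(c) == "ordered"
    states = sorted(
        {s for row in matrix.cells for s in row[c]}
    ) or [0]
    lo, hi = min(states), max(states)
    domain = list(range(lo, hi + 1)) if ordered else states
    internals = tree.internal_nodes()
    nodes = list(tree.postorder())

    def step(a, b):
        return abs(a - b) if ordered else (0 if a == b else 1)

    best = None
    for assign in product(domain, repeat=len(internals)):
        amap = dict(zip((id(n) for n in internals), assign))
        cost = 0
        for node in nodes:
            if node is tree.root:
                continue
            p = amap[id(node.parent)]
            if node.is_leaf:
                cell = matrix.cell(node.label, c)
                if cell:
                    cost += min(step(s, p) for s in cell)
            else:
                cost += step(amap[id(node)], p)
        best = cost if best is None else min(best, cost)
    return best


def oracle_tree_length(tree: Tree, matrix: CharacterMatrix) -> int:
    return sum(
        oracle_character_steps(tree, matrix, c)
        for c in range(matrix.n_char)
        if matrix.active[c]
    )


# ---------------------------------------------------------------------------
# rooted-topology enumeration oracle
# ---------------------------------------------------------------------------


def all_rooted_trees(labels) -> list[Tree]:
    """Every rooted binary labelled topology on ``labels`` ((2n-3)!! shapes)."""
    labels = list(labels)

    def grow(shapes, label):
        out = []
        for shape in shapes:
            # slot 0 is the whole shape, i.e. a new root above everything
            for i in range(_n_slots(shape)):
                out.append(_insert_slot(shape, i, label)[0])
        return out

    shapes = [labels[0]]
    for label in labels[1:]:
        shapes = grow(shapes, label)
    return [_shape_to_tree(s) for s in shapes]


def _n_slots(shape) -> int:
    if isinstance(shape, str):
        return 1
    return 1 + _n_slots(shape[0]) + _n_slots(shape[1])


def _insert_slot(shape, i, label):
    if i == 0:
        return (shape, label), -1
    if isinstance(shape, str):
        return None, i - 1
    i -= 1
    new, i = _insert_slot(shape[0], i, label)
    if new is not None:
        return (new, shape[1]), -1
    new, i = _insert_slot(shape[1], i, label)
    if new is not None:
        return (shape[0], new), -1
    return None, i


def _shape_to_tree(shape) -> Tree:
    def rec(s):
        if isinstance(s, str):
            return Node(s)
        node = Node()
        node.add_child(rec(s[0]))
        node.add_child(rec(s[1]))
        return node

    root = rec(shape)
    if root.is_leaf:
        wrap = Node()
        wrap.add_child(root)
        root = wrap
    return Tree(root)


@pytest.fixture(scope="session")
def rooted_trees_4():
    return all_rooted_trees(["A", "B", "C", "D"])
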