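"""Searches for minimum-length trees.

Three searches share one engine:

* :func:`exhaustive_search` scores every binary topology (an oracle for the
  others; capped at 9 taxa),
* :func:`branch_and_bound` is exact at practical sizes: taxa are added one
  at a time (most complete first) and a partial tree is abandoned when its
  length plus an admissible completion bound exceeds the best known length,
* :func:`heuristic_search` builds random-addition-sequence Wagner trees and
  refines them by subtree pruning and regrafting (SPR).

Topologies are manipulated as nested tuples over taxon indices; the tree is
rooted at a designated leaf (the constrained outgroup), so a clade
constraint is a statement about leaf sets of internal nodes.  Scoring packs
all unit-cost characters into single big integers (10 bits per character)
and runs Fitch with word-parallel bit tricks; ordered characters are
decomposed into the standard additive binary factors (exact whenever
polymorphic scorings form contiguous state intervals, which is checked;
the rare non-interval cells fall back to a Sankoff pass).

Zero-minimum-length branches are collapsed to soft polytomies: a branch is
contracted when contracting it leaves the tree length unchanged, which is
the case exactly when some most-parsimonious assignment places no change on
it.  Tree identity, in particular the count of distinct most parsimonious
trees, is defined on bipartition sets after collapse.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .matrix import CharacterMatrix, FULL_MASK, N_STATES
from .parsimony import BIG, _combine_ordered, _leaf_costs, min_steps, tree_length
from .tree import Node, Tree

__all__ = [
    "TopologyConstraint",
    "SearchResult",
    "constrain",
    "exhaustive_search",
    "branch_and_bound",
    "heuristic_search",
    "collapse_zero",
    "strict_consensus",
]

EXHAUSTIVE_CAP = 9


# ---------------------------------------------------------------------------
# constraints
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TopologyConstraint:
    """Enforce or prohibit monophyly of a clade (rooted sense)."""

    clade: frozenset
    mode: str  # "enforce" | "prohibit"

    def __post_init__(self):
        if self.mode not in ("enforce", "prohibit"):
            raise ValueError("mode must be 'enforce' or 'prohibit'")


def constrain(matrix: CharacterMatrix, clade: Iterable[str], mode: str) -> TopologyConstraint:
    """Validated monophyly constraint for ``matrix``'s taxa."""
    clade = frozenset(clade)
    unknown = clade - set(matrix.taxa)
    if unknown:
        raise ValueError(f"constraint names unknown taxa: {sorted(unknown)}")
    if not 2 <= len(clade) <= matrix.n_taxa - 2:
        raise ValueError(
            "constraint clade must be a proper subset with 2..n-2 members"
        )
    return TopologyConstraint(clade, mode)


# ---------------------------------------------------------------------------
# nested-tuple topology helpers (leaves are taxon indices)
# ---------------------------------------------------------------------------


def _iter_paths(topo, path=()):
    yield path
    if isinstance(topo, tuple):
        yield from _iter_paths(topo[0], path + (0,))
        yield from _iter_paths(topo[1], path + (1,))


def _get(topo, path):
    for i in path:
        topo = topo[i]
    return topo


def _replace(topo, path, new):
    if not path:
        return new
    a, b = topo
    if path[0] == 0:
        return (_replace(a, path[1:], new), b)
    return (a, _replace(b, path[1:], new))


def _insert_leaf(topo, path, leaf):
    return _replace(topo, path, (_get(topo, path), leaf))


def _leafset(topo) -> frozenset:
    if isinstance(topo, int):
        return frozenset((topo,))
    return _leafset(topo[0]) | _leafset(topo[1])


def _tuple_to_tree(root_leaf: int, topo, taxa: Sequence[str]) -> Tree:
    def rec(t) -> Node:
        if isinstance(t, int):
            return Node(taxa[t])
        node = Node()
        node.add_child(rec(t[0]))
        node.add_child(rec(t[1]))
        return node

    root = Node()
    root.add_child(Node(taxa[root_leaf]))
    root.add_child(rec(topo))
    return Tree(root)


# ---------------------------------------------------------------------------
# fast length evaluator
# ---------------------------------------------------------------------------


class Evaluator:
    """Parsimony length of nested-tuple topologies over a fixed matrix."""

    def __init__(self, matrix: CharacterMatrix):
        self.matrix = matrix
        ordered = matrix.ordered_flags
        active = np.flatnonzero(matrix.active)
        unord_cols = [int(c) for c in active if not ordered[c]]
        ord_cols = [int(c) for c in active if ordered[c]]

        interval_cols, general_cols = [], []
        for c in ord_cols:
            if all(self._is_interval(row[c]) for row in matrix.cells):
                interval_cols.append(c)
            else:
                general_cols.append(c)

        blocks: list[tuple[str, int, int]] = [("u", c, 0) for c in unord_cols]
        for c in interval_cols:
            states = sorted(
                s for row in matrix.cells for s in row[c]
            )
            if states:
                lo, hi = states[0], states[-1]
                blocks.extend(("f", c, j) for j in range(lo, hi))
        self._n_blocks = len(blocks)
        self._lsb = sum(1 << (10 * b) for b in range(self._n_blocks))
        self._packed = [self._pack_row(row, blocks) for row in matrix.cells]

        self._general_cols = np.array(general_cols, dtype=int)
        if general_cols:
            self._gcosts = _leaf_costs(matrix, self._general_cols)
        else:
            self._gcosts = None
        self.evaluations = 0

    @staticmethod
    def _is_interval(cell: frozenset) -> bool:
        if len(cell) <= 1:
            return True
        return max(cell) - min(cell) + 1 == len(cell)

    @staticmethod
    def _pack_row(row, blocks) -> int:
        packed = 0
        for b, (kind, c, j) in enumerate(blocks):
            cell = row[c]
            if kind == "u":
                if cell:
                    mask = 0
                    for s in cell:
                        mask |= 1 << s
                else:
                    mask = FULL_MASK
            else:  # binary factor of an ordered character at threshold j
                if not cell:
                    mask = 0b11
                else:
                    lo, hi = min(cell), max(cell)
                    if lo > j:
                        mask = 0b10
                    elif hi <= j:
                        mask = 0b01
                    else:
                        mask = 0b11
            packed |= mask << (10 * b)
        return packed

    def _fitch(self, node):
        """Return (state bitset int, accumulated changes) for packed chars."""
        if isinstance(node, int):
            return self._packed[node], 0
        ma, sa = self._fitch(node[0])
        mb, sb = self._fitch(node[1])
        inter = ma & mb
        # OR-fold each 10-bit block into its LSB without crossing blocks:
        # y1[k] = x[k]|x[k+5] (k<5), then fold y1[0..4] into bit 0.
        y1 = inter | (inter >> 5)
        y = y1 | (y1 >> 1)
        y |= y >> 2
        y |= y1 >> 4
        occupied = y & self._lsb
        conflict = occupied ^ self._lsb
        if conflict:
            fill = conflict * 0x3FF
            state = (inter & ~fill) | ((ma | mb) & fill)
            return state, sa + sb + conflict.bit_count()
        return inter, sa + sb

    def _sankoff(self, node):
        if isinstance(node, int):
            return self._gcosts[node]
        a = self._sankoff(node[0])
        b = self._sankoff(node[1])
        return _combine_ordered(a) + _combine_ordered(b)

    def length(self, root_leaf: int, topo) -> int:
        """Length of the binary tree rooted on ``root_leaf``'s pendant edge."""
        self.evaluations += 1
        full = (root_leaf, topo) if topo is not None else root_leaf
        total = 0
        if self._n_blocks:
            _, steps = self._fitch(full)
            total += steps
        if self._gcosts is not None:
            total += int(self._sankoff(full).min(axis=-1).sum())
        return total


# ---------------------------------------------------------------------------
# constraint checks on tuple topologies
# ---------------------------------------------------------------------------


def _min_spanning_leafset(full, members: frozenset) -> frozenset:
    """Leaf set of the smallest subtree containing all of ``members``."""
    best = [None]

    def rec(node) -> frozenset:
        if isinstance(node, int):
            return frozenset((node,))
        ls = rec(node[0]) | rec(node[1])
        if best[0] is None and members <= ls:
            best[0] = ls
        return ls

    whole = rec(full)
    return best[0] if best[0] is not None else whole


def _enforce_possible(full, clade: frozenset, placed: frozenset) -> bool:
    """False when the partial tree already breaks ``clade`` irreparably."""
    present = clade & placed
    if len(present) < 2:
        return True
    span = _min_spanning_leafset(full, present)
    return span <= clade


def _clade_in_full(full, clade: frozenset) -> bool:
    return _min_spanning_leafset(full, clade) == clade


def _satisfies(full, constraints: Sequence[TopologyConstraint], index: dict) -> bool:
    for con in constraints:
        clade = frozenset(index[t] for t in con.clade)
        present = _clade_in_full(full, clade)
        if con.mode == "enforce" and not present:
            return False
        if con.mode == "prohibit" and present:
            return False
    return True


def _check_constraints(matrix: CharacterMatrix, constraints) -> list:
    constraints = list(constraints or ())
    seen = {}
    for con in constraints:
        unknown = con.clade - set(matrix.taxa)
        if unknown:
            raise ValueError(f"constraint names unknown taxa: {sorted(unknown)}")
        if con.clade in seen and seen[con.clade] != con.mode:
            raise ValueError(f"contradictory constraints on clade {sorted(con.clade)}")
        seen[con.clade] = con.mode
    return constraints


def _pick_root_taxon(matrix, constraints, outgroup: Optional[str]) -> int:
    if outgroup is not None:
        if outgroup not in matrix.taxa:
            raise ValueError(f"outgroup '{outgroup}' not in matrix")
        for con in constraints:
            if con.mode == "enforce" and outgroup in con.clade:
                raise ValueError("outgroup cannot be inside an enforced clade")
        return matrix.taxa.index(outgroup)
    blocked = set()
    for con in constraints:
        if con.mode == "enforce":
            blocked |= con.clade
    for i, t in enumerate(matrix.taxa):
        if t not in blocked:
            return i
    raise ValueError("no taxon available outside all enforced clades to root on")


# ---------------------------------------------------------------------------
# results
# ---------------------------------------------------------------------------


@dataclass
class SearchResult:
    """Optimal length, the distinct collapsed optimal trees, and counters."""

    best_length: int
    trees: list
    nodes_visited: int
    settings: dict = field(default_factory=dict)

    @property
    def n_trees(self) -> int:
        return len(self.trees)


def _finalize(
    matrix: CharacterMatrix,
    raw: list,
    best: int,
    root_leaf: int,
    visited: int,
    settings: dict,
    collapse: bool = True,
    max_trees: int = 10_000,
) -> SearchResult:
    trees, seen = [], set()
    for topo in raw:
        tree = _tuple_to_tree(root_leaf, topo, matrix.taxa)
        if collapse:
            tree = collapse_zero(tree, matrix)
        key = frozenset(tree.bipartitions())
        if key not in seen:
            seen.add(key)
            trees.append(tree)
        if len(trees) >= max_trees:
            break
    trees.sort(key=lambda t: t.to_newick())
    return SearchResult(best, trees, visited, settings)


# ---------------------------------------------------------------------------
# exhaustive search
# ---------------------------------------------------------------------------


def exhaustive_search(
    matrix: CharacterMatrix,
    constraints: Sequence[TopologyConstraint] = (),
    outgroup: Optional[str] = None,
    max_trees: int = 10_000,
) -> SearchResult:
    """Score every binary topology; exact, capped at 9 taxa."""
    if matrix.n_taxa > EXHAUSTIVE_CAP:
        raise ValueError(
            f"exhaustive search capped at {EXHAUSTIVE_CAP} taxa "
            f"(got {matrix.n_taxa}); use branch_and_bound"
        )
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    constraints = _check_constraints(matrix, constraints)
    root_leaf = _pick_root_taxon(matrix, constraints, outgroup)
    ev = Evaluator(matrix)
    rest = [i for i in range(matrix.n_taxa) if i != root_leaf]
    index = {t: i for i, t in enumerate(matrix.taxa)}

    best = None
    raw: list = []
    visited = 0
    for topo in _all_topologies(rest):
        visited += 1
        full = (root_leaf, topo)
        if constraints and not _satisfies(full, constraints, index):
            continue
        L = ev.length(root_leaf, topo)
        if best is None or L < best:
            best, raw = L, [topo]
        elif L == best:
            raw.append(topo)
    if best is None:
        raise ValueError("no topology satisfies the constraints")
    return _finalize(
        matrix, raw, best, root_leaf, visited,
        {"method": "exhaustive", "outgroup": matrix.taxa[root_leaf]},
        max_trees=max_trees,
    )


def _all_topologies(leaves: Sequence[int]):
    """Every distinct unrooted shape as a tuple over ``leaves`` (the root
    leaf is supplied separately)."""
    if len(leaves) == 1:
        yield leaves[0]
        return
    first, rest = leaves[0], leaves[1:]

    def grow(topo, remaining):
        if not remaining:
            yield topo
            return
        leaf, tail = remaining[0], remaining[1:]
        for path in _iter_paths(topo):
            yield from grow(_insert_leaf(topo, path, leaf), tail)

    yield from grow(first, rest)


# ---------------------------------------------------------------------------
# branch and bound
# ---------------------------------------------------------------------------


def branch_and_bound(
    matrix: CharacterMatrix,
    constraints: Sequence[TopologyConstraint] = (),
    outgroup: Optional[str] = None,
    max_trees: int = 10_000,
    seed: int = 0,
    initial_bound: Optional[int] = None,
) -> SearchResult:
    """Provably optimal trees under the constraints.

    Taxa are added most-complete-first (alphabetical tie-break); the lower
    bound for a partial tree adds, per character, the minimum extra steps
    the unplaced taxa must create (new states not yet spanned).
    """
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    constraints = _check_constraints(matrix, constraints)
    root_leaf = _pick_root_taxon(matrix, constraints, outgroup)
    index = {t: i for i, t in enumerate(matrix.taxa)}

    order = [root_leaf] + sorted(
        (i for i in range(matrix.n_taxa) if i != root_leaf),
        key=lambda i: (matrix.missing_fraction(i), matrix.taxa[i]),
    )
    bound_add = _completion_bounds(matrix, order)
    ev = Evaluator(matrix)

    best = initial_bound
    if best is None:
        heur = heuristic_search(
            matrix, constraints, n_replicates=max(3, matrix.n_taxa // 3),
            seed=seed, outgroup=matrix.taxa[root_leaf], collapse=False,
        )
        best = heur.best_length if heur.trees else None

    enforce = [
        frozenset(index[t] for t in con.clade)
        for con in constraints
        if con.mode == "enforce"
    ]
    n = matrix.n_taxa
    raw: list = []
    visited = 0
    best_box = [best if best is not None else 1 << 30]

    def grow(topo, k, placed):
        nonlocal raw, visited
        if k == n:
            full = (root_leaf, topo)
            if not _satisfies(full, constraints, index):
                return
            L = ev.length(root_leaf, topo)
            if L < best_box[0]:
                best_box[0] = L
                raw = [topo]
            elif L == best_box[0]:
                raw.append(topo)
            return
        leaf = order[k]
        new_placed = placed | frozenset((leaf,))
        for path in _iter_paths(topo):
            visited += 1
            cand = _insert_leaf(topo, path, leaf)
            full = (root_leaf, cand)
            L = ev.length(root_leaf, cand)
            if L + bound_add[k + 1] > best_box[0]:
                continue
            if enforce and any(
                not _enforce_possible(full, c, new_placed) for c in enforce
            ):
                continue
            grow(cand, k + 1, new_placed)

    grow(order[1], 2, frozenset(order[:2]))
    if not raw:
        raise ValueError("no topology satisfies the constraints")
    return _finalize(
        matrix, raw, best_box[0], root_leaf, visited,
        {
            "method": "branch_and_bound",
            "outgroup": matrix.taxa[root_leaf],
            "seed": seed,
            "max_trees": max_trees,
        },
        max_trees=max_trees,
    )


def _completion_bounds(matrix: CharacterMatrix, order: Sequence[int]) -> list[int]:
    """bound_add[k]: minimum extra steps the taxa beyond ``order[:k]`` must
    add, summed over active characters (admissible)."""
    active = [int(c) for c in np.flatnonzero(matrix.active)]
    m_all = {c: min_steps(matrix, c) for c in active}
    bounds = []
    for k in range(len(order) + 1):
        if k < 3:
            bounds.append(sum(m_all.values()))
            continue
        sub = matrix.subset_taxa([matrix.taxa[i] for i in order[:k]])
        extra = sum(m_all[c] - min_steps(sub, c) for c in active)
        bounds.append(extra)
    return bounds


# ---------------------------------------------------------------------------
# heuristic search (random addition + SPR)
# ---------------------------------------------------------------------------


def heuristic_search(
    matrix: CharacterMatrix,
    constraints: Sequence[TopologyConstraint] = (),
    n_replicates: int = 10,
    seed: int = 0,
    outgroup: Optional[str] = None,
    spr: bool = True,
    collapse: bool = True,
    max_trees: int = 10_000,
) -> SearchResult:
    """Random-addition Wagner trees refined by SPR; deterministic per seed."""
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if matrix.n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    constraints = _check_constraints(matrix, constraints)
    root_leaf = _pick_root_taxon(matrix, constraints, outgroup)
    index = {t: i for i, t in enumerate(matrix.taxa)}
    enforce = [
        frozenset(index[t] for t in con.clade)
        for con in constraints
        if con.mode == "enforce"
    ]
    ev = Evaluator(matrix)
    rng = np.random.default_rng(seed)

    best = None
    raw: list = []
    others = [i for i in range(matrix.n_taxa) if i != root_leaf]
    for _ in range(n_replicates):
        addition = [int(i) for i in rng.permutation(others)]
        topo = _wagner_build(ev, root_leaf, addition, enforce)
        if topo is None:
            continue
        L = ev.length(root_leaf, topo)
        if spr:
            topo, L = _spr_refine(ev, root_leaf, topo, L, enforce)
        full = (root_leaf, topo)
        if not _satisfies(full, constraints, index):
            continue
        if best is None or L < best:
            best, raw = L, [topo]
        elif L == best and topo not in raw:
            raw.append(topo)
    if best is None:
        return SearchResult(0, [], ev.evaluations, {"method": "heuristic"})
    return _finalize(
        matrix, raw, best, root_leaf, ev.evaluations,
        {
            "method": "heuristic",
            "outgroup": matrix.taxa[root_leaf],
            "seed": seed,
            "n_replicates": n_replicates,
            "spr": spr,
        },
        collapse=collapse,
        max_trees=max_trees,
    )


def _wagner_build(ev, root_leaf, addition, enforce):
    topo = addition[0]
    placed = frozenset((root_leaf, addition[0]))
    for leaf in addition[1:]:
        placed = placed | frozenset((int(leaf),))
        best_cand, best_len = None, None
        for path in _iter_paths(topo):
            cand = _insert_leaf(topo, path, int(leaf))
            if enforce and any(
                not _enforce_possible((root_leaf, cand), c, placed)
                for c in enforce
            ):
                continue
            L = ev.length(root_leaf, cand)
            if best_len is None or L < best_len:
                best_cand, best_len = cand, L
        if best_cand is None:
            return None
        topo = best_cand
    return topo


def _spr_neighbors(topo):
    """Prune every proper subtree and regraft everywhere else."""
    paths = [p for p in _iter_paths(topo) if p]
    for path in paths:
        pruned = _get(topo, path)
        parent_path, side = path[:-1], path[-1]
        sibling = _get(topo, parent_path)[1 - side]
        reduced = _replace(topo, parent_path, sibling)
        for dest in _iter_paths(reduced):
            yield _replace(reduced, dest, (_get(reduced, dest), pruned))


def _spr_refine(ev, root_leaf, topo, L, enforce):
    placed = _leafset((root_leaf, topo))
    improved = True
    while improved:
        improved = False
        for cand in _spr_neighbors(topo):
            Lc = ev.length(root_leaf, cand)
            if Lc < L:
                if enforce and any(
                    not _enforce_possible((root_leaf, cand), c, placed)
                    for c in enforce
                ):
                    continue
                topo, L = cand, Lc
                improved = True
                break
    return topo, L


# ---------------------------------------------------------------------------
# collapse and consensus
# ---------------------------------------------------------------------------


def collapse_zero(tree: Tree, matrix: CharacterMatrix) -> Tree:
    """Contract every branch whose minimum length over all most-parsimonious
    assignments is zero (soft polytomies); the tree length is unchanged.

    A branch can carry zero changes in some optimal assignment exactly when
    contracting it leaves the parsimony length unchanged, which is what is
    tested edge by edge.  Branches are interpreted on the unrooted shape: a
    degree-2 root sits in the middle of one edge, whose contraction merges
    both root children.
    """
    base = tree_length(tree, matrix)
    work = tree.copy()
    root = work.root
    to_collapse: list[Node] = []
    for node in list(work.postorder()):
        if node.is_leaf or node is root:
            continue
        if node.parent is root and len(root.children) == 2:
            sibling = next(c for c in root.children if c is not node)
            if sibling.is_leaf:
                continue  # this is the pendant edge of that leaf
            if node is not root.children[0]:
                continue  # same unrooted edge as the first child: test once
            contracted = _contract_nodes(work, [node, sibling])
            if tree_length(contracted, matrix) == base:
                to_collapse.extend([node, sibling])
        else:
            contracted = _contract_nodes(work, [node])
            if tree_length(contracted, matrix) == base:
                to_collapse.append(node)
    for node in to_collapse:
        parent = node.parent
        idx = parent.children.index(node)
        parent.children[idx : idx + 1] = node.children
        for child in node.children:
            child.parent = parent
    return work


def _node_path(node: Node) -> list[int]:
    path = []
    while node.parent is not None:
        path.append(node.parent.children.index(node))
        node = node.parent
    return list(reversed(path))


def _contract_nodes(tree: Tree, nodes: list[Node]) -> Tree:
    clone = tree.copy()
    # splice deeper/later siblings first so stored paths stay valid
    for path in sorted((_node_path(n) for n in nodes), reverse=True):
        target = clone.root
        for idx in path:
            target = target.children[idx]
        parent = target.parent
        idx = parent.children.index(target)
        parent.children[idx : idx + 1] = target.children
        for child in target.children:
            child.parent = parent
    return clone


def strict_consensus(trees: Sequence[Tree]) -> Tree:
    """Tree containing exactly the clades common to every input tree."""
    if not trees:
        raise ValueError("need at least one tree")
    leafsets = {frozenset(t.leaf_labels()) for t in trees}
    if len(leafsets) != 1:
        raise ValueError("trees must share one leaf set")
    labels = sorted(leafsets.pop())
    shared = set.intersection(*(t.clades() for t in trees))
    return tree_from_clades(labels, shared)


def tree_from_clades(labels: Sequence[str], clades: Iterable[frozenset]) -> Tree:
    """Build the rooted tree realising a nested (compatible) clade set."""
    clades = sorted(set(clades), key=len, reverse=True)
    root = Node()
    node_of: dict[frozenset, Node] = {frozenset(labels): root}
    order = [frozenset(labels)] + clades
    for clade in clades:
        parent = min(
            (c for c in order if clade < c),
            key=len,
        )
        node_of[clade] = Node()
        node_of[parent].add_child(node_of[clade])
    for label in labels:
        parent = min(
            (c for c in order if label in c),
            key=len,
        )
        node_of[parent].add_child(Node(label))
    return Tree(root)
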