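"""Synthetic trees, matrices and age tables.

The generators reproduce the statistical shape of a desk-scale
morphological systematics study — a modest taxon sample scored for a
couple of hundred mostly binary characters with a handful of ordered
multistate characters, strongly heterogeneous per-taxon missing data, and
first-appearance ages drawn from stage boundaries — so that every analysis
module can be exercised and calibrated without any real scorings.

Characters evolve along the given topology with a fixed per-edge change
probability (an Mk-like process without branch lengths: parsimony testing
needs homoplasy control, not rates).  Ordered characters step +/-1 along
the morphocline.  Missing data are masked in afterwards and never alter
the underlying state, so the same seed with and without masking yields the
same visible scorings where cells survive.

All generators take explicit seeds and never touch global random state.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence, Union

import numpy as np

from .ages import AgeTable
from .matrix import CharacterMatrix
from .tree import Node, Tree

__all__ = ["simulate_tree", "simulate_matrix", "simulate_ages"]


# ---------------------------------------------------------------------------
# trees
# ---------------------------------------------------------------------------


def simulate_tree(
    n_taxa: int, seed: int = 0, labels: Optional[Sequence[str]] = None
) -> Tree:
    """Uniformly random rooted binary labelled topology.

    Leaves are added one at a time on a uniformly chosen edge (including
    the edge above the root), which makes every rooted binary shape on the
    labels equally likely.
    """
    if n_taxa < 3:
        raise ValueError("need at least 3 taxa")
    if labels is None:
        labels = [f"t{i + 1:02d}" for i in range(n_taxa)]
    labels = list(labels)
    if len(labels) != n_taxa:
        raise ValueError("label count must equal n_taxa")
    rng = np.random.default_rng(seed)

    topo: object = (labels[0], labels[1])
    for leaf in labels[2:]:
        paths = list(_paths(topo))
        choice = int(rng.integers(0, len(paths)))
        topo = _insert(topo, paths[choice], leaf)

    def build(t) -> Node:
        if isinstance(t, str):
            return Node(t)
        node = Node()
        node.add_child(build(t[0]))
        node.add_child(build(t[1]))
        return node

    return Tree(build(topo))


def _paths(topo, path=()):
    yield path
    if isinstance(topo, tuple):
        yield from _paths(topo[0], path + (0,))
        yield from _paths(topo[1], path + (1,))


def _insert(topo, path, leaf):
    if not path:
        return (topo, leaf)
    a, b = topo
    if path[0] == 0:
        return (_insert(a, path[1:], leaf), b)
    return (a, _insert(b, path[1:], leaf))


# ---------------------------------------------------------------------------
# matrices
# ---------------------------------------------------------------------------


def simulate_matrix(
    tree: Tree,
    n_char: int = 60,
    n_states: int = 2,
    change_prob: float = 0.1,
    ordered_fraction: float = 0.0,
    missing_profile: Union[None, float, Mapping[str, float]] = None,
    seed: int = 0,
) -> CharacterMatrix:
    """Evolve a character matrix along ``tree``.

    Each character changes state on each edge with probability
    ``change_prob`` (uniform new state if unordered, +/-1 step if ordered).
    A fraction ``ordered_fraction`` of characters is ordered (these use the
    full 0..n_states-1 morphocline).  ``missing_profile`` masks cells per
    taxon to the requested fraction (within one cell), without altering
    the evolved states underneath.
    """
    if not 0 <= change_prob <= 1:
        raise ValueError("change_prob must be in [0, 1]")
    if not 0 <= ordered_fraction <= 1:
        raise ValueError("ordered_fraction must be in [0, 1]")
    if n_states < 2 or n_states > 10:
        raise ValueError("n_states must be in 2..10")
    evo_seed, miss_seed = np.random.SeedSequence(seed).spawn(2)
    rng = np.random.default_rng(evo_seed)

    n_ordered = int(round(ordered_fraction * n_char))
    ordered_positions = sorted(
        int(i) for i in rng.choice(n_char, size=n_ordered, replace=False)
    )
    is_ordered = np.zeros(n_char, dtype=bool)
    is_ordered[ordered_positions] = True

    taxa = tree.leaf_labels()
    states: dict[str, np.ndarray] = {}
    root_states = rng.integers(0, n_states, size=n_char)
    stack = [(tree.root, root_states)]
    while stack:
        node, current = stack.pop()
        if node.is_leaf:
            states[node.label] = current
            continue
        for child in node.children:
            change = rng.random(n_char) < change_prob
            new = current.copy()
            if change.any():
                unord = change & ~is_ordered
                if unord.any():
                    shift = rng.integers(1, n_states, size=int(unord.sum()))
                    new[unord] = (new[unord] + shift) % n_states
                order = change & is_ordered
                if order.any():
                    step = np.where(rng.random(int(order.sum())) < 0.5, -1, 1)
                    new[order] = np.clip(new[order] + step, 0, n_states - 1)
            stack.append((child, new))

    cells = [[frozenset([int(s)]) for s in states[t]] for t in taxa]

    if missing_profile is not None:
        miss_rng = np.random.default_rng(miss_seed)
        if isinstance(missing_profile, Mapping):
            fractions = {t: float(missing_profile.get(t, 0.0)) for t in taxa}
        else:
            fractions = {t: float(missing_profile) for t in taxa}
        for frac in fractions.values():
            if not 0 <= frac <= 1:
                raise ValueError("missing fractions must be in [0, 1]")
        for i, t in enumerate(taxa):
            k = int(round(fractions[t] * n_char))
            if k:
                hide = miss_rng.choice(n_char, size=k, replace=False)
                for c in hide:
                    cells[i][int(c)] = frozenset()

    return CharacterMatrix(taxa, cells, ordered=ordered_positions)


# ---------------------------------------------------------------------------
# ages
# ---------------------------------------------------------------------------


def simulate_ages(
    tree: Tree,
    mode: str = "congruent",
    seed: int = 0,
    oldest: float = 170.0,
    jitter: float = 3.0,
) -> AgeTable:
    """First-appearance intervals for the leaves of ``tree``.

    ``congruent`` assigns point FADs so the tree is perfectly congruent
    (MIG equals the FAD range, hence SCI = GER = MSM* = 1 on the
    generating tree); ``shuffled`` permutes those FADs across leaves.
    Intervals are built around the point FADs by stage-width jitter and
    always contain them.  The point FADs are attached to the returned
    table as ``table.points``.
    """
    if mode not in ("congruent", "shuffled"):
        raise ValueError("mode must be 'congruent' or 'shuffled'")
    rng = np.random.default_rng(seed)
    points: dict[str, float] = {}

    def decrement() -> float:
        return float(rng.uniform(2.0, 8.0))

    def constant(node: Node, age: float) -> None:
        if node.is_leaf:
            points[node.label] = age
        else:
            for child in node.children:
                constant(child, age)

    def assign(node: Node, age: float) -> None:
        if node.is_leaf:
            points[node.label] = age
            return
        kids = node.children
        internal = [k for k in kids if not k.is_leaf]
        if internal:
            chain = internal[0]
            may_decline = all(k.is_leaf for k in kids if k is not chain)
            for k in kids:
                if k is chain:
                    assign(k, age - decrement() if may_decline else age)
                elif k.is_leaf:
                    points[k.label] = age
                else:
                    constant(k, age)
        else:
            for k in kids[:-1]:
                points[k.label] = age
            points[kids[-1].label] = age - decrement()

    assign(tree.root, oldest)

    if mode == "shuffled":
        labels = list(points)
        values = [points[t] for t in labels]
        perm = rng.permutation(len(values))
        points = {t: values[int(i)] for t, i in zip(labels, perm)}

    intervals = {}
    for t, p in points.items():
        up = float(rng.uniform(0, jitter))
        down = float(rng.uniform(0, jitter))
        intervals[t] = (p + up, max(p - down, 1e-6))
    table = AgeTable(intervals)
    table.points = dict(points)  # generator bookkeeping for calibration
    return table
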