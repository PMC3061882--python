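"""Parsimony scoring of character matrices on trees.

Two character models are supported:

* ``unordered`` (Fitch): any state change costs 1;
* ``ordered`` (Wagner / additive): a change from state ``a`` to ``b`` costs
  ``|a - b|``, the number of steps along the morphocline.

Scoring uses the Sankoff dynamic programme over the state alphabet, which
handles missing cells (no cost anywhere), polymorphic cells (any member
state is available at the leaf for free) and multifurcating nodes in one
pass.  Multifurcations are scored as the minimum-cost assignment on the
multifurcating tree itself (the PAUP*/TNT convention, and the convention
under which the maximum conceivable length of a character equals its length
on the star tree).  For the zero-minimum-length branches that the tree
search collapses, this equals the minimum over binary resolutions, so
collapsing never changes reported tree lengths.

Ensemble fit indices follow the standard definitions: with ``s`` the
realised steps, ``m`` the minimum conceivable steps (on the best possible
tree) and ``g`` the maximum conceivable steps (on the star tree), summed
over characters,

    CI = sum(m) / sum(s),   RI = (sum(g) - sum(s)) / (sum(g) - sum(m)),
    RCI = CI * RI.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np

from .matrix import CharacterMatrix, MAX_STATE, N_STATES
from .tree import Tree

__all__ = [
    "CharacterModel",
    "FitReport",
    "character_steps",
    "per_character_steps",
    "tree_length",
    "min_steps",
    "max_steps",
    "ensemble_indices",
    "count_informative",
    "is_informative",
]

BIG = np.int32(1 << 20)


@dataclass(frozen=True)
class CharacterModel:
    """Step-cost model of a single character."""

    kind: str  # "unordered" | "ordered"

    def step(self, a: int, b: int) -> int:
        if self.kind == "ordered":
            return abs(a - b)
        return 0 if a == b else 1


# ---------------------------------------------------------------------------
# Sankoff scoring
# ---------------------------------------------------------------------------


def _leaf_costs(matrix: CharacterMatrix, cols: np.ndarray) -> np.ndarray:
    """int32 array (n_taxa, len(cols), N_STATES): 0 where a state is
    available at the leaf, BIG elsewhere; missing cells are all-zero."""
    masks = matrix.state_masks()[:, cols]
    states = np.arange(N_STATES, dtype=np.uint16)
    allowed = (masks[..., None] >> states) & 1
    return np.where(allowed.astype(bool), np.int32(0), BIG)


def _combine_unordered(cost: np.ndarray) -> np.ndarray:
    """min-plus with the unit step matrix: out[s] = min(cost[s], min(cost)+1)."""
    return np.minimum(cost, cost.min(axis=-1, keepdims=True) + 1)


def _combine_ordered(cost: np.ndarray) -> np.ndarray:
    """min-plus with |a-b| costs via forward/backward distance transform."""
    out = cost.copy()
    for s in range(1, N_STATES):
        np.minimum(out[..., s], out[..., s - 1] + 1, out=out[..., s])
    for s in range(N_STATES - 2, -1, -1):
        np.minimum(out[..., s], out[..., s + 1] + 1, out=out[..., s])
    return out


def _sankoff_root_costs(
    tree: Tree, matrix: CharacterMatrix, cols: np.ndarray
) -> np.ndarray:
    """Root-state cost vectors, shape (len(cols), N_STATES)."""
    leaf_costs = _leaf_costs(matrix, cols)
    ordered = matrix.ordered_flags[cols]
    taxon_of = {t: i for i, t in enumerate(matrix.taxa)}
    missing = set(tree.leaf_labels()) - set(matrix.taxa)
    if missing:
        raise ValueError(f"tree leaves absent from matrix: {sorted(missing)}")

    costs: dict[int, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            costs[id(node)] = leaf_costs[taxon_of[node.label]]
        else:
            total = np.zeros((len(cols), N_STATES), dtype=np.int64)
            for child in node.children:
                c = costs.pop(id(child))
                contrib = np.empty_like(c)
                if ordered.any():
                    contrib[ordered] = _combine_ordered(c[ordered])
                if (~ordered).any():
                    contrib[~ordered] = _combine_unordered(c[~ordered])
                total += contrib
            costs[id(node)] = total
    return costs[id(tree.root)]


def per_character_steps(
    tree: Tree, matrix: CharacterMatrix, positions: Optional[Sequence[int]] = None
) -> np.ndarray:
    """Minimum weighted state changes of each character on ``tree``.

    ``positions`` are 0-based character positions; defaults to the active
    characters.  Missing cells impose no cost; polymorphic cells offer any
    member state at the leaf.
    """
    if positions is None:
        cols = np.flatnonzero(matrix.active)
    else:
        cols = np.asarray(list(positions), dtype=int)
        if cols.size and (cols.min() < 0 or cols.max() >= matrix.n_char):
            raise IndexError("character position out of range")
    if cols.size == 0:
        return np.zeros(0, dtype=np.int64)
    root = _sankoff_root_costs(tree, matrix, cols)
    return root.min(axis=-1).astype(np.int64)


def character_steps(tree: Tree, matrix: CharacterMatrix, c: int) -> int:
    """Steps of one character (0-based position) on the tree."""
    if not (0 <= c < matrix.n_char):
        raise IndexError(f"character position {c} out of range")
    return int(per_character_steps(tree, matrix, [c])[0])


def tree_length(tree: Tree, matrix: CharacterMatrix) -> int:
    """Total parsimony length over active characters; rooting-invariant."""
    return int(per_character_steps(tree, matrix).sum())


# ---------------------------------------------------------------------------
# per-character bounds m and g
# ---------------------------------------------------------------------------


def _cell_masks(matrix: CharacterMatrix, c: int) -> list[int]:
    masks = []
    for row in matrix.cells:
        cell = row[c]
        if cell:
            m = 0
            for s in cell:
                m |= 1 << s
            masks.append(m)
    return masks


def min_steps(matrix: CharacterMatrix, c: int) -> int:
    """Minimum conceivable steps of character ``c`` on any tree.

    Unordered: one change fewer than the smallest number of states that can
    cover every scored cell (polymorphic cells may settle on any member).
    Ordered: the smallest achievable observed state range.
    """
    if not (0 <= c < matrix.n_char):
        raise IndexError(f"character position {c} out of range")
    cells = _cell_masks(matrix, c)
    if not cells:
        return 0
    if matrix.ordering(c) == "ordered":
        best = MAX_STATE
        for lo in range(N_STATES):
            for hi in range(lo, N_STATES):
                window = ((1 << (hi - lo + 1)) - 1) << lo
                if all(cm & window for cm in cells):
                    best = min(best, hi - lo)
                    break
        return best
    distinct = set(cells)
    for size in range(1, N_STATES + 1):
        for submask in _masks_of_popcount(size):
            if all(cm & submask for cm in distinct):
                return size - 1
    raise AssertionError("unreachable")


def _masks_of_popcount(k: int):
    for mask in range(1 << N_STATES):
        if mask.bit_count() == k:
            yield mask


def max_steps(matrix: CharacterMatrix, c: int) -> int:
    """Maximum conceivable steps: the character's length on the star tree,
    i.e. min over a central state v of the summed leaf-to-centre costs."""
    if not (0 <= c < matrix.n_char):
        raise IndexError(f"character position {c} out of range")
    cells = _cell_masks(matrix, c)
    if not cells:
        return 0
    ordered = matrix.ordering(c) == "ordered"
    best = None
    for v in range(N_STATES):
        total = 0
        for cm in cells:
            if ordered:
                cost = min(abs(s - v) for s in range(N_STATES) if cm >> s & 1)
            else:
                cost = 0 if cm >> v & 1 else 1
            total += cost
        best = total if best is None else min(best, total)
    return int(best)


# ---------------------------------------------------------------------------
# informativeness and ensemble indices
# ---------------------------------------------------------------------------


def is_informative(
    matrix: CharacterMatrix, c: int, taxa: Optional[Sequence[str]] = None
) -> bool:
    """Parsimony-informative: at least two states each scored in >= 2 taxa."""
    rows = (
        matrix.cells
        if taxa is None
        else [matrix.cells[matrix.taxon_index(t)] for t in taxa]
    )
    counts = [0] * N_STATES
    for row in rows:
        for s in row[c]:
            counts[s] += 1
    return sum(1 for n in counts if n >= 2) >= 2


def count_informative(
    matrix: CharacterMatrix, taxa: Optional[Sequence[str]] = None
) -> int:
    """Number of active characters informative for the taxon subset."""
    if taxa is not None and len(list(taxa)) == 0:
        raise ValueError("empty taxon subset")
    return sum(
        1
        for c in np.flatnonzero(matrix.active)
        if is_informative(matrix, int(c), taxa)
    )


@dataclass
class FitReport:
    """Tree length and ensemble fit indices with per-character decomposition."""

    S: int
    steps: np.ndarray  # s_i over reported characters
    min_possible: np.ndarray  # m_i
    max_possible: np.ndarray  # g_i
    positions: np.ndarray  # 0-based character positions reported
    CI: float
    RI: float
    RCI: float
    include_uninformative: bool = True
    extras: dict = field(default_factory=dict)

    def per_character_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "character": self.positions + 1,  # 1-based in reports
                "steps": self.steps,
                "min": self.min_possible,
                "max": self.max_possible,
            }
        )

    def summary(self) -> dict:
        return {
            "length": int(self.S),
            "CI": round(float(self.CI), 4),
            "RI": round(float(self.RI), 4),
            "RCI": round(float(self.RCI), 4),
            "n_characters": int(len(self.positions)),
            "include_uninformative": self.include_uninformative,
        }


def ensemble_indices(
    tree: Tree, matrix: CharacterMatrix, include_uninformative: bool = True
) -> FitReport:
    """Length, CI, RI and RCI of ``tree`` on the active characters.

    With ``include_uninformative=False`` the sums run over
    parsimony-informative characters only (both conventions circulate in the
    literature; PAUP* reports both).
    """
    active = np.flatnonzero(matrix.active)
    if not include_uninformative:
        cols = np.array(
            [c for c in active if is_informative(matrix, int(c))], dtype=int
        )
    else:
        cols = active
    s = per_character_steps(tree, matrix, cols)
    m = np.array([min_steps(matrix, int(c)) for c in cols], dtype=np.int64)
    g = np.array([max_steps(matrix, int(c)) for c in cols], dtype=np.int64)

    s_all = per_character_steps(tree, matrix, active)
    S = int(s_all.sum())

    sum_s, sum_m, sum_g = int(s.sum()), int(m.sum()), int(g.sum())
    CI = 1.0 if sum_s == 0 else sum_m / sum_s
    RI = 1.0 if sum_g == sum_m else (sum_g - sum_s) / (sum_g - sum_m)
    return FitReport(
        S=S,
        steps=s,
        min_possible=m,
        max_possible=g,
        positions=cols,
        CI=CI,
        RI=RI,
        RCI=CI * RI,
        include_uninformative=include_uninformative,
    )
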