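"""Discrete-trait parsimony on a fixed topology: the body-size analysis.

Taxa are classified as larger- or smaller-bodied from up to three linear
measurements — total body length, skull length and femur length — with
thresholds of 10 m, 1 m and 1 m respectively.  A taxon is "larger" when
every available measurement exceeds its threshold, "smaller" when any
available measurement is at or below, and "unknown" with no measurements.
The classification is then optimised on a topology by Fitch parsimony
(unknown leaves are free), and the optimal reconstructions are enumerated
to report how many are gains vs. reversals.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional

from .matrix import CharacterMatrix
from .parsimony import tree_length
from .tree import Tree

__all__ = [
    "BODY_THRESHOLDS_CM",
    "classify_body_size",
    "fitch_min_changes",
    "TraitOptimization",
    "optimize_trait",
]

# thresholds in cm: body length 10 m, skull length 1 m, femur length 1 m
BODY_THRESHOLDS_CM = {
    "body_length": 1000.0,
    "skull_length": 100.0,
    "femur_length": 100.0,
}


def classify_body_size(
    measurements: Mapping[str, Mapping[str, Optional[float]]]
) -> dict[str, str]:
    """Per-taxon {'larger' | 'smaller' | 'unknown'} from linear measurements.

    ``measurements[taxon]`` maps any of body_length / skull_length /
    femur_length to cm (missing entries or None are allowed).
    """
    out = {}
    for taxon, row in measurements.items():
        available = {}
        for key, threshold in BODY_THRESHOLDS_CM.items():
            value = row.get(key)
            if value is None:
                continue
            if value < 0:
                raise ValueError(f"{taxon}: negative {key} ({value})")
            available[key] = float(value)
        if not available:
            out[taxon] = "unknown"
        elif all(v > BODY_THRESHOLDS_CM[k] for k, v in available.items()):
            out[taxon] = "larger"
        else:
            out[taxon] = "smaller"
    return out


def _trait_matrix(tree: Tree, trait: Mapping[str, str], states: dict) -> CharacterMatrix:
    cells = []
    taxa = tree.leaf_labels()
    for t in taxa:
        value = trait.get(t, "unknown")
        if value not in states and value != "unknown":
            raise ValueError(f"{t}: unknown trait value '{value}'")
        cells.append([states.get(value, frozenset())])
    return CharacterMatrix(taxa, cells)


def fitch_min_changes(tree: Tree, trait: Mapping[str, str | int | None]) -> int:
    """Minimum state changes of a discrete trait on the rooted tree.

    Trait values may be the body-size labels ('smaller'/'larger'/'unknown')
    or small integers; unknown / missing leaves impose no cost.
    """
    values = {trait.get(t) for t in tree.leaf_labels()}
    if values <= {"smaller", "larger", "unknown", None}:
        states = {"smaller": frozenset([0]), "larger": frozenset([1])}
        mat = _trait_matrix(tree, {k: v for k, v in trait.items() if v}, states)
    else:
        cells = []
        for t in tree.leaf_labels():
            v = trait.get(t)
            cells.append([frozenset() if v is None else frozenset([int(v)])])
        mat = CharacterMatrix(tree.leaf_labels(), cells)
    return tree_length(tree, mat)


@dataclass
class TraitOptimization:
    """Minimum changes plus the gain/loss make-up of the optimal solutions."""

    changes: int
    gains_losses: list[tuple[int, int]]  # distinct (gains, losses) among MPRs
    ambiguous_direction: bool

    def summary(self) -> dict:
        return {
            "changes": self.changes,
            "gains_losses": sorted(self.gains_losses),
            "ambiguous_directions": self.ambiguous_direction,
        }


def optimize_trait(tree: Tree, trait: Mapping[str, str | int | None]) -> TraitOptimization:
    """Fitch count plus an enumeration of optimal binary reconstructions.

    For a binary trait (the body-size case) every minimum-change assignment
    of ancestral states is enumerated; a change is a gain when it runs
    0 -> 1 (smaller -> larger) along descent, a loss otherwise.
    """
    changes = fitch_min_changes(tree, trait)
    state_of = {}
    for t in tree.leaf_labels():
        v = trait.get(t)
        if v in ("smaller", 0):
            state_of[t] = 0
        elif v in ("larger", 1):
            state_of[t] = 1
        else:
            state_of[t] = None

    internals = tree.internal_nodes()
    combos = set()
    if len(internals) <= 16:
        free_leaves = [t for t, s in state_of.items() if s is None]
        for internal_states in itertools.product((0, 1), repeat=len(internals)):
            assign = dict(zip((id(n) for n in internals), internal_states))
            for leaf_states in itertools.product((0, 1), repeat=len(free_leaves)):
                full = dict(assign)
                for t, s in zip(free_leaves, leaf_states):
                    full[t] = s
                gains = losses = 0
                ok = True
                for node in tree.postorder():
                    if node is tree.root:
                        continue
                    s = _state(node, full, state_of)
                    p = _state(node.parent, full, state_of)
                    if s is None or p is None:
                        ok = False
                        break
                    if p == 0 and s == 1:
                        gains += 1
                    elif p == 1 and s == 0:
                        losses += 1
                if ok and gains + losses == changes:
                    combos.add((gains, losses))
    directions = {g for g, _ in combos}
    return TraitOptimization(
        changes=changes,
        gains_losses=sorted(combos),
        ambiguous_direction=len(combos) > 1 or len(directions) > 1,
    )


def _state(node, full, state_of):
    if node.is_leaf:
        s = state_of[node.label]
        return full.get(node.label) if s is None else s
    return full[id(node)]
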