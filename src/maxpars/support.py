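"""Clade support: nonparametric bootstrap and Bremer decay indices.

Bootstrap: characters are resampled with replacement (keeping the original
count), each pseudo-replicate is searched heuristically with the same
settings as the primary analysis, the replicate's optimal trees are
summarised by strict consensus (majority-rule optional), and a reference
clade's support is the percentage of replicates whose summary contains it.

Bremer support of a clade is the length of the best tree that lacks the
clade minus the unconstrained optimum, computed exactly by a
converse-constraint (prohibit) branch-and-bound search.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np

from .matrix import CharacterMatrix
from .search import (
    TopologyConstraint,
    branch_and_bound,
    heuristic_search,
    strict_consensus,
)
from .tree import Tree

__all__ = ["bootstrap_support", "bremer_support", "support_table"]


def bootstrap_support(
    matrix: CharacterMatrix,
    n_replicates: int = 1000,
    seed: int = 0,
    reference: Optional[Tree] = None,
    outgroup: Optional[str] = None,
    search_replicates: int = 3,
    spr: bool = True,
    min_report: float = 50.0,
    summary: str = "strict",
) -> dict[frozenset, float]:
    """Bootstrap percentages for the clades of the reference tree.

    Returns ``{clade (frozenset of taxa): percentage}`` for reference clades
    above ``min_report`` (set it to 0 to report every clade).  If no
    reference tree is given, one is found by heuristic search first.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if summary not in ("strict", "majority"):
        raise ValueError("summary must be 'strict' or 'majority'")
    rng = np.random.default_rng(seed)
    if reference is None:
        ref_result = heuristic_search(
            matrix, n_replicates=max(5, search_replicates), seed=seed,
            outgroup=outgroup, spr=spr,
        )
        reference = ref_result.trees[0]
    ref_clades = reference.clades()

    counts = {clade: 0 for clade in ref_clades}
    for _ in range(n_replicates):
        cols = rng.integers(0, matrix.n_char, size=matrix.n_char)
        boot = matrix.select_characters(cols)
        result = heuristic_search(
            boot,
            n_replicates=search_replicates,
            seed=int(rng.integers(0, 2**31 - 1)),
            outgroup=outgroup,
            spr=spr,
            collapse=True,
        )
        if not result.trees:
            continue
        if summary == "strict":
            present = strict_consensus(result.trees).clades()
        else:
            present = _majority_clades(result.trees)
        for clade in ref_clades & present:
            counts[clade] += 1

    out = {
        clade: 100.0 * n / n_replicates
        for clade, n in counts.items()
        if 100.0 * n / n_replicates > min_report
    }
    return out


def _majority_clades(trees: Sequence[Tree]) -> set[frozenset]:
    tally: dict[frozenset, int] = {}
    for tree in trees:
        for clade in tree.clades():
            tally[clade] = tally.get(clade, 0) + 1
    half = len(trees) / 2
    return {clade for clade, n in tally.items() if n > half}


def bremer_support(
    matrix: CharacterMatrix,
    mpt: Tree,
    clade: Iterable[str],
    outgroup: Optional[str] = None,
    seed: int = 0,
) -> int:
    """Extra steps needed before ``clade`` is lost from the optimal trees."""
    clade = frozenset(clade)
    if mpt.find_clade(clade) is None:
        raise ValueError(f"clade {sorted(clade)} absent from the given tree")
    if not 2 <= len(clade) <= matrix.n_taxa - 2:
        raise ValueError(
            "Bremer support is undefined for trivial clades (present in "
            "every tree rooted on the outgroup)"
        )
    free = branch_and_bound(matrix, outgroup=outgroup, seed=seed)
    if any(t.find_clade(clade) is None for t in free.trees):
        return 0  # clade not in every optimal tree
    con = TopologyConstraint(clade, "prohibit")
    constrained = branch_and_bound(
        matrix, constraints=[con], outgroup=outgroup, seed=seed
    )
    return constrained.best_length - free.best_length


@dataclass
class SupportRow:
    clade: frozenset
    bootstrap: Optional[float]
    bremer: Optional[int]


def support_table(
    matrix: CharacterMatrix,
    mpt: Tree,
    bootstrap: Optional[dict[frozenset, float]] = None,
    bremer: bool = True,
    outgroup: Optional[str] = None,
    seed: int = 0,
) -> list[SupportRow]:
    """Bootstrap and Bremer values for every clade of ``mpt``."""
    rows = []
    for clade in sorted(mpt.clades(), key=lambda c: (len(c), sorted(c))):
        boot = bootstrap.get(clade) if bootstrap else None
        decay = None
        if bremer and 2 <= len(clade) <= matrix.n_taxa - 2:
            decay = bremer_support(matrix, mpt, clade, outgroup=outgroup, seed=seed)
        rows.append(SupportRow(clade, boot, decay))
    return rows
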