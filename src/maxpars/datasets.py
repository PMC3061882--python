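"""Packaged case study: allosauroid theropod phylogeny.

This module carries the inputs of the package's worked example, a
published-style reference analysis of Allosauroidea (the clade of large
Jurassic-Cretaceous predatory dinosaurs containing Allosaurus and the
carcharodontosaurids):

* the reference topology, in which Acrocanthosaurus nests deeply within
  Carcharodontosauridae as sister to Eocarcharia rather than grouping
  with Allosaurus;
* an alternative placement (Acrocanthosaurus with Allosaurus and
  Neovenator) used for the body-size comparison;
* published linear body-size measurements for the twelve allosauroid
  terminals;
* a per-taxon first-appearance interval table.  The original analysis
  distributed its age table as supplementary material that is not
  redistributed here; this table is a SYNTHETIC RECONSTRUCTION from the
  stage assignments of each taxon's oldest referred material, converted
  to Ma with the packaged stage-boundary lookup.  It reproduces the
  published stratigraphic-fit values but is not a transcription.

The character matrix of the original analysis (18 taxa x 177 characters)
is likewise supplementary material that is not redistributed; searches in
examples and tests run on synthetic matrices with the same dimensions,
ordering structure and missing-data profile (see :func:`study_like_matrix`).
"""

from __future__ import annotations

from typing import Optional

import pandas as pd

from .ages import AgeTable, stage_interval
from .matrix import CharacterMatrix
from .simulate import simulate_matrix, simulate_tree
from .tree import Tree, parse_newick

__all__ = [
    "ALLOSAUROID_TAXA",
    "SHARED_TAXA_8",
    "allosauroid_tree",
    "reference_tree_with_outgroups",
    "alternative_placement_tree",
    "body_size_measurements",
    "allosauroid_age_table",
    "study_like_matrix",
    "STUDY_MISSINGNESS",
    "STUDY_ORDERED_COUNT",
]

# Twelve allosauroid terminals of the reference analysis.
ALLOSAUROID_TAXA = [
    "Monolophosaurus",
    "Yangchuanosaurus",
    "Sinraptor",
    "Allosaurus",
    "Neovenator",
    "Tyrannotitan",
    "Eocarcharia",
    "Acrocanthosaurus",
    "Shaochilong",
    "Carcharodontosaurus",
    "Mapusaurus",
    "Giganotosaurus",
]

# Taxa shared with the competing analysis that places Acrocanthosaurus
# near Allosaurus; comparisons are made on trees pruned to these.
SHARED_TAXA_8 = [
    "Monolophosaurus",
    "Allosaurus",
    "Sinraptor",
    "Neovenator",
    "Acrocanthosaurus",
    "Carcharodontosaurus",
    "Tyrannotitan",
    "Giganotosaurus",
]

_TREE_12 = (
    "(Monolophosaurus,((Sinraptor,Yangchuanosaurus),(Allosaurus,(Neovenator,"
    "(Tyrannotitan,((Acrocanthosaurus,Eocarcharia),(Shaochilong,"
    "(Carcharodontosaurus,(Mapusaurus,Giganotosaurus)))))))));"
)

_TREE_18 = (
    "(Herrerasaurus,(Coelophysoidea,(Piatnitzkysaurus,((Compsognathidae,"
    "(Dilong,Tyrannosaurus)),(Monolophosaurus,((Sinraptor,Yangchuanosaurus),"
    "(Allosaurus,(Neovenator,(Tyrannotitan,((Acrocanthosaurus,Eocarcharia),"
    "(Shaochilong,(Carcharodontosaurus,(Mapusaurus,Giganotosaurus)))))))))))));"
)

# Alternative placement on the 8 shared taxa: Acrocanthosaurus groups with
# Allosaurus + Neovenator, outside Carcharodontosauria.
_TREE_ALT_8 = (
    "(Monolophosaurus,(Sinraptor,((Acrocanthosaurus,(Allosaurus,Neovenator)),"
    "(Tyrannotitan,(Carcharodontosaurus,Giganotosaurus)))));"
)


def allosauroid_tree() -> Tree:
    """Reference topology on the 12 allosauroid terminals (rooted with
    Monolophosaurus basal-most)."""
    return parse_newick(_TREE_12)


def reference_tree_with_outgroups() -> Tree:
    """Reference topology on all 18 terminals, rooted on Herrerasaurus."""
    return parse_newick(_TREE_18)


def alternative_placement_tree() -> Tree:
    """Competing placement of Acrocanthosaurus (with Allosaurus/Neovenator)
    on the 8 shared taxa."""
    return parse_newick(_TREE_ALT_8)


# ---------------------------------------------------------------------------
# body size (published measurements, cm; None = not preserved/reported)
# ---------------------------------------------------------------------------

_BODY_SIZE = {
    "Monolophosaurus": (510, 67.0, None),
    "Yangchuanosaurus": (790, 78.0, 85.0),
    "Sinraptor": (900, 90.0, 87.6),
    "Allosaurus": (970, 100.8, 88.0),
    "Neovenator": (750, 70.0, 75.0),
    "Tyrannotitan": (1220, None, 140.0),
    "Eocarcharia": (800, 98.0, None),
    "Acrocanthosaurus": (1150, 129.0, 109.0),
    "Shaochilong": (None, None, None),
    "Carcharodontosaurus": (1279, 160.0, 126.0),
    "Mapusaurus": (1260, None, None),
    "Giganotosaurus": (1320, 195.0, 143.0),
}


def body_size_measurements(as_frame: bool = False):
    """Total body, skull and femur lengths (cm) per allosauroid taxon."""
    table = {
        taxon: {
            "body_length": body,
            "skull_length": skull,
            "femur_length": femur,
        }
        for taxon, (body, skull, femur) in _BODY_SIZE.items()
    }
    if as_frame:
        return pd.DataFrame(table).T
    return table


# ---------------------------------------------------------------------------
# ages (synthetic reconstruction from stage assignments)
# ---------------------------------------------------------------------------

_STAGE_ASSIGNMENTS = {
    # taxon: (oldest stage, youngest stage) of the first-appearance interval
    "Monolophosaurus": ("Bathonian", "Callovian"),
    "Yangchuanosaurus": ("Oxfordian", "Oxfordian"),
    "Sinraptor": ("Oxfordian", "Oxfordian"),
    "Allosaurus": ("Oxfordian", "Kimmeridgian"),
    "Neovenator": ("Barremian", "Barremian"),
    "Tyrannotitan": ("Aptian", "Aptian"),
    "Eocarcharia": ("Aptian", "Aptian"),
    "Acrocanthosaurus": ("Aptian", "Albian"),
    "Shaochilong": ("Aptian", "Turonian"),
    "Carcharodontosaurus": ("Aptian", "Cenomanian"),
    "Mapusaurus": ("Cenomanian", "Turonian"),
    "Giganotosaurus": ("Cenomanian", "Cenomanian"),
}

# The published age table gives Neovenator 131.5-124.0 Ma (uppermost
# Barremian material reaches into the earliest Aptian).
_EXPLICIT_INTERVALS = {"Neovenator": (131.5, 124.0)}


def allosauroid_age_table() -> AgeTable:
    """SYNTHETIC reconstruction of the case study's first-appearance
    intervals (Ma) from per-taxon stage assignments; see module docstring."""
    intervals = {}
    for taxon, (first, last) in _STAGE_ASSIGNMENTS.items():
        intervals[taxon] = _EXPLICIT_INTERVALS.get(
            taxon, stage_interval(first, last)
        )
    return AgeTable(intervals)


# ---------------------------------------------------------------------------
# synthetic study-scale matrix
# ---------------------------------------------------------------------------

# Per-taxon missing-data fractions echoing the reference analysis: the two
# best-known taxa at 0% and 6%, three fragmentary terminals above 80%, the
# worst at 91.5%.
STUDY_MISSINGNESS = {
    "Allosaurus": 0.0,
    "Acrocanthosaurus": 0.06,
    "Sinraptor": 0.10,
    "Monolophosaurus": 0.15,
    "Herrerasaurus": 0.20,
    "Tyrannosaurus": 0.20,
    "Giganotosaurus": 0.30,
    "Carcharodontosaurus": 0.35,
    "Piatnitzkysaurus": 0.40,
    "Coelophysoidea": 0.40,
    "Compsognathidae": 0.45,
    "Neovenator": 0.45,
    "Dilong": 0.50,
    "Mapusaurus": 0.55,
    "Shaochilong": 0.65,
    "Yangchuanosaurus": 0.82,
    "Eocarcharia": 0.85,
    "Tyrannotitan": 0.915,
}

STUDY_ORDERED_COUNT = 13


def study_like_matrix(seed: int = 0, tree: Optional[Tree] = None) -> CharacterMatrix:
    """Synthetic 18 x 177 matrix with the study's structure.

    177 characters, mostly binary with 13 ordered multistate characters,
    evolved on the reference topology (or a supplied tree) and masked to
    the study's per-taxon missing-data profile.
    """
    taxa = list(STUDY_MISSINGNESS)
    if tree is None:
        tree = reference_tree_with_outgroups()
        keep = [t for t in taxa if t in set(tree.leaf_labels())]
        assert sorted(keep) == sorted(tree.leaf_labels())
    return simulate_matrix(
        tree,
        n_char=177,
        n_states=3,
        change_prob=0.08,
        ordered_fraction=STUDY_ORDERED_COUNT / 177,
        missing_profile=STUDY_MISSINGNESS,
        seed=seed,
    )
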