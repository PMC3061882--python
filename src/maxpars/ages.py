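"""First-appearance-datum (FAD) age tables.

Ages are in Ma with larger = older.  Each taxon carries an interval
``[fad_min, fad_max]``: the youngest and oldest plausible age of its first
appearance, typically the boundaries of the geologic stage(s) its oldest
referred material is assigned to, including dating uncertainty.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Union

import pandas as pd

__all__ = ["AgeTable", "read_age_table", "STAGE_BOUNDARIES", "stage_interval"]

# Stage -> (older bound, younger bound) in Ma, Middle Jurassic to end
# Cretaceous, 2009-era International Stratigraphic Chart flavour.
STAGE_BOUNDARIES: dict[str, tuple[float, float]] = {
    "Aalenian": (175.6, 171.6),
    "Bajocian": (171.6, 167.7),
    "Bathonian": (167.7, 164.7),
    "Callovian": (164.7, 161.2),
    "Oxfordian": (161.2, 155.8),
    "Kimmeridgian": (155.8, 150.8),
    "Tithonian": (150.8, 145.5),
    "Berriasian": (145.5, 143.2),
    "Valanginian": (143.2, 133.9),
    "Hauterivian": (133.9, 131.5),
    "Barremian": (131.5, 125.0),
    "Aptian": (125.0, 112.0),
    "Albian": (112.0, 99.6),
    "Cenomanian": (99.6, 93.5),
    "Turonian": (93.5, 89.3),
    "Coniacian": (89.3, 85.8),
    "Santonian": (85.8, 83.5),
    "Campanian": (83.5, 70.6),
    "Maastrichtian": (70.6, 65.5),
}


def stage_interval(first_stage: str, last_stage: str | None = None) -> tuple[float, float]:
    """(fad_max, fad_min) spanned by one stage or an inclusive stage range."""
    last_stage = last_stage or first_stage
    try:
        older = STAGE_BOUNDARIES[first_stage][0]
        younger = STAGE_BOUNDARIES[last_stage][1]
    except KeyError as exc:
        raise KeyError(f"unknown stage {exc}") from exc
    return older, younger


class AgeTable:
    """Per-taxon first-appearance interval [fad_min, fad_max] in Ma."""

    def __init__(self, intervals: Mapping[str, tuple[float, float]]):
        self._fad_max: dict[str, float] = {}
        self._fad_min: dict[str, float] = {}
        for taxon, (fad_max, fad_min) in intervals.items():
            fad_max, fad_min = float(fad_max), float(fad_min)
            if not fad_max >= fad_min > 0:
                raise ValueError(
                    f"{taxon}: need fad_max >= fad_min > 0, got "
                    f"({fad_max}, {fad_min})"
                )
            self._fad_max[taxon] = fad_max
            self._fad_min[taxon] = fad_min

    @property
    def taxa(self) -> list[str]:
        return list(self._fad_max)

    def fad_max(self, taxon: str) -> float:
        return self._fad_max[taxon]

    def fad_min(self, taxon: str) -> float:
        return self._fad_min[taxon]

    def interval(self, taxon: str) -> tuple[float, float]:
        return self._fad_max[taxon], self._fad_min[taxon]

    def point_ages(self, which: str = "max") -> dict[str, float]:
        """Collapse intervals to single FADs ('max' = oldest bound, the
        reporting default; 'min' or 'mid' alternatively)."""
        if which == "max":
            return dict(self._fad_max)
        if which == "min":
            return dict(self._fad_min)
        if which == "mid":
            return {
                t: 0.5 * (self._fad_max[t] + self._fad_min[t]) for t in self._fad_max
            }
        raise ValueError("which must be 'max', 'min' or 'mid'")

    def subset(self, keep: Iterable[str]) -> "AgeTable":
        keep = list(keep)
        missing = [t for t in keep if t not in self._fad_max]
        if missing:
            raise KeyError(f"taxa without ages: {missing}")
        return AgeTable({t: (self._fad_max[t], self._fad_min[t]) for t in keep})

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.taxa,
                "fad_max": [self._fad_max[t] for t in self.taxa],
                "fad_min": [self._fad_min[t] for t in self.taxa],
            }
        )

    def __len__(self) -> int:
        return len(self._fad_max)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self._fad_max

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AgeTable)
            and self._fad_max == other._fad_max
            and self._fad_min == other._fad_min
        )


def read_age_table(path) -> AgeTable:
    """Read a delimited text file with taxon, fad_max, fad_min columns."""
    df = pd.read_csv(path, sep=None, engine="python")
    cols = {c.lower().strip(): c for c in df.columns}
    for needed in ("taxon", "fad_max", "fad_min"):
        if needed not in cols:
            raise ValueError(f"age table must have a '{needed}' column")
    intervals = {
        str(row[cols["taxon"]]): (row[cols["fad_max"]], row[cols["fad_min"]])
        for _, row in df.iterrows()
    }
    return AgeTable(intervals)


def write_age_table(table: AgeTable, path) -> None:
    table.to_frame().to_csv(path, index=False)
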