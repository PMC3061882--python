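"""Discrete morphological character matrices.

A :class:`CharacterMatrix` is a taxa x characters table of *state sets*:

* a singleton set is an ordinary fixed scoring,
* a multi-element set is a polymorphic scoring (``{01}`` in NEXUS,
  ``[01]`` in TNT),
* the empty set is a missing scoring (``?``; the inapplicable symbol ``-``
  is read as missing, the PAUP*/TNT default for parsimony).

Each character carries an ordering flag.  Unordered characters change state
at unit cost; ordered (additive) characters form a morphocline and cost the
absolute state difference.  Characters are numbered from 1 in every file
format and report; the Python API uses 0-based positions.

The readers and writers cover the small NEXUS and TNT ``xread`` subsets in
which morphological matrices actually circulate, including the
``ASSUMPTIONS``/``ccode`` ordering metadata that general-purpose libraries
drop.  ``write_matrix(read_matrix(f))`` is canonical and byte-stable.
"""

from __future__ import annotations

import re
from typing import Iterable, Optional, Sequence, Union

import numpy as np

__all__ = [
    "CharacterMatrix",
    "MatrixParseError",
    "read_matrix",
    "write_matrix",
    "MISSING",
]

MAX_STATE = 9
N_STATES = MAX_STATE + 1
FULL_MASK = (1 << N_STATES) - 1
MISSING: frozenset = frozenset()

Cell = frozenset


class MatrixParseError(ValueError):
    """A malformed matrix file; the message names the offending line."""


class DuplicateTaxonError(MatrixParseError):
    pass


class BadStateSymbolError(MatrixParseError):
    pass


def _as_cell(value) -> frozenset:
    if isinstance(value, (set, frozenset, list, tuple)):
        cell = frozenset(int(v) for v in value)
    elif value is None:
        cell = MISSING
    else:
        cell = frozenset([int(value)])
    for state in cell:
        if not (0 <= state <= MAX_STATE):
            raise ValueError(f"state {state} outside 0..{MAX_STATE}")
    return cell


class CharacterMatrix:
    """Taxa x characters table of state sets with ordering metadata."""

    def __init__(
        self,
        taxa: Sequence[str],
        cells: Sequence[Sequence],
        ordered: Optional[Iterable[int]] = None,
        partitions: Optional[Sequence[Optional[str]]] = None,
        active: Optional[Sequence[bool]] = None,
    ):
        self.taxa = list(taxa)
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("taxon labels must be unique")
        if not self.taxa:
            raise ValueError("matrix needs at least one taxon")
        self.cells: list[list[frozenset]] = [
            [_as_cell(c) for c in row] for row in cells
        ]
        n_char = len(self.cells[0]) if self.cells else 0
        if n_char == 0:
            raise ValueError("matrix needs at least one character")
        if any(len(row) != n_char for row in self.cells):
            raise ValueError("ragged matrix rows")
        if len(self.cells) != len(self.taxa):
            raise ValueError("row count does not match taxon count")
        self.n_char = n_char

        self._ordered = np.zeros(n_char, dtype=bool)
        if ordered is not None:
            for c in ordered:
                if not (0 <= c < n_char):
                    raise ValueError(f"ordered character position {c} out of range")
                self._ordered[c] = True

        self.partitions = list(partitions) if partitions is not None else [None] * n_char
        if len(self.partitions) != n_char:
            raise ValueError("partition labels do not match character count")
        self.active = (
            np.asarray(active, dtype=bool)
            if active is not None
            else np.ones(n_char, dtype=bool)
        )
        if self.active.shape != (n_char,):
            raise ValueError("active flags do not match character count")
        self._masks: Optional[np.ndarray] = None

    # -- basic accessors ---------------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxon_index(self, taxon: Union[str, int]) -> int:
        if isinstance(taxon, str):
            return self.taxa.index(taxon)
        return int(taxon)

    def cell(self, taxon: Union[str, int], c: int) -> frozenset:
        """State set of taxon x character (0-based character position)."""
        if not (0 <= c < self.n_char):
            raise IndexError(f"character position {c} out of range")
        return self.cells[self.taxon_index(taxon)][c]

    def ordering(self, c: int) -> str:
        return "ordered" if self._ordered[c] else "unordered"

    @property
    def ordered_flags(self) -> np.ndarray:
        return self._ordered.copy()

    @property
    def ordered_numbers(self) -> list[int]:
        """1-based numbers of the ordered characters (reporting convention)."""
        return [int(i) + 1 for i in np.flatnonzero(self._ordered)]

    def missing_fraction(self, taxon: Union[str, int]) -> float:
        row = self.cells[self.taxon_index(taxon)]
        return sum(1 for cell in row if not cell) / self.n_char

    # -- numeric view ------------------------------------------------------

    def state_masks(self) -> np.ndarray:
        """uint16 bitmask view, (n_taxa, n_char); missing cells allow any state."""
        if self._masks is None:
            masks = np.zeros((self.n_taxa, self.n_char), dtype=np.uint16)
            for t, row in enumerate(self.cells):
                for c, cell in enumerate(row):
                    if cell:
                        m = 0
                        for s in cell:
                            m |= 1 << s
                        masks[t, c] = m
                    else:
                        masks[t, c] = FULL_MASK
            self._masks = masks
        return self._masks

    # -- derived matrices ---------------------------------------------------

    def subset_taxa(self, keep: Iterable[str]) -> "CharacterMatrix":
        keep = list(keep)
        missing = set(keep) - set(self.taxa)
        if missing:
            raise ValueError(f"unknown taxa: {sorted(missing)}")
        rows = [self.cells[self.taxa.index(t)] for t in keep]
        return CharacterMatrix(
            keep,
            rows,
            ordered=list(np.flatnonzero(self._ordered)),
            partitions=self.partitions,
            active=self.active,
        )

    def select_characters(self, positions: Sequence[int]) -> "CharacterMatrix":
        """New matrix from 0-based character positions (with repetition allowed,
        as needed by bootstrap resampling)."""
        positions = [int(p) for p in positions]
        for p in positions:
            if not (0 <= p < self.n_char):
                raise IndexError(f"character position {p} out of range")
        rows = [[row[p] for p in positions] for row in self.cells]
        ordered = [i for i, p in enumerate(positions) if self._ordered[p]]
        return CharacterMatrix(
            self.taxa,
            rows,
            ordered=ordered,
            partitions=[self.partitions[p] for p in positions],
            active=[bool(self.active[p]) for p in positions],
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, CharacterMatrix)
            and self.taxa == other.taxa
            and self.cells == other.cells
            and bool(np.array_equal(self._ordered, other._ordered))
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<CharacterMatrix {self.n_taxa} taxa x {self.n_char} characters>"


# ---------------------------------------------------------------------------
# shared symbol handling
# ---------------------------------------------------------------------------

_OPEN_CLOSE = {"nexus": ("{", "}"), "tnt": ("[", "]")}


def _parse_row_symbols(
    seq: str, dialect: str, lineno: int, n_char_expected: Optional[int]
) -> list[frozenset]:
    opener, closer = _OPEN_CLOSE[dialect]
    cells: list[frozenset] = []
    i = 0
    while i < len(seq):
        ch = seq[i]
        if ch in " \t":
            i += 1
            continue
        if ch in "?-":
            cells.append(MISSING)
            i += 1
        elif ch.isdigit():
            cells.append(frozenset([int(ch)]))
            i += 1
        elif ch == opener:
            j = seq.find(closer, i)
            if j < 0:
                raise MatrixParseError(
                    f"line {lineno}: unterminated polymorphism starting at column {i + 1}"
                )
            states = seq[i + 1 : j]
            if not states or not all(s.isdigit() for s in states):
                raise BadStateSymbolError(
                    f"line {lineno}: bad polymorphic cell '{seq[i:j + 1]}'"
                )
            cells.append(frozenset(int(s) for s in states))
            i = j + 1
        else:
            raise BadStateSymbolError(
                f"line {lineno}: state symbol '{ch}' outside declared alphabet "
                f"(column {i + 1})"
            )
    if n_char_expected is not None and len(cells) != n_char_expected:
        raise MatrixParseError(
            f"line {lineno}: expected {n_char_expected} characters, found {len(cells)}"
        )
    return cells


def _format_cell(cell: frozenset, dialect: str) -> str:
    opener, closer = _OPEN_CLOSE[dialect]
    if not cell:
        return "?"
    if len(cell) == 1:
        return str(next(iter(cell)))
    return opener + "".join(str(s) for s in sorted(cell)) + closer


def _strip_comments(text: str) -> str:
    # NEXUS [...] comments; preserve line structure for error messages.
    out, depth = [], 0
    for ch in text:
        if ch == "[":
            depth += 1
        elif ch == "]" and depth:
            depth -= 1
        elif depth == 0 or ch == "\n":
            out.append(ch)
    return "".join(out)


# ---------------------------------------------------------------------------
# NEXUS
# ---------------------------------------------------------------------------


def _read_nexus(text: str) -> CharacterMatrix:
    clean = _strip_comments(text)
    if not clean.lstrip().upper().startswith("#NEXUS"):
        raise MatrixParseError("line 1: missing #NEXUS header")
    lines = clean.splitlines()

    ntax = nchar = None
    taxa: list[str] = []
    rows: list[list[frozenset]] = []
    ordered_1based: list[int] = []
    in_matrix = in_assumptions = False

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        upper = line.upper()
        if upper.startswith("DIMENSIONS"):
            m = re.search(r"NTAX\s*=\s*(\d+)", upper)
            ntax = int(m.group(1)) if m else None
            m = re.search(r"NCHAR\s*=\s*(\d+)", upper)
            nchar = int(m.group(1)) if m else None
            if nchar == 0 or ntax == 0:
                raise MatrixParseError(f"line {lineno}: empty dimensions")
        elif upper.startswith("MATRIX"):
            in_matrix = True
        elif upper.startswith("BEGIN ASSUMPTIONS"):
            in_assumptions = True
        elif in_assumptions and upper.startswith("TYPESET"):
            body = line.split("=", 1)
            if len(body) == 2:
                for part in body[1].rstrip(";").split(","):
                    part = part.strip()
                    if part.lower().startswith("ord:"):
                        ordered_1based.extend(
                            _expand_char_list(part[4:], lineno)
                        )
        elif in_matrix:
            if line == ";":
                in_matrix = False
                continue
            label, seq = _split_row(line, lineno)
            if label in taxa:
                raise DuplicateTaxonError(f"line {lineno}: duplicate taxon '{label}'")
            taxa.append(label)
            rows.append(_parse_row_symbols(seq.rstrip(";"), "nexus", lineno, nchar))
            if line.endswith(";"):
                in_matrix = False
        elif upper.startswith("END"):
            in_assumptions = False

    if not rows:
        raise MatrixParseError("no MATRIX block found")
    if ntax is not None and len(taxa) != ntax:
        raise MatrixParseError(
            f"NTAX={ntax} but {len(taxa)} taxon rows present"
        )
    n_char = len(rows[0])
    for c in ordered_1based:
        if not (1 <= c <= n_char):
            raise MatrixParseError(f"ordered character {c} out of range 1..{n_char}")
    return CharacterMatrix(taxa, rows, ordered=[c - 1 for c in ordered_1based])


def _split_row(line: str, lineno: int) -> tuple[str, str]:
    if line.startswith("'"):
        m = re.match(r"'((?:[^']|'')*)'\s+(.*)$", line)
        if not m:
            raise MatrixParseError(f"line {lineno}: unterminated quoted label")
        return m.group(1).replace("''", "'"), m.group(2)
    parts = line.split(None, 1)
    if len(parts) != 2:
        raise MatrixParseError(f"line {lineno}: matrix row needs label and states")
    return parts[0], parts[1]


def _expand_char_list(spec: str, lineno: int) -> list[int]:
    out = []
    for token in spec.replace(";", " ").split():
        if "-" in token:
            a, b = token.split("-", 1)
            try:
                out.extend(range(int(a), int(b) + 1))
            except ValueError:
                raise MatrixParseError(f"line {lineno}: bad character range '{token}'")
        else:
            try:
                out.append(int(token))
            except ValueError:
                raise MatrixParseError(f"line {lineno}: bad character number '{token}'")
    return out


def _write_nexus(matrix: CharacterMatrix) -> str:
    pad = max(len(_format_label(t)) for t in matrix.taxa) + 2
    lines = [
        "#NEXUS",
        "",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={matrix.n_taxa} NCHAR={matrix.n_char};",
        'FORMAT DATATYPE=STANDARD SYMBOLS="0123456789" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for t, row in zip(matrix.taxa, matrix.cells):
        seq = "".join(_format_cell(c, "nexus") for c in row)
        lines.append(f"{_format_label(t):<{pad}}{seq}")
    lines.append(";")
    lines.append("END;")
    ordered = matrix.ordered_numbers
    if ordered:
        unordered = [c for c in range(1, matrix.n_char + 1) if c not in set(ordered)]
        lines.append("")
        lines.append("BEGIN ASSUMPTIONS;")
        lines.append("OPTIONS DEFTYPE=unord;")
        typeset = "TYPESET * default = ord: " + " ".join(str(c) for c in ordered)
        if unordered:
            typeset += ", unord: " + _compact_ranges(unordered)
        lines.append(typeset + ";")
        lines.append("END;")
    return "\n".join(lines) + "\n"


def _format_label(label: str) -> str:
    if re.fullmatch(r"[\w.]+", label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _compact_ranges(numbers: list[int]) -> str:
    out, start, prev = [], None, None
    for n in numbers:
        if start is None:
            start = prev = n
        elif n == prev + 1:
            prev = n
        else:
            out.append(f"{start}-{prev}" if prev > start else str(start))
            start = prev = n
    if start is not None:
        out.append(f"{start}-{prev}" if prev > start else str(start))
    return " ".join(out)


# ---------------------------------------------------------------------------
# TNT xread
# ---------------------------------------------------------------------------


def _read_tnt(text: str) -> CharacterMatrix:
    lines = text.splitlines()
    it = iter(enumerate(lines, start=1))
    header = None
    for lineno, raw in it:
        line = raw.strip()
        if not line or line.startswith("'"):
            continue
        if line.lower().startswith("xread"):
            rest = line[5:].strip()
            header = rest
            break
    else:
        raise MatrixParseError("no xread statement found")

    while not header:
        lineno, raw = next(it, (None, None))
        if raw is None:
            raise MatrixParseError("xread: missing dimensions")
        header = raw.strip()
        if header.startswith("'"):
            header = ""
    m = re.match(r"(\d+)\s+(\d+)", header)
    if not m:
        raise MatrixParseError(f"line {lineno}: xread needs 'nchar ntax'")
    nchar, ntax = int(m.group(1)), int(m.group(2))

    taxa, rows = [], []
    ordered_0based: list[int] = []
    matrix_done = False
    for lineno, raw in it:
        line = raw.strip()
        if not line:
            continue
        if not matrix_done:
            if line == ";":
                matrix_done = True
                continue
            label, seq = _split_row(line.rstrip(";"), lineno)
            if label in taxa:
                raise DuplicateTaxonError(f"line {lineno}: duplicate taxon '{label}'")
            taxa.append(label)
            rows.append(_parse_row_symbols(seq, "tnt", lineno, nchar))
            if line.endswith(";"):
                matrix_done = True
        elif line.lower().startswith("ccode"):
            body = line[5:].rstrip(";")
            mode = None
            for token in body.split():
                if token in "+-[]/*":
                    mode = token
                elif token.isdigit() and mode == "+":
                    ordered_0based.append(int(token))

    if len(taxa) != ntax:
        raise MatrixParseError(f"xread declared {ntax} taxa, found {len(taxa)}")
    for c in ordered_0based:
        if not (0 <= c < nchar):
            raise MatrixParseError(f"ccode character {c} out of range 0..{nchar - 1}")
    return CharacterMatrix(taxa, rows, ordered=ordered_0based)


def _write_tnt(matrix: CharacterMatrix) -> str:
    pad = max(len(_format_label(t)) for t in matrix.taxa) + 2
    lines = [
        "xread",
        f"{matrix.n_char} {matrix.n_taxa}",
    ]
    for t, row in zip(matrix.taxa, matrix.cells):
        seq = "".join(_format_cell(c, "tnt") for c in row)
        lines.append(f"{_format_label(t):<{pad}}{seq}")
    lines.append(";")
    ordered = np.flatnonzero(matrix.ordered_flags)
    if ordered.size:
        lines.append("ccode + " + " ".join(str(int(c)) for c in ordered) + ";")
    lines.append("proc /;")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------


def read_matrix(path, dialect: str = "nexus") -> CharacterMatrix:
    """Read a character matrix from ``path`` in the named dialect."""
    with open(path) as fh:
        text = fh.read()
    return parse_matrix(text, dialect)


def parse_matrix(text: str, dialect: str = "nexus") -> CharacterMatrix:
    if dialect == "nexus":
        return _read_nexus(text)
    if dialect == "tnt":
        return _read_tnt(text)
    raise ValueError(f"unknown dialect '{dialect}'")


def format_matrix(matrix: CharacterMatrix, dialect: str = "nexus") -> str:
    if dialect == "nexus":
        return _write_nexus(matrix)
    if dialect == "tnt":
        return _write_tnt(matrix)
    raise ValueError(f"unknown dialect '{dialect}'")


def write_matrix(matrix: CharacterMatrix, path, dialect: str = "nexus") -> None:
    with open(path, "w") as fh:
        fh.write(format_matrix(matrix, dialect))
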