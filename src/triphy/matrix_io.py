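"""Reading, writing, validation and canonicalization of character matrices.

A character matrix holds ``n`` taxa (rows) over ``m`` characters (columns),
each character taking at most three discrete states.  After canonicalization
each column's states are exactly ``{0, ..., k-1}`` (``k <= 3``), indexed by
order of first appearance down the column.  Missing values are rejected:
every taxon must be a full species.
"""

from __future__ import annotations

import csv
import io
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import FormatError, MissingValueError, StateArityError

logger = logging.getLogger(__name__)

#: Marker for an unassigned character state in a species (renders as ``*``).
MISSING: int = -1

#: Symbols interpreted as missing values on input.
MISSING_SYMBOLS = frozenset({"*", "?"})

MAX_STATES = 3

FORMATS = ("csv", "tsv", "phylip_digits")


@dataclass(frozen=True)
class CharacterMatrix:
    """An ``n x m`` matrix of canonical small-integer states.

    Attributes
    ----------
    taxa_ids:
        Row (taxon) names, length ``n``.
    character_ids:
        Column (character) names, length ``m``.
    states:
        ``(n, m)`` integer array; entry ``(t, c)`` is the state of taxon
        ``t`` at character ``c``.
    dropped_characters:
        Names of constant columns removed during canonicalization
        (provenance note; trivially compatible characters carry no signal).
    """

    taxa_ids: tuple[str, ...]
    character_ids: tuple[str, ...]
    states: np.ndarray
    dropped_characters: tuple[str, ...] = field(default=(), compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.states, dtype=np.int64)
        arr.setflags(write=False)
        object.__setattr__(self, "states", arr)
        if arr.ndim != 2:
            raise FormatError("state grid must be two-dimensional")
        n, m = arr.shape
        if n < 1 or m < 1:
            raise FormatError("matrix must have at least one taxon and one character")
        if len(self.taxa_ids) != n or len(self.character_ids) != m:
            raise FormatError("taxa/character id counts do not match the state grid")
        if (arr < 0).any():
            raise MissingValueError("missing values are not permitted")
        for c in range(m):
            col = arr[:, c]
            k = len(np.unique(col))
            if k > MAX_STATES:
                raise StateArityError(
                    f"character {self.character_ids[c]!r} has {k} states (max {MAX_STATES})"
                )
            if col.max() != k - 1:
                raise FormatError(
                    f"character {self.character_ids[c]!r} is not canonical"
                )

    # ------------------------------------------------------------------ #

    @property
    def n(self) -> int:
        return self.states.shape[0]

    @property
    def m(self) -> int:
        return self.states.shape[1]

    def num_states(self, c: int) -> int:
        """Number of canonical states of character ``c``."""
        return int(self.states[:, c].max()) + 1

    def column(self, c: int) -> np.ndarray:
        return self.states[:, c]

    def row(self, t: int) -> np.ndarray:
        return self.states[t, :]

    def submatrix(self, characters: Sequence[int]) -> "CharacterMatrix":
        """Column-restricted matrix (states re-canonicalized)."""
        chars = list(characters)
        return from_rows(
            self.states[:, chars],
            taxa_ids=self.taxa_ids,
            character_ids=[self.character_ids[c] for c in chars],
            drop_constant=False,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        return (
            self.taxa_ids == other.taxa_ids
            and self.character_ids == other.character_ids
            and np.array_equal(self.states, other.states)
        )

    def __hash__(self) -> int:
        return hash((self.taxa_ids, self.character_ids, self.states.tobytes()))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"CharacterMatrix(n={self.n}, m={self.m})"


def canonical_column(symbols: Iterable) -> list[int]:
    """Map a column's symbols to dense 0-based state indices.

    Columns whose symbols already are the integers ``{0, ..., k-1}`` are
    kept verbatim (so numeric matrices round-trip exactly); any other
    symbol set is mapped by order of first appearance down the column.
    """
    syms = list(symbols)
    try:
        ints = [int(s) for s in syms]
    except (TypeError, ValueError):
        ints = None
    if ints is not None and set(ints) == set(range(max(ints) + 1)):
        return ints
    mapping: dict = {}
    out = []
    for s in syms:
        if s not in mapping:
            mapping[s] = len(mapping)
        out.append(mapping[s])
    return out


def from_rows(
    rows,
    taxa_ids: Sequence[str] | None = None,
    character_ids: Sequence[str] | None = None,
    drop_constant: bool = False,
) -> CharacterMatrix:
    """Build a canonical matrix from raw row data of arbitrary symbols.

    Symbols equal to a missing marker raise :class:`MissingValueError`.
    With ``drop_constant``, single-state columns are removed (and logged).
    """
    grid = [list(r) for r in rows]
    if not grid or not grid[0]:
        raise FormatError("matrix must have at least one taxon and one character")
    m = len(grid[0])
    if any(len(r) != m for r in grid):
        raise FormatError("ragged rows")
    n = len(grid)
    for r in grid:
        for cell in r:
            if isinstance(cell, str) and cell.strip() in MISSING_SYMBOLS:
                raise MissingValueError("matrix contains a missing value marker")
    taxa = tuple(taxa_ids) if taxa_ids is not None else tuple(f"t{i+1}" for i in range(n))
    chars = (
        tuple(character_ids)
        if character_ids is not None
        else tuple(f"c{j+1}" for j in range(m))
    )
    cols = []
    kept_ids = []
    dropped = []
    for j in range(m):
        col = canonical_column(grid[i][j] for i in range(n))
        if drop_constant and max(col) == 0:
            dropped.append(chars[j])
            continue
        cols.append(col)
        kept_ids.append(chars[j])
    if dropped:
        logger.warning(
            "dropped %d constant character(s): %s", len(dropped), ", ".join(map(str, dropped))
        )
    if not cols:
        raise FormatError("all characters are constant; nothing to analyze")
    states = np.array(cols, dtype=np.int64).T
    return CharacterMatrix(taxa, tuple(kept_ids), states, tuple(dropped))


# ---------------------------------------------------------------------- #
# I/O

def _read_delimited(text: str, delimiter: str) -> CharacterMatrix:
    reader = csv.reader(io.StringIO(text), delimiter=delimiter)
    table = [row for row in reader if row and any(cell.strip() for cell in row)]
    if len(table) < 2:
        raise FormatError("need a header row and at least one taxon row")
    header = table[0]
    if len(header) < 2:
        raise FormatError("need at least one character column")
    char_ids = [h.strip() for h in header[1:]]
    taxa_ids = []
    rows = []
    for row in table[1:]:
        if len(row) != len(header):
            raise FormatError(f"row {row[0]!r} has {len(row)-1} cells, expected {len(char_ids)}")
        taxa_ids.append(row[0].strip())
        rows.append([cell.strip() for cell in row[1:]])
    return from_rows(rows, taxa_ids, char_ids, drop_constant=True)


def _read_phylip_digits(text: str) -> CharacterMatrix:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if not lines:
        raise FormatError("empty input")
    head = lines[0].split()
    if len(head) != 2:
        raise FormatError("phylip_digits header must be 'n m'")
    try:
        n, m = int(head[0]), int(head[1])
    except ValueError as exc:
        raise FormatError("phylip_digits header must be two integers") from exc
    body = lines[1:]
    if len(body) != n:
        raise FormatError(f"expected {n} taxon lines, found {len(body)}")
    taxa_ids = []
    rows = []
    for ln in body:
        parts = ln.split(None, 1)
        if len(parts) != 2:
            raise FormatError(f"malformed taxon line: {ln!r}")
        name, seq = parts[0], parts[1].replace(" ", "")
        if len(seq) != m:
            raise FormatError(f"taxon {name!r} has {len(seq)} sites, expected {m}")
        for ch in seq:
            if ch in MISSING_SYMBOLS:
                raise MissingValueError("matrix contains a missing value marker")
            if not ch.isdigit():
                raise FormatError(f"non-digit state symbol {ch!r} in phylip_digits input")
        taxa_ids.append(name)
        rows.append(list(seq))
    return from_rows(rows, taxa_ids, None, drop_constant=True)


def read_matrix(source, format: str = "csv") -> CharacterMatrix:
    """Read a validated, canonicalized matrix from a stream, path or string.

    ``format`` is one of ``csv``, ``tsv`` or ``phylip_digits``.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
    if isinstance(text, bytes):
        text = text.decode("utf-8")
    if format == "csv":
        return _read_delimited(text, ",")
    if format == "tsv":
        return _read_delimited(text, "\t")
    if format == "phylip_digits":
        return _read_phylip_digits(text)
    raise FormatError(f"unknown format {format!r}")


def write_matrix(M: CharacterMatrix, format: str = "csv") -> str:
    """Serialize ``M``; ``read_matrix(write_matrix(M), format)`` round-trips."""
    if format in ("csv", "tsv"):
        delim = "," if format == "csv" else "\t"
        out = io.StringIO()
        writer = csv.writer(out, delimiter=delim, lineterminator="\n")
        writer.writerow(["taxon", *M.character_ids])
        for t in range(M.n):
            writer.writerow([M.taxa_ids[t], *map(int, M.states[t])])
        return out.getvalue()
    if format == "phylip_digits":
        if M.states.max() > 9:  # cannot occur with r <= 3; defensive
            raise FormatError("phylip_digits requires single-digit states")
        lines = [f"{M.n} {M.m}"]
        for t in range(M.n):
            lines.append(f"{M.taxa_ids[t]} " + "".join(str(int(s)) for s in M.states[t]))
        return "\n".join(lines) + "\n"
    raise FormatError(f"unknown format {format!r}")


def species_string(species: Sequence[int]) -> str:
    """Render a species as e.g. ``0,1,*`` (``*`` marks MISSING)."""
    return ",".join("*" if s == MISSING else str(int(s)) for s in species)


# ---------------------------------------------------------------------- #
# Packaged fixtures

def fixtures() -> dict[str, CharacterMatrix]:
    """Small reference matrices used throughout the test suite.

    F1, F2, F3 are compatible; F4 fails the pairwise (four-gamete style)
    screen; F5 passes it yet is incompatible (its graph carries a chordless
    5-cycle).
    """
    def mk(rows, taxa):
        # states are already 0-based and dense; keep them verbatim rather
        # than remapping by first appearance
        arr = np.array(rows, dtype=np.int64)
        chars = tuple(f"c{j+1}" for j in range(arr.shape[1]))
        return CharacterMatrix(tuple(taxa), chars, arr)

    return {
        "F1": mk([(0, 0, 1), (1, 0, 2), (1, 1, 0), (0, 2, 0)], ["t1", "t2", "t3", "t4"]),
        "F2": mk([(0, 0, 0), (1, 0, 0), (1, 1, 0), (1, 1, 1)], ["a", "b", "c", "d"]),
        "F3": mk([(0, 0), (1, 1), (2, 2)], ["t1", "t2", "t3"]),
        "F4": mk([(0, 0), (0, 1), (1, 1), (1, 0)], ["t1", "t2", "t3", "t4"]),
        "F5": mk(
            [(0, 0, 1), (1, 0, 1), (1, 2, 0), (2, 1, 0), (0, 1, 1)],
            ["t1", "t2", "t3", "t4", "t5"],
        ),
    }
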