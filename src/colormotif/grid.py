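"""Munsell chip grid, naming-task file parsing, and per-participant naming matrices.

The World Color Survey (WCS) stimulus array has 330 Munsell chips: 8 chromatic
lightness rows (letters B through I) spanning 40 hue columns, plus 10
achromatic chips (rows A through J at column 0).  Naming-task files are long
lists of ``language  speaker  chip  term`` records, one per line.  This module
parses such files, applies the standard filtering (drop excluded languages,
keep only the 320 chromatic chips) and formats each participant's responses
into a binary term-by-chip *naming matrix* with exactly one term per chip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

logger = logging.getLogger("colormotif")

#: Chromatic lightness rows, top (light) to bottom (dark).
CHROMATIC_ROWS = "BCDEFGHI"
N_COLS = 40
N_CHROMATIC = len(CHROMATIC_ROWS) * N_COLS  # 320
N_CHIPS = 330


class GridError(ValueError):
    """Raised for inconsistent chip-map definitions."""


class TermFileError(ValueError):
    """Raised for malformed naming-task files; carries offending line numbers."""

    def __init__(self, message: str, lines: Sequence[int] = ()):  # pragma: no cover - trivial
        super().__init__(message)
        self.lines = tuple(lines)


class IncompleteNamingError(ValueError):
    """A participant did not name every chromatic chip."""

    def __init__(self, participant_key, missing_chips: Sequence[int]):
        self.participant_key = participant_key
        self.missing_chips = tuple(missing_chips)
        super().__init__(
            f"participant {participant_key} is missing {len(missing_chips)} "
            f"chromatic chip(s): {list(missing_chips)[:10]}"
        )


class ConflictingNamingError(ValueError):
    """A participant named the same chip with two different terms."""


@dataclass(frozen=True)
class ChipGrid:
    """Bijection between chip numbers and (row, column) cells of the stimulus grid.

    ``chip_to_cell`` maps a chromatic chip number to ``(row_index, col)`` with
    ``row_index`` in ``0..7`` (row B is 0) and ``col`` in ``1..40``.
    ``achromatic_ids`` holds the 10 neutral chips (rows A/J and column 0),
    which are excluded from all analyses.
    """

    chip_to_cell: Mapping[int, tuple[int, int]]
    achromatic_ids: frozenset[int]
    cell_to_chip: Mapping[tuple[int, int], int] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        cells = set(self.chip_to_cell.values())
        expected = {(r, c) for r in range(len(CHROMATIC_ROWS)) for c in range(1, N_COLS + 1)}
        if cells != expected:
            raise GridError(
                f"chip map must cover exactly the {N_CHROMATIC} chromatic cells; "
                f"missing {len(expected - cells)}, extra {len(cells - expected)}"
            )
        if len(self.chip_to_cell) != N_CHROMATIC:
            raise GridError("chip map is not one-to-one over chromatic cells")
        if self.achromatic_ids & set(self.chip_to_cell):
            raise GridError("achromatic chips cannot occupy chromatic cells")
        object.__setattr__(
            self, "cell_to_chip", {cell: chip for chip, cell in self.chip_to_cell.items()}
        )

    @classmethod
    def default(cls) -> "ChipGrid":
        """Canonical synthetic numbering: chips 1..320 row-major over (B..I) x (1..40),
        achromatic chips 321..330 (rows A..J at column 0)."""
        mapping = {}
        chip = 1
        for r in range(len(CHROMATIC_ROWS)):
            for c in range(1, N_COLS + 1):
                mapping[chip] = (r, c)
                chip += 1
        return cls(
            chip_to_cell=mapping,
            achromatic_ids=frozenset(range(N_CHROMATIC + 1, N_CHIPS + 1)),
        )

    @classmethod
    def from_chip_map(cls, path) -> "ChipGrid":
        """Read a chip-map file: ``chip  row_letter  column`` per line.

        Rows A/J and column 0 denote achromatic chips.
        """
        chip_to_cell: dict[int, tuple[int, int]] = {}
        achromatic: set[int] = set()
        bad: list[int] = []
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
            line = raw.strip()
            if not line:
                continue
            parts = line.split()
            try:
                chip = int(parts[0])
                row_letter = parts[1].upper()
                col = int(parts[2])
            except (IndexError, ValueError):
                bad.append(lineno)
                continue
            if not (1 <= chip <= N_CHIPS):
                bad.append(lineno)
                continue
            if col == 0 or row_letter in ("A", "J"):
                achromatic.add(chip)
            elif row_letter in CHROMATIC_ROWS and 1 <= col <= N_COLS:
                chip_to_cell[chip] = (CHROMATIC_ROWS.index(row_letter), col)
            else:
                bad.append(lineno)
        if bad:
            raise TermFileError(f"malformed chip-map lines: {bad[:20]}", bad)
        return cls(chip_to_cell=chip_to_cell, achromatic_ids=frozenset(achromatic))

    def is_chromatic(self, chip: int) -> bool:
        return chip in self.chip_to_cell

    def canonical_chips(self) -> list[int]:
        """Chip numbers in canonical order: row-major over (B..I) x (1..40)."""
        return [
            self.cell_to_chip[(r, c)]
            for r in range(len(CHROMATIC_ROWS))
            for c in range(1, N_COLS + 1)
        ]

    def canonical_index(self, chip: int) -> int:
        r, c = self.chip_to_cell[chip]
        return r * N_COLS + (c - 1)

    def write_chip_map(self, path) -> None:
        lines = []
        for chip, (r, c) in sorted(self.chip_to_cell.items()):
            lines.append(f"{chip}\t{CHROMATIC_ROWS[r]}\t{c}")
        # achromatic chips listed at column 0; row letters cycle A..J
        letters = "ABCDEFGHIJ"
        for i, chip in enumerate(sorted(self.achromatic_ids)):
            lines.append(f"{chip}\t{letters[i % 10]}\t0")
        Path(path).write_text("\n".join(lines) + "\n")


@dataclass(frozen=True)
class NamingRecord:
    """One naming response: participant ``(language, speaker)`` called ``chip`` by ``term``."""

    language: int
    speaker: int
    chip: int
    term: str

    def __post_init__(self):
        if self.language <= 0 or self.speaker <= 0:
            raise ValueError("language and speaker numbers must be positive")
        if not (1 <= self.chip <= N_CHIPS):
            raise ValueError(f"chip number {self.chip} outside 1..{N_CHIPS}")
        if not self.term:
            raise ValueError("empty term token")


@dataclass(frozen=True)
class NamingMatrix:
    """A participant's term-by-chip binary matrix over the 320 chromatic chips.

    Rows are the participant's distinct terms in first-appearance order over
    the canonical chip order; every column sums to exactly one.
    """

    participant_key: tuple[int, int]
    terms: tuple[str, ...]
    matrix: np.ndarray  # (n_terms, 320) uint8

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=np.uint8)
        if m.ndim != 2 or m.shape != (len(self.terms), N_CHROMATIC):
            raise ValueError(f"matrix must be (n_terms, {N_CHROMATIC})")
        if not np.isin(m, (0, 1)).all():
            raise ValueError("matrix entries must be binary")
        if not (m.sum(axis=0) == 1).all():
            raise ValueError("every chip column must carry exactly one term")
        if len(set(self.terms)) != len(self.terms):
            raise ValueError("terms must be distinct")
        object.__setattr__(self, "matrix", m)

    @property
    def n_terms(self) -> int:
        return len(self.terms)

    def labels(self) -> np.ndarray:
        """Per-chip term-row index, length 320, in canonical chip order."""
        return self.matrix.argmax(axis=0)

    def term_of_chip(self, canonical_idx: int) -> str:
        return self.terms[int(self.matrix[:, canonical_idx].argmax())]

    @classmethod
    def from_labels(
        cls, participant_key, labels: Sequence, term_names: Mapping | None = None
    ) -> "NamingMatrix":
        """Build from a length-320 per-chip label sequence (any hashable labels)."""
        labels = list(labels)
        if len(labels) != N_CHROMATIC:
            raise ValueError(f"need {N_CHROMATIC} labels, got {len(labels)}")
        order: dict = {}
        for lab in labels:
            if lab not in order:
                order[lab] = len(order)
        m = np.zeros((len(order), N_CHROMATIC), dtype=np.uint8)
        for j, lab in enumerate(labels):
            m[order[lab], j] = 1
        if term_names is None:
            terms = tuple(str(lab) for lab in order)
        else:
            terms = tuple(str(term_names[lab]) for lab in order)
        return cls(participant_key=tuple(participant_key), terms=terms, matrix=m)


# ---------------------------------------------------------------------------
# File parsing and filtering
# ---------------------------------------------------------------------------

def read_term_file(path, chip_map: ChipGrid | None = None) -> list[NamingRecord]:
    """Parse a WCS-style naming-task file into records.

    Lines are tab- or whitespace-delimited ``language speaker chip term`` with
    no header; blank lines are ignored.  All malformed lines are collected and
    reported together with their line numbers.
    """
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"term file not found: {path}")
    records: list[NamingRecord] = []
    bad: list[tuple[int, str]] = []
    for lineno, raw in enumerate(p.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            bad.append((lineno, "expected 4 fields"))
            continue
        try:
            rec = NamingRecord(
                language=int(parts[0]),
                speaker=int(parts[1]),
                chip=int(parts[2]),
                term=parts[3],
            )
        except ValueError as exc:
            bad.append((lineno, str(exc)))
            continue
        records.append(rec)
    if bad:
        detail = "; ".join(f"line {ln}: {msg}" for ln, msg in bad[:10])
        raise TermFileError(
            f"{len(bad)} malformed line(s) in {path}: {detail}", [ln for ln, _ in bad]
        )
    return records


def filter_corpus(
    records: Iterable[NamingRecord],
    excluded_languages: Iterable[int] = (),
    chip_grid: ChipGrid | None = None,
) -> list[NamingRecord]:
    """Drop records from excluded languages and records on achromatic chips.

    Order is preserved and the operation is idempotent.  The excluded-language
    set is user-supplied configuration (default empty).
    """
    grid = chip_grid or ChipGrid.default()
    excluded = set(excluded_languages)
    return [
        r for r in records if r.language not in excluded and grid.is_chromatic(r.chip)
    ]


def group_by_participant(
    records: Iterable[NamingRecord],
) -> dict[tuple[int, int], list[NamingRecord]]:
    """Group records by ``(language, speaker)`` preserving record order."""
    groups: dict[tuple[int, int], list[NamingRecord]] = {}
    for r in records:
        groups.setdefault((r.language, r.speaker), []).append(r)
    return groups


def build_naming_matrix(
    records: Iterable[NamingRecord], chip_grid: ChipGrid | None = None
) -> NamingMatrix:
    """Assemble one participant's naming matrix from their chromatic-chip records.

    Raises :class:`IncompleteNamingError` if any chromatic chip is unnamed and
    :class:`ConflictingNamingError` if a chip carries two different terms.
    """
    grid = chip_grid or ChipGrid.default()
    records = list(records)
    if not records:
        raise IncompleteNamingError(None, grid.canonical_chips())
    keys = {(r.language, r.speaker) for r in records}
    if len(keys) != 1:
        raise ValueError(f"records span multiple participants: {sorted(keys)}")
    key = keys.pop()
    term_of: dict[int, str] = {}
    for r in records:
        if not grid.is_chromatic(r.chip):
            continue
        idx = grid.canonical_index(r.chip)
        if idx in term_of and term_of[idx] != r.term:
            raise ConflictingNamingError(
                f"participant {key}: chip {r.chip} named both "
                f"'{term_of[idx]}' and '{r.term}'"
            )
        term_of[idx] = r.term
    missing = sorted(set(range(N_CHROMATIC)) - set(term_of))
    if missing:
        chips = grid.canonical_chips()
        raise IncompleteNamingError(key, [chips[i] for i in missing])
    labels = [term_of[i] for i in range(N_CHROMATIC)]
    return NamingMatrix.from_labels(key, labels)


def build_corpus_matrices(
    records: Iterable[NamingRecord], chip_grid: ChipGrid | None = None
) -> list[NamingMatrix]:
    """Naming matrices for every participant, in first-appearance order.

    Participants with incomplete chromatic naming are dropped with a warning
    (the downstream transform requires a total labeling); conflicts still raise.
    """
    grid = chip_grid or ChipGrid.default()
    matrices = []
    for key, recs in group_by_participant(records).items():
        try:
            matrices.append(build_naming_matrix(recs, grid))
        except IncompleteNamingError as exc:
            logger.warning(
                "dropping participant %s: %d chromatic chips unnamed",
                key,
                len(exc.missing_chips),
            )
    return matrices


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def write_naming_matrix(nm: NamingMatrix, path) -> None:
    """Delimited text: one row per term — term token then 320 binary columns."""
    with open(path, "w") as fh:
        fh.write(f"# participant\t{nm.participant_key[0]}\t{nm.participant_key[1]}\n")
        for t, row in zip(nm.terms, nm.matrix):
            fh.write(t + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def read_naming_matrix(path) -> NamingMatrix:
    terms: list[str] = []
    rows: list[list[int]] = []
    key = (1, 1)
    for raw in Path(path).read_text().splitlines():
        if raw.startswith("#"):
            parts = raw.split("\t")
            key = (int(parts[1]), int(parts[2]))
            continue
        parts = raw.split("\t")
        terms.append(parts[0])
        rows.append([int(v) for v in parts[1:]])
    return NamingMatrix(
        participant_key=key, terms=tuple(terms), matrix=np.array(rows, dtype=np.uint8)
    )
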