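"""Neighbor-agreement feature vectors over the chromatic chip grid.

Each participant's naming matrix is reduced to a binary vector indexed by
pairs of grid-adjacent chips: an entry is 1 when the participant gave both
chips of the pair the same term.  The vector depends only on the *partition*
of the grid, never on the term strings, which makes participants comparable
across languages.

The pair set is controlled by a :class:`NeighborScheme`: a von Neumann
(4-cell) or Moore (8-cell) neighborhood, directed (both orientations of each
pair stored) or undirected, with or without hue wraparound (column 40
adjacent to column 1; rows never wrap).  The default scheme — Moore
8-neighborhood, directed, with wraparound — yields 2,320 attributes over the
320 chromatic chips: the six interior rows contribute 40 x 8 ordered pairs
each and the two edge rows (B and I) 40 x 5 each.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np

from .grid import CHROMATIC_ROWS, N_COLS, ChipGrid, NamingMatrix

#: Fixed neighbor-offset order: (drow, dcol) for N, S, E, W, NE, NW, SE, SW.
_OFFSETS = {
    "von_neumann_4": ((-1, 0), (1, 0), (0, 1), (0, -1)),
    "moore_8": (
        (-1, 0), (1, 0), (0, 1), (0, -1),
        (-1, 1), (-1, -1), (1, 1), (1, -1),
    ),
}

N_ROWS = len(CHROMATIC_ROWS)


@dataclass(frozen=True)
class NeighborScheme:
    """Grid-adjacency scheme; fully determines the pair set."""

    kind: str = "moore_8"
    directed: bool = True
    hue_wraparound: bool = True

    def __post_init__(self):
        if self.kind not in _OFFSETS:
            raise ValueError(f"unknown neighborhood kind: {self.kind!r}")

    def offsets(self) -> tuple[tuple[int, int], ...]:
        return _OFFSETS[self.kind]

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "directed": self.directed,
            "hue_wraparound": self.hue_wraparound,
        }


DEFAULT_SCHEME = NeighborScheme()


def _neighbor_cell(r: int, c: int, dr: int, dc: int, wrap: bool):
    """Neighboring (row, col) or None if it falls off the grid. Rows never wrap."""
    nr = r + dr
    if not (0 <= nr < N_ROWS):
        return None
    nc = c + dc
    if wrap:
        nc = (nc - 1) % N_COLS + 1
    elif not (1 <= nc <= N_COLS):
        return None
    return nr, nc


@dataclass(frozen=True)
class PairIndex:
    """Ordered list of (reference chip, neighbor chip) comparisons.

    Reference chips run in canonical chip order; for each reference the
    neighbors follow the fixed offset order N, S, E, W, NE, NW, SE, SW (as
    applicable).  Undirected schemes keep each unordered pair once, at its
    first occurrence.
    """

    scheme: NeighborScheme
    pairs: tuple[tuple[int, int], ...]
    #: canonical chip indices (0..319) of each pair's two chips
    i_idx: np.ndarray
    j_idx: np.ndarray

    @property
    def dimension(self) -> int:
        return len(self.pairs)

    def undirected_view(self) -> "PairIndex":
        """The same pair set with one orientation per unordered pair."""
        if not self.scheme.directed:
            return self
        seen = set()
        keep = []
        for p, (a, b) in enumerate(self.pairs):
            key = frozenset((a, b))
            if key not in seen:
                seen.add(key)
                keep.append(p)
        keep = np.array(keep, dtype=np.int64)
        return PairIndex(
            scheme=NeighborScheme(self.scheme.kind, False, self.scheme.hue_wraparound),
            pairs=tuple(self.pairs[p] for p in keep),
            i_idx=self.i_idx[keep],
            j_idx=self.j_idx[keep],
        )


def build_pair_index(
    scheme: NeighborScheme = DEFAULT_SCHEME, grid: ChipGrid | None = None
) -> PairIndex:
    """Enumerate the adjacency pairs of the chromatic grid under ``scheme``."""
    grid = grid or ChipGrid.default()
    pairs: list[tuple[int, int]] = []
    seen: set[frozenset] = set()
    for chip in grid.canonical_chips():
        r, c = grid.chip_to_cell[chip]
        for dr, dc in scheme.offsets():
            cell = _neighbor_cell(r, c, dr, dc, scheme.hue_wraparound)
            if cell is None:
                continue
            nb = grid.cell_to_chip[cell]
            if scheme.directed:
                pairs.append((chip, nb))
            else:
                key = frozenset((chip, nb))
                if key not in seen:
                    seen.add(key)
                    pairs.append((chip, nb))
    i_idx = np.array([grid.canonical_index(a) for a, _ in pairs], dtype=np.int64)
    j_idx = np.array([grid.canonical_index(b) for _, b in pairs], dtype=np.int64)
    return PairIndex(scheme=scheme, pairs=tuple(pairs), i_idx=i_idx, j_idx=j_idx)


def neighbor_count(
    chip: int, scheme: NeighborScheme = DEFAULT_SCHEME, grid: ChipGrid | None = None
) -> int:
    """Number of grid-adjacent chromatic chips of ``chip`` under the scheme."""
    grid = grid or ChipGrid.default()
    if not grid.is_chromatic(chip):
        raise ValueError(f"chip {chip} is not chromatic")
    r, c = grid.chip_to_cell[chip]
    return sum(
        _neighbor_cell(r, c, dr, dc, scheme.hue_wraparound) is not None
        for dr, dc in scheme.offsets()
    )


@dataclass(frozen=True)
class FeatureMatrix:
    """N participants x P binary neighbor-agreement attributes."""

    participant_keys: tuple[tuple[int, int], ...]
    values: np.ndarray  # (N, P) uint8
    pair_index: PairIndex

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.uint8)
        if v.ndim != 2 or v.shape[1] != self.pair_index.dimension:
            raise ValueError("feature matrix width must match the pair index")
        if v.shape[0] != len(self.participant_keys):
            raise ValueError("one key per row required")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def dimension(self) -> int:
        return self.values.shape[1]


def transform_participant(nm: NamingMatrix, idx: PairIndex) -> np.ndarray:
    """Binary vector: entry p is 1 iff both chips of pair p share a term."""
    labels = nm.labels()
    return (labels[idx.i_idx] == labels[idx.j_idx]).astype(np.uint8)


def transform_corpus(
    matrices: Iterable[NamingMatrix], idx: PairIndex
) -> FeatureMatrix:
    """Stack participant feature vectors in input order."""
    matrices = list(matrices)
    if matrices:
        values = np.stack([transform_participant(nm, idx) for nm in matrices])
    else:
        values = np.zeros((0, idx.dimension), dtype=np.uint8)
    return FeatureMatrix(
        participant_keys=tuple(nm.participant_key for nm in matrices),
        values=values,
        pair_index=idx,
    )


def save_feature_matrix(fm: FeatureMatrix, path) -> None:
    """Delimited text with a JSON header line recording the neighbor scheme."""
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(fm.pair_index.scheme.to_dict()) + "\n")
        for key, row in zip(fm.participant_keys, fm.values):
            fh.write(
                f"{key[0]}\t{key[1]}\t" + "\t".join(str(int(v)) for v in row) + "\n"
            )


def load_feature_matrix(path, grid: ChipGrid | None = None) -> FeatureMatrix:
    lines = Path(path).read_text().splitlines()
    scheme = NeighborScheme(**json.loads(lines[0].lstrip("# ")))
    idx = build_pair_index(scheme, grid)
    keys = []
    rows = []
    for raw in lines[1:]:
        if not raw.strip():
            continue
        parts = raw.split("\t")
        keys.append((int(parts[0]), int(parts[1])))
        rows.append([int(v) for v in parts[2:]])
    values = (
        np.array(rows, dtype=np.uint8)
        if rows
        else np.zeros((0, idx.dimension), dtype=np.uint8)
    )
    return FeatureMatrix(participant_keys=tuple(keys), values=values, pair_index=idx)
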