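"""Synthetic color-naming corpora generated from latent motif partitions.

A *motif* is a partition of the 320 chromatic chips into contiguous color
categories; real naming surveys find a small set of such motifs recurring
across languages.  The generator draws each motif as a nearest-seed (Voronoi)
partition of the grid under L1 distance with circular hue columns, then
produces participants by copying a motif and perturbing it with *boundary
noise*: each chip independently, with probability ``noise_rate``, takes the
label of a uniformly chosen grid neighbor.  Because interior chips are
surrounded by same-label neighbors, this noise only moves category
boundaries, mimicking the boundary disagreement seen in real naming data.

Emitted corpora use the survey file dialect (``language speaker chip term``
lines over the chromatic chips only); the ground-truth motif of each
participant is returned separately so recovery can be scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import CHROMATIC_ROWS, N_COLS, N_CHROMATIC, ChipGrid, NamingMatrix

N_ROWS = len(CHROMATIC_ROWS)


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for corpus generation.

    Defaults describe a desk-scale survey: 8 motifs of 6 color categories
    each, boundary-noise rate 0.03, and 20 languages x 25 participants (500
    participants), with every language drawing motifs uniformly — real
    surveys show substantial motif diversity within languages.
    """

    n_motifs: int = 8
    terms_per_motif: int = 6
    noise_rate: float = 0.03
    n_languages: int = 20
    participants_per_language: int = 25
    motif_mixture: tuple | None = None  # per-language rows of motif probabilities
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.noise_rate < 0.5):
            raise ValueError("noise_rate must lie in [0, 0.5) (below chance)")
        if self.terms_per_motif < 1 or self.n_motifs < 1:
            raise ValueError("counts must be >= 1")
        if self.n_languages < 1 or self.participants_per_language < 1:
            raise ValueError("counts must be >= 1")
        if self.motif_mixture is not None:
            mix = np.asarray(self.motif_mixture, dtype=float)
            if mix.shape != (self.n_languages, self.n_motifs):
                raise ValueError("motif_mixture must be (n_languages, n_motifs)")
            if (mix < 0).any() or not np.allclose(mix.sum(axis=1), 1.0):
                raise ValueError("motif_mixture rows must be distributions")

    def mixture(self) -> np.ndarray:
        if self.motif_mixture is None:
            return np.full((self.n_languages, self.n_motifs), 1.0 / self.n_motifs)
        return np.asarray(self.motif_mixture, dtype=float)


def _grid_distance(r1: int, c1: int, r2: np.ndarray, c2: np.ndarray) -> np.ndarray:
    """L1 grid distance with circular hue columns; rows do not wrap."""
    dc = np.abs(c1 - c2)
    return np.abs(r1 - r2) + np.minimum(dc, N_COLS - dc)


def _vn_neighbors(idx: int) -> list[int]:
    """Canonical indices of the von Neumann neighbors (hue wraparound)."""
    r, c = divmod(idx, N_COLS)
    out = []
    if r > 0:
        out.append((r - 1) * N_COLS + c)
    if r < N_ROWS - 1:
        out.append((r + 1) * N_COLS + c)
    out.append(r * N_COLS + (c + 1) % N_COLS)
    out.append(r * N_COLS + (c - 1) % N_COLS)
    return out


def generate_motif(k: int, grid: ChipGrid | None = None, seed: int = 0) -> np.ndarray:
    """A k-category Voronoi partition of the chromatic grid.

    ``k`` seed chips are sampled without replacement; every chip takes the
    label of its nearest seed under L1 distance with hue wraparound, ties
    resolved toward the lowest seed index.  Every category is non-empty (each
    seed is its own unique nearest) and grid-connected (any L1 geodesic from
    a member to its seed stays inside the cell).

    Returns a length-320 integer label array in canonical chip order.
    """
    if not (1 <= k <= N_CHROMATIC):
        raise ValueError(f"k must be in 1..{N_CHROMATIC}")
    rng = np.random.default_rng(seed)
    seeds = rng.choice(N_CHROMATIC, size=k, replace=False)
    rows = np.arange(N_CHROMATIC) // N_COLS
    cols = np.arange(N_CHROMATIC) % N_COLS
    dists = np.stack(
        [_grid_distance(s // N_COLS, s % N_COLS, rows, cols) for s in seeds]
    )  # (k, 320)
    return dists.argmin(axis=0)  # argmin ties -> lowest seed index


def generate_participant(
    motif: np.ndarray,
    noise_rate: float,
    seed: int = 0,
    participant_key=(1, 1),
    term_names=None,
) -> NamingMatrix:
    """Perturb a motif with boundary noise and wrap it as a naming matrix.

    Each chip independently, with probability ``noise_rate``, is relabeled
    with the motif label of a uniformly chosen von Neumann grid neighbor;
    one term per chip is preserved by construction.
    """
    motif = np.asarray(motif)
    if motif.shape != (N_CHROMATIC,):
        raise ValueError(f"motif must have {N_CHROMATIC} labels")
    rng = np.random.default_rng(seed)
    labels = motif.copy()
    flip = rng.random(N_CHROMATIC) < noise_rate
    for idx in np.flatnonzero(flip):
        nbrs = _vn_neighbors(idx)
        labels[idx] = motif[nbrs[rng.integers(len(nbrs))]]
    return NamingMatrix.from_labels(participant_key, labels, term_names=term_names)


@dataclass(frozen=True)
class SyntheticCorpus:
    """Generated term lines plus the ground truth needed to score recovery."""

    lines: tuple[str, ...]
    truth: dict  # (language, speaker) -> motif id
    motifs: np.ndarray  # (n_motifs, 320) label arrays
    config: SyntheticConfig

    def truth_labels(self, keys) -> np.ndarray:
        return np.array([self.truth[tuple(k)] for k in keys])


def generate_corpus(cfg: SyntheticConfig, grid: ChipGrid | None = None) -> SyntheticCorpus:
    """Emit a survey-dialect corpus of ``n_languages x participants_per_language``
    participants, each drawn from its language's motif mixture."""
    grid = grid or ChipGrid.default()
    rng = np.random.default_rng(cfg.seed)
    motifs = np.stack(
        [
            generate_motif(cfg.terms_per_motif, grid, seed=int(s))
            for s in rng.integers(0, 2**31, size=cfg.n_motifs)
        ]
    )
    mixture = cfg.mixture()
    chips = grid.canonical_chips()
    lines: list[str] = []
    truth: dict[tuple[int, int], int] = {}
    for lang in range(1, cfg.n_languages + 1):
        for spk in range(1, cfg.participants_per_language + 1):
            m = int(rng.choice(cfg.n_motifs, p=mixture[lang - 1]))
            nm = generate_participant(
                motifs[m],
                cfg.noise_rate,
                seed=int(rng.integers(0, 2**31)),
                participant_key=(lang, spk),
                term_names={j: f"t{j}" for j in range(cfg.terms_per_motif)},
            )
            truth[(lang, spk)] = m
            labels = nm.labels()
            for j, chip in enumerate(chips):
                lines.append(f"{lang}\t{spk}\t{chip}\t{nm.terms[labels[j]]}")
    return SyntheticCorpus(
        lines=tuple(lines), truth=truth, motifs=motifs, config=cfg
    )


def write_corpus(corpus: SyntheticCorpus, out_dir, grid: ChipGrid | None = None) -> dict:
    """Write term file, chip map, ground truth and config echo; return paths."""
    grid = grid or ChipGrid.default()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "terms": out / "term.txt",
        "chip_map": out / "chip_map.txt",
        "truth": out / "ground_truth.tsv",
        "config": out / "synthetic_config.json",
    }
    paths["terms"].write_text("\n".join(corpus.lines) + "\n")
    grid.write_chip_map(paths["chip_map"])
    with open(paths["truth"], "w") as fh:
        for (lang, spk), m in sorted(corpus.truth.items()):
            fh.write(f"{lang}\t{spk}\t{m}\n")
    cfg = corpus.config
    paths["config"].write_text(
        json.dumps(
            {
                "n_motifs": cfg.n_motifs,
                "terms_per_motif": cfg.terms_per_motif,
                "noise_rate": cfg.noise_rate,
                "n_languages": cfg.n_languages,
                "participants_per_language": cfg.participants_per_language,
                "seed": cfg.seed,
            },
            indent=2,
        )
        + "\n"
    )
    return {k: str(v) for k, v in paths.items()}
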