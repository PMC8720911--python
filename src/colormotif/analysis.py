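"""Post-clustering measures: centroids, boundary heatmaps, schematic
similarity and group error.

All measures operate on the term-label-free feature representation (or, for
same-language centroids, on raw naming matrices), so groups from different
languages remain comparable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np

from .features import FeatureMatrix, PairIndex, transform_participant
from .grid import CHROMATIC_ROWS, N_COLS, N_CHROMATIC, NamingMatrix
from .model import ClusterResult

N_ROWS = len(CHROMATIC_ROWS)


def language_centroid(matrices: Sequence[NamingMatrix]) -> NamingMatrix:
    """Modal map of a same-language group: per chip, the most frequent term,
    ties broken toward the lexicographically smallest token.  Minimizes the
    total per-chip disagreement with the group's members."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("empty group")
    modal = []
    for j in range(N_CHROMATIC):
        counts = Counter(nm.term_of_chip(j) for nm in matrices)
        top = max(counts.values())
        best = min(t for t, c in counts.items() if c == top)
        modal.append(best)
    lang = matrices[0].participant_key[0]
    return NamingMatrix.from_labels((lang, 0), modal)


def cluster_feature_centroid(rows: np.ndarray) -> np.ndarray:
    """Per-attribute majority bit of a cluster's feature rows (ties -> 1).

    The majority vector minimizes the total Hamming distance to the rows, so
    it plays the same representative role in feature space that the modal
    map plays in term space."""
    rows = np.atleast_2d(np.asarray(rows))
    if rows.shape[0] == 0:
        raise ValueError("empty cluster")
    return (rows.mean(axis=0) >= 0.5).astype(np.uint8)


def boundary_heatmap(
    matrices: Iterable[NamingMatrix], idx: PairIndex
) -> np.ndarray:
    """8 x 40 matrix of per-chip boundary probabilities for a group.

    A chip's boundary probability is the mean, over participants and over the
    undirected adjacency pairs incident to the chip, of the disagreement
    indicator (1 minus the neighbor-agreement feature).  0 means every
    participant names the chip and all its neighbors alike; 1 means the chip
    always disagrees with every neighbor.
    """
    matrices = list(matrices)
    if not matrices:
        raise ValueError("empty group")
    und = idx.undirected_view()
    disagree_sum = np.zeros(N_CHROMATIC)
    for nm in matrices:
        feats = transform_participant(nm, und).astype(float)
        d = 1.0 - feats
        np.add.at(disagree_sum, und.i_idx, d)
        np.add.at(disagree_sum, und.j_idx, d)
    incident = np.zeros(N_CHROMATIC)
    np.add.at(incident, und.i_idx, 1.0)
    np.add.at(incident, und.j_idx, 1.0)
    probs = disagree_sum / (incident * len(matrices))
    return probs.reshape(N_ROWS, N_COLS)


def schematic_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Fraction of adjacency pairs on which two naming schemes agree.

    1 for identical partitions; 0 when one scheme uses a single term and the
    other gives every chip its own term (no pair classified alike).  Because
    the same-name relation is symmetric, the value is identical whether the
    vectors were built from a directed or an undirected pair set.
    """
    u = np.asarray(u).ravel()
    v = np.asarray(v).ravel()
    if u.shape != v.shape:
        raise ValueError("feature vectors must share one pair index")
    if u.size == 0:
        raise ValueError("empty feature vectors")
    return float(np.mean(u == v))


def ss_matrix(fm: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Pairwise schematic-similarity matrix: symmetric, unit diagonal."""
    X = fm.values if isinstance(fm, FeatureMatrix) else np.atleast_2d(np.asarray(fm))
    n, p = X.shape
    eq = 1.0 - _hamming_matrix(X) / p
    np.fill_diagonal(eq, 1.0)
    return eq


def _hamming_matrix(X: np.ndarray) -> np.ndarray:
    Xf = X.astype(np.float64)
    g = Xf @ Xf.T
    ones = Xf.sum(axis=1)
    # disagreements = |i has 1, j has 0| + |i has 0, j has 1|
    return ones[:, None] + ones[None, :] - 2.0 * g


def group_error(assignments: Sequence[int]) -> float:
    """Within-group diversity: the fraction of unordered participant pairs
    assigned to different clusters.  0 when the whole group shares one
    cluster; 1 when every participant sits in its own cluster.  Invariant
    under relabeling of cluster ids."""
    z = np.asarray(list(assignments))
    n = len(z)
    if n < 2:
        raise ValueError("group error requires at least 2 participants")
    split = sum(1 for i, j in combinations(range(n), 2) if z[i] != z[j])
    return split / (n * (n - 1) / 2)


def group_error_weighted(
    assignments: Sequence[int], result: ClusterResult
) -> float:
    """Distance-weighted variant: each split pair contributes 1 minus the
    schematic similarity of its two clusters' (binarized) feature centroids,
    so splits between near-identical clusters count less.  Reported
    separately from the default pair-split fraction."""
    z = np.asarray(list(assignments))
    n = len(z)
    if n < 2:
        raise ValueError("group error requires at least 2 participants")
    occ = list(result.occupied_clusters)
    bits = (result.centroids >= 0.5).astype(np.uint8)
    centroid_of = {int(c): bits[i] for i, c in enumerate(occ)}
    total = 0.0
    for i, j in combinations(range(n), 2):
        if z[i] != z[j]:
            total += 1.0 - schematic_similarity(
                centroid_of[int(z[i])], centroid_of[int(z[j])]
            )
    return total / (n * (n - 1) / 2)


@dataclass(frozen=True)
class GroupErrorReport:
    """Per-language diversity table."""

    languages: tuple[int, ...]
    sizes: tuple[int, ...]
    occupied_counts: tuple[int, ...]
    errors: tuple[float, ...]          # default pair-split fraction (nan if n < 2)
    weighted_errors: tuple[float, ...]


def group_error_report(
    keys: Sequence[tuple[int, int]], result: ClusterResult
) -> GroupErrorReport:
    """Group error per language over a fitted clustering."""
    z = result.assignments
    langs = sorted({k[0] for k in keys})
    sizes, occs, errs, werrs = [], [], [], []
    for lang in langs:
        rows = [i for i, k in enumerate(keys) if k[0] == lang]
        zl = z[rows]
        sizes.append(len(rows))
        occs.append(len(np.unique(zl)))
        if len(rows) < 2:
            errs.append(float("nan"))
            werrs.append(float("nan"))
        else:
            errs.append(group_error(zl))
            werrs.append(group_error_weighted(zl, result))
    return GroupErrorReport(
        languages=tuple(langs),
        sizes=tuple(sizes),
        occupied_counts=tuple(occs),
        errors=tuple(errs),
        weighted_errors=tuple(werrs),
    )


def write_heatmap(hm: np.ndarray, path) -> None:
    np.savetxt(path, hm, fmt="%.6f", delimiter="\t")


def write_group_errors(report: GroupErrorReport, path) -> None:
    with open(path, "w") as fh:
        fh.write("language\tn\tK_occupied\terror\tweighted_error\n")
        for row in zip(
            report.languages,
            report.sizes,
            report.occupied_counts,
            report.errors,
            report.weighted_errors,
        ):
            fh.write("\t".join(str(v) for v in row) + "\n")
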