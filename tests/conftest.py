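import numpy as np
import pytest

import colormotif as cm
from colormotif.grid import N_COLS, N_CHROMATIC, NamingMatrix, NamingRecord


@pytest.fixture(scope="session")
def grid():
    return cm.ChipGrid.default()


@pytest.fixture(scope="session")
def idx_default(grid):
    """Default scheme: Moore 8-neighborhood, directed, hue wraparound."""
    return cm.build_pair_index(cm.DEFAULT_SCHEME, grid)


@pytest.fixture(scope="session")
def idx_vn4_undirected(grid):
    return cm.build_pair_index(
        cm.NeighborScheme("von_neumann_4", directed=False, hue_wraparound=True), grid
    )


def labels_matrix(labels, key=(1, 1)):
    return NamingMatrix.from_labels(key, labels)


@pytest.fixture()
def single_term_participant():
    return labels_matrix(["A"] * N_CHROMATIC)


@pytest.fixture()
def all_singleton_participant():
    return labels_matrix([f"t{j}" for j in range(N_CHROMATIC)])


@pytest.fixture()
def vertical_split_participant():
    """Two terms split between hue columns 20|21 and 40|1 (wraparound)."""
    labels = []
    for i in range(N_CHROMATIC):
        col = i % N_COLS + 1
        labels.append("A" if col <= 20 else "B")
    return labels_matrix(labels)


def corpus_records(corpus):
    """Parse synthetic corpus lines into NamingRecords without touching disk."""
    return [
        NamingRecord(int(l), int(s), int(c), t)
        for l, s, c, t in (line.split("\t") for line in corpus.lines)
    ]


@pytest.fixture(scope="session")
def small_corpus_fm(grid, idx_default):
    """A small, well-separated synthetic corpus with its feature matrix."""
    cfg = cm.SyntheticConfig(
        n_motifs=4, n_languages=4, participants_per_language=8, seed=3
    )
    corpus = cm.generate_corpus(cfg, grid)
    mats = cm.build_corpus_matrices(corpus_records(corpus), grid)
    fm = cm.transform_corpus(mats, idx_default)
    return corpus, fm
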