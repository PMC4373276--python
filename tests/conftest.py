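import numpy as np
import pandas as pd
import pytest

from brainlattice import corpus, revinf, synthgen, volgrid


@pytest.fixture(scope="session")
def grid():
    """Coarse synthetic brain mask: whole suites run in seconds on it."""
    return volgrid.Grid.ellipsoid(resolution=8.0)


@pytest.fixture(scope="session")
def demo_corpus(grid):
    """The bundled synthetic corpus at seed 0, with its ground truth."""
    tables, manifest = synthgen.generate(synthgen.SynthSpec(seed=0), grid)
    return tables, manifest


@pytest.fixture(scope="session")
def demo_maps(grid, demo_corpus):
    """Activation matrix plus term and author reverse-inference maps."""
    tables, manifest = demo_corpus
    am = volgrid.activation_matrix(tables, grid)
    roster = corpus.extract_pis(tables)
    term_maps = revinf.batch_maps(am, revinf.term_labels(tables, am.studies))
    author_maps = revinf.batch_maps(
        am, revinf.author_labels(tables, am.studies, roster)
    )
    return am, term_maps, author_maps


def toy_tables(
    coordinates=None, authorship=None, term_freq=None
) -> corpus.CorpusTables:
    """Hand-built CorpusTables with sane defaults for the missing pieces."""
    if coordinates is None:
        coordinates = [("S1", 0.0, 0.0, 0.0, "MNI")]
    if authorship is None:
        studies = sorted({r[0] for r in coordinates})
        authorship = [(s, 1, f"Author {i}") for i, s in enumerate(studies)]
    if term_freq is None:
        term_freq = [(coordinates[0][0], "memory", 0.01)]
    return corpus.CorpusTables(
        coordinates=pd.DataFrame(
            coordinates, columns=["study_id", "x", "y", "z", "space"]
        ),
        authorship=pd.DataFrame(
            authorship, columns=["study_id", "position", "author"]
        ),
        term_freq=pd.DataFrame(
            term_freq, columns=["study_id", "term", "frequency"]
        ),
    )


def authorship_tables(rows) -> corpus.CorpusTables:
    """CorpusTables from (study, position, author) rows only."""
    studies = sorted({r[0] for r in rows})
    return toy_tables(
        coordinates=[(s, 0.0, 0.0, 0.0, "MNI") for s in studies],
        authorship=rows,
        term_freq=[(studies[0], "memory", 0.01)],
    )


def random_activation(rng: np.random.Generator, n_studies: int, n_voxels: int):
    values = (rng.random((n_studies, n_voxels)) < 0.3).astype(np.uint8)
    studies = [f"S{i:03d}" for i in range(n_studies)]
    return volgrid.ActivationMatrix(studies=studies, values=values)
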