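import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for the oracles module

from ssforge import fixtures as fx
from ssforge import library as lib
from ssforge import structure_io as sio

CORPUS_SEED = 7
CORPUS_SIZE = 50


@pytest.fixture(scope="session")
def cystine_corpus():
    """50 single-cystine bundles, chi3 modes +-97 deg, sg_sg 2.05 +- 0.02 A."""
    return fx.make_cystine_corpus(CORPUS_SIZE, chi3_modes=(97.0, -97.0),
                                  noise_sd=0.02, seed=CORPUS_SEED)


@pytest.fixture(scope="session")
def native_library(cystine_corpus):
    corpus, _ = cystine_corpus
    return lib.build_library(corpus)


@pytest.fixture(scope="session")
def bundle():
    """Two-helix bundle with one ideal planted cross-helix pair, parsed back
    from its own PDB text so the full IO path is exercised."""
    st, key_a, key_b = fx.make_two_helix_bundle(seed=3)
    parsed = sio.parse_structure(sio.write_structure(st), structure_id=st.id)
    return parsed, key_a, key_b


@pytest.fixture(scope="session")
def separable_training_set():
    return fx.make_separable_training_set(n=100, seed=42)


@pytest.fixture(scope="session")
def trained_model(separable_training_set):
    from ssforge import classifier as clf

    return clf.train(separable_training_set, clf.TrainConfig(seed=42))


@pytest.fixture(scope="session")
def ranked_records(bundle, native_library):
    """Candidates of the bundle fixture, ranked once for the whole session."""
    from ssforge import scoring

    st, _, _ = bundle
    return scoring.rank_candidates(st, native_library)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
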