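import numpy as np
import pytest

from wordpatch import (
    SyntheticLexiconSpec,
    build_design,
    make_synthetic_lexica,
)


@pytest.fixture(scope="session")
def toy_lexica():
    """Small bilingual lexicon pair shared across tests."""
    spec = SyntheticLexiconSpec(n_words=4000)
    return make_synthetic_lexica(spec, seed=11)


@pytest.fixture(scope="session")
def toy_design(toy_lexica):
    """Full pipeline at 2 items/category (feasible on the small lexica)."""
    a, b = toy_lexica
    return build_design(a, b, items_per_category=2, seed=11, match_tolerance=0.3)


@pytest.fixture(scope="session")
def full_lexica():
    """Full-scale lexicon pair (20k words/language)."""
    return make_synthetic_lexica(SyntheticLexiconSpec(), seed=20)


@pytest.fixture(scope="session")
def full_design(full_lexica):
    """The complete 14 x 180 stimulus design on full-scale lexica."""
    a, b = full_lexica
    return build_design(a, b, items_per_category=180, seed=20)


@pytest.fixture(scope="session")
def laplace_mixture():
    """Planted 3-component mixture with heavy-tailed voxel weights."""
    rng = np.random.default_rng(42)
    profiles = np.linalg.qr(rng.standard_normal((14, 3)))[0].T
    weights = rng.laplace(0, 1, (5000, 3)) * np.array([3.0, 2.0, 1.5])
    data = weights @ profiles + rng.normal(0, 0.01, (5000, 14))
    return data, profiles, weights
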