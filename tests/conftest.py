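import pytest

import fallfusion as ff


@pytest.fixture(scope="session")
def params():
    """Default generator parameters (the study conditions), seed 0."""
    return ff.MotionModelParams(seed=0)


@pytest.fixture(scope="session")
def small_corpus(params):
    """Balanced 8-trials-per-class labelled corpus (48 recordings)."""
    return ff.generate_corpus(8, params)


@pytest.fixture(scope="session")
def train_set(small_corpus):
    return ff.TrainingSet.from_corpus(small_corpus)


@pytest.fixture(scope="session")
def fitted(small_corpus):
    """Fitted system on the small corpus (cross-validated k)."""
    return ff.FallDetectionModel.from_corpus(small_corpus).fit()
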