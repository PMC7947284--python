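import numpy as np
import pytest

from facetriad import metrics, models, synthgen


@pytest.fixture(scope="session")
def clean_params():
    """Zero-noise generator settings: separable planted signals only."""
    return synthgen.FaceGenParams(seed=3, idiosyncrasy_sd=0.0, pixel_noise_sd=0.0)


@pytest.fixture(scope="session")
def small_cohort(clean_params):
    records, metadata, manifest = synthgen.make_cohort(clean_params, 2)
    return records, metadata, manifest


@pytest.fixture(scope="session")
def separable_features(clean_params):
    """Features + labels of a zero-noise cohort large enough to train on."""
    records, metadata, _ = synthgen.make_cohort(clean_params, 8)
    feats = {m: metrics.feature_table(records, m) for m in metrics.METRICS}
    labels = metadata.set_index("face_id")["emotion"]
    return feats, labels, metadata


@pytest.fixture(scope="session")
def trained_separable(separable_features):
    feats, labels, _ = separable_features
    config = models.LearnerConfig(C=10.0)
    return models.train_combined(
        {m: feats[m].loc[labels.index] for m in feats}, labels, config, seed=0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
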