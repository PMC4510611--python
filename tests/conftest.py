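"""Shared fixtures: small deterministic datasets and trained toy models."""

import numpy as np
import pytest

import cascadet as cd


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def easy_patches():
    """Separable blob-vs-clutter patches (overlap 0), 60 pos / 400 neg, 16x16."""
    cfg = cd.SynthConfig(n_pos=60, n_neg=400, overlap=0.0, seed=7)
    return cd.generate_patches(cfg)


@pytest.fixture(scope="session")
def easy_features(easy_patches):
    """Haar feature matrices for the easy patches, coarse enumeration."""
    fc = cd.haar_config(16, 16, stride=3, scale_step=3)
    extract, _ = cd.build_extractor(fc)
    pos, neg = easy_patches
    return extract(pos), extract(neg), fc


@pytest.fixture(scope="session")
def trained_cascade(easy_features):
    """A small confidence-selection cascade trained on the easy features."""
    X_pos, X_neg, fc = easy_features
    cfg = cd.TrainConfig(F=0.05, selection_mode="confidence", seed=0)
    return cd.train_cascade(X_pos, cd.NegativePool(X_neg), cfg,
                            feature_config=fc, window=(16, 16))


@pytest.fixture()
def gauss_2d():
    """Two-class 2-D Gaussian data, linearly separable in feature 0."""
    rng = np.random.default_rng(42)
    X_pos = rng.normal([3.0, 0.0], 1.0, (40, 2))
    X_neg = rng.normal([-3.0, 0.0], 1.0, (40, 2))
    return X_pos, X_neg
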