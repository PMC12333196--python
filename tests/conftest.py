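import numpy as np
import pytest

from lsgi import LsgiConfig, SpatialProfile


def make_profile(n=200, k=2, seed=0, span=10.0, features=None, kind="factor_loadings"):
    """Random uniform profile; features default to non-negative noise."""
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0.0, span, size=(n, 2))
    if features is None:
        features = rng.uniform(0.0, 1.0, size=(n, k))
    features = np.asarray(features, dtype=float)
    return SpatialProfile(
        unit_ids=[f"u{i}" for i in range(n)],
        coords=coords,
        features=features,
        feature_names=[f"F{j + 1}" for j in range(features.shape[1])],
        feature_kind=kind,
    )


@pytest.fixture
def default_config():
    return LsgiConfig()


@pytest.fixture
def linear_profile():
    """Noise-free planted gradient F1 = x on a random point cloud."""
    rng = np.random.default_rng(7)
    coords = rng.uniform(0.0, 10.0, size=(300, 2))
    return SpatialProfile(
        unit_ids=[f"u{i}" for i in range(300)],
        coords=coords,
        features=coords[:, 0:1].copy(),
        feature_names=["F1"],
    )
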