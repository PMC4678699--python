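import numpy as np
import pytest
from hypothesis import settings

from stisodata.phantom import PhantomConfig, SignatureRegion, generate_phantom
from stisodata.preprocess import FeatureMatrix

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


def small_phantom_config(seed=0, noise=True, regions=None):
    """A 32x32x16 phantom small enough for unit tests."""
    if regions is None:
        regions = (
            SignatureRegion("II", center=(9, 12, 8), radii=(4.0, 4.0, 3.0)),
            SignatureRegion("V", center=(10, 22, 8), radii=(3.5, 3.5, 3.0)),
        )
    noise_sd = None if noise else {"ADC": 0.0, "FA": 0.0, "T2": 0.0}
    kwargs = dict(grid_shape=(32, 32, 16), signature_regions=regions, seed=seed)
    if noise_sd is not None:
        kwargs["noise_sd"] = noise_sd
    return PhantomConfig(**kwargs)


@pytest.fixture(scope="session")
def small_phantom():
    return generate_phantom(small_phantom_config(seed=7))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(small_phantom_config(seed=7, noise=False))


def make_features(X, feature_index=None):
    """Wrap a raw (n, d) array as a FeatureMatrix on a synthetic 1D grid."""
    X = np.asarray(X, dtype=float)
    n, d = X.shape
    if feature_index is None:
        feature_index = tuple((float(j), "rADC") for j in range(d))
    voxel_index = np.stack(
        [np.arange(n), np.zeros(n, dtype=int), np.zeros(n, dtype=int)], axis=1
    )
    return FeatureMatrix(
        data=X.copy(),
        voxel_index=voxel_index,
        feature_index=tuple(feature_index),
        shape=(n, 1, 1),
    )


def two_blob_features(n_per=200, separation=10.0, sd=1.0, d=2, seed=0):
    """Two spherical Gaussian blobs separated along the first axis."""
    rng = np.random.default_rng(seed)
    a = rng.normal(0.0, sd, size=(n_per, d))
    b = rng.normal(0.0, sd, size=(n_per, d))
    b[:, 0] += separation * sd
    X = np.vstack([a, b])
    labels = np.repeat([0, 1], n_per)
    return make_features(X), labels
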