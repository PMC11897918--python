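import numpy as np
import pytest

from ganospec.pipeline import build_spectra_table
from ganospec.synthetic import SceneSpec, generate_scene

try:
    from hypothesis import settings

    settings.register_profile("suite", derandomize=True, max_examples=25,
                              deadline=None)
    settings.load_profile("suite")
except ImportError:
    pass


@pytest.fixture(scope="session")
def tiny_scene():
    """Small but complete campaign: 6 samples, both forms/ranges, 2 replicates."""
    return generate_scene(SceneSpec(n_samples=6, replicates=2, seed=7))


@pytest.fixture(scope="session")
def tiny_swir_table(tiny_scene):
    return build_spectra_table(tiny_scene, "SWIR")


@pytest.fixture(scope="session")
def easy_regression():
    """Well-behaved regression data with 3 planted features among 30.

    Reflectance-scaled columns; the target is a linear combination of
    columns 4, 12 and 21 plus light noise, so wrapper selection has an
    unambiguous ground truth.
    """
    rng = np.random.default_rng(42)
    n, p = 80, 30
    X = 0.5 + 0.1 * rng.normal(size=(n, p))
    informative = np.array([4, 12, 21])
    y = X[:, informative] @ np.array([3.0, -2.0, 2.5]) + 0.02 * rng.normal(size=n)
    return X, y, informative
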