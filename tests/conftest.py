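import numpy as np
import pytest

import drentropy as de


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)


@pytest.fixture(scope="session")
def two_class_set():
    """Small two-class set with the default entropy separation (NoDR vs severe)."""
    cfg = de.SyntheticConfig(
        classes=(de.DEFAULT_CLASSES[0], de.DEFAULT_CLASSES[4]),
        n_per_class=30,
        seed=42,
    )
    return de.generate_dataset(cfg)


@pytest.fixture(scope="session")
def five_class_features():
    """Feature table over all five severity classes (small n, session-cached)."""
    cfg = de.SyntheticConfig(n_per_class=15, seed=7)
    return de.build_feature_table(de.generate_dataset(cfg))


@pytest.fixture(scope="session")
def separable_design():
    """Two distant Gaussian blobs: any reasonable classifier reaches accuracy 1."""
    rng = np.random.default_rng(5)
    n = 60
    X = np.vstack(
        [
            rng.normal([0.0, 0.0], 0.1, size=(n, 2)),
            rng.normal([10.0, 10.0], 0.1, size=(n, 2)),
        ]
    )
    y = np.repeat([0, 1], n)
    spec = de.ModelSpec(index="M1", dr_level="mild", preprocessing="O")
    ids = tuple(f"img_{i:05d}" for i in range(2 * n))
    return de.DesignMatrix(X=X, y=y, image_ids=ids, spec=spec)
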