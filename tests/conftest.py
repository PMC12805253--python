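import numpy as np
import pytest

import cnattention as cn


@pytest.fixture(scope="session")
def clean_cohort():
    """Separable-by-construction cohort: high penetrance, light noise."""
    config = cn.SimulationConfig(penetrance=0.95, background_rate=0.01, seed=3)
    return cn.simulate_cohort(config)


@pytest.fixture(scope="session")
def trained(clean_cohort):
    """A model trained on the clean cohort, plus the held-out part."""
    cohort, truth = clean_cohort
    train_part, test_part = cn.split_cohort(cohort, 0.2, seed=5)
    model = cn.CNAttention(train_part, embed_dim=64, attention_dim=32)
    results = model.fit(cn.TrainConfig(epochs=50, seed=0))
    return results, test_part, truth


@pytest.fixture(scope="session")
def tiny_params():
    """Small random model with a non-trivial classifier head."""
    rng = np.random.default_rng(11)
    params = cn.MILModelParams.initialize(D=6, M=5, L=4, C=3, seed=11)
    params.Wc = rng.normal(size=params.Wc.shape) * 0.4
    params.bc = rng.normal(size=params.bc.shape) * 0.1
    return params


@pytest.fixture()
def two_class_cohort():
    """Deterministic 2-class cohort where two features are jointly (but not
    individually) sufficient and two are pure noise."""
    rng = np.random.default_rng(42)
    n = 40
    y = np.array([0, 1] * (n // 2))
    half = np.arange(n) < n // 2
    f1 = np.where(half, np.where(y == 0, 1, -1), 0)
    f2 = np.where(~half, np.where(y == 0, 2, -2), 0)
    noise1 = rng.integers(-2, 3, size=n)
    noise2 = rng.integers(-2, 3, size=n)
    X = np.stack([f1, f2, noise1, noise2], axis=1)
    genes = ["inf1", "inf2", "noiseA", "noiseB"]
    matrix = cn.CNAMatrix([f"s{i}" for i in range(n)], genes, X)
    labels = {f"s{i}": ("a" if y[i] == 0 else "b") for i in range(n)}
    return cn.LabeledCohort(matrix, labels)
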