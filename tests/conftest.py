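import numpy as np
import pytest

from erpglm import EpochSet, SubjectStack, build_design_matrix, fit_glm


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def random_epochs(rng):
    """4 channels x 10 frames x 40 trials of white noise."""
    return EpochSet(
        data=rng.standard_normal((4, 10, 40)),
        channel_labels=[f"ch{i}" for i in range(4)],
        times_ms=np.arange(10, dtype=float) * 4.0,
        sampling_rate_hz=250.0,
    )


@pytest.fixture
def mixed_design(rng):
    """3 conditions + 1 covariate + constant over 40 trials (rank deficient)."""
    labels = [["A", "B", "C"][i % 3] for i in range(40)]
    cov = rng.standard_normal((40, 1))
    return labels, cov, build_design_matrix(labels, covariates=cov)


@pytest.fixture
def fitted(random_epochs, mixed_design):
    _, _, design = mixed_design
    return fit_glm(random_epochs, design)


@pytest.fixture
def gaussian_stack(rng):
    return SubjectStack(rng.standard_normal((15, 3, 6)))
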