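import numpy as np
import pytest

from fedbatch.rate_estimation import estimate_rates
from fedbatch.synthetic import NoiseSpec, generate_dataset, make_truth_params


@pytest.fixture(scope="session")
def truth():
    return make_truth_params("reduced_default")


@pytest.fixture(scope="session")
def dataset_clean(truth):
    """Noise-free 12-run central-composite fixture."""
    return generate_dataset(truth, noise=NoiseSpec(0.0, 0.0, 0.0), seed=3)


@pytest.fixture(scope="session")
def obs_clean(truth, dataset_clean):
    return estimate_rates(
        dataset_clean, (truth.Y_XrG, truth.Y_PG),
        smoothing={"X": 0, "P": 0, "G": 0},
    )


@pytest.fixture(scope="session")
def dataset_noisy(truth):
    """12 runs with the default measurement noise (3% X, 15% P, 5% G)."""
    return generate_dataset(truth, noise=NoiseSpec(), seed=11)


@pytest.fixture(scope="session")
def center_run_clean(truth, dataset_clean):
    rec = dataset_clean[0]
    assert rec.run_id.endswith("center")
    return rec


@pytest.fixture(scope="session")
def param_error_fn():
    from fedbatch.validation import parameter_errors

    return parameter_errors
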