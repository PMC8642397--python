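import numpy as np
import pytest

from peakvote import SimSpec, simulate_dataset, train_ensemble
from peakvote._domain import IsotopeTrace


def gaussian_trace(
    isotope_index=0,
    sigma=0.1,
    center=10.0,
    apex=1e5,
    dt=0.02,
    half_width_sigmas=4.0,
    boundary_sigmas=2.5,
    scale=1.0,
):
    """Noise-free sampled Gaussian elution peak."""
    half = half_width_sigmas * sigma
    t = np.arange(center - half, center + half + dt / 2, dt)
    y = scale * apex * np.exp(-0.5 * ((t - center) / sigma) ** 2)
    return IsotopeTrace(
        isotope_index, t, y,
        center - boundary_sigmas * sigma, center + boundary_sigmas * sigma,
    )


@pytest.fixture(scope="session")
def small_dataset():
    """120 well-separated simulated examples for fast training tests."""
    examples, groups = simulate_dataset(SimSpec(n_peptide=60, n_noise=60, seed=7, separation=2.0))
    return examples, groups


#: one-entry grids so ensemble tests train in seconds
SMALL_GRIDS = {
    "svm": [{"C": 1.0}],
    "knn": [{"n_neighbors": 5}],
    "ann": [{"hidden_layer_sizes": (10,), "alpha": 1e-3}],
    "rf": [{"n_estimators": 50, "max_depth": 5}],
    "xgb": [{"n_estimators": 50, "max_depth": 3, "learning_rate": 0.1}],
}


@pytest.fixture(scope="session")
def small_model(small_dataset):
    examples, _ = small_dataset
    return train_ensemble(examples, seed=11, grids=SMALL_GRIDS)
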