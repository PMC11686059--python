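import numpy as np
import pytest

from netenergy.core_energy import ConnectivityMatrix
from netenergy.synthetic_data import SyntheticParams, generate_cohort


def random_matrix(n, seed, subject_id="sub", condition="rest"):
    """Valid random symmetric matrix with Uniform(-1, 1) off-diagonal weights."""
    rng = np.random.default_rng(seed)
    w = rng.uniform(-1, 1, size=(n, n))
    w = (w + w.T) / 2
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(weights=w, subject_id=subject_id, condition=condition)


def complete_matrix(n, value, **kwargs):
    w = np.full((n, n), float(value))
    np.fill_diagonal(w, 0.0)
    return ConnectivityMatrix(weights=w, **kwargs)


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 6-subject cohort with a rest-vs-task conflict contrast."""
    params = SyntheticParams(
        n_subjects=6,
        n_regions=36,
        n_networks=4,
        t_points=80,
        conflict_kappa={
            "rest": 0.05,
            "shifting": 0.25,
            "nback0": 0.25,
            "nback1": 0.25,
            "nback2": 0.25,
            "gng_initiation": 0.25,
            "gng_inhibition": 0.25,
        },
        seed=42,
    )
    return generate_cohort(params)
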