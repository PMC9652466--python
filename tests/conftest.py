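import numpy as np
import pytest

import tpdcnet as t

A_COUPLED = np.array([[0.5, 0.0], [0.4, 0.5]])


@pytest.fixture(scope="session")
def coupled_var1_series():
    """Long VAR(1) realisation with unidirectional coupling 1 -> 2."""
    spec = t.MVARSpec(
        n_channels=2,
        order=1,
        coeff_fn=t.constant_coeff_fn(A_COUPLED),
        noise_cov=np.eye(2),
        sampling_rate=1.0,
        n_samples=5000,
    )
    return t.simulate_mvar(spec, seed=11)


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a 3-feature planted response (100 rows)."""
    spec = t.CohortSpec(
        n_per_group=25,
        true_subset=("CB->SC", "MC->SC", "PFC->MC"),
        response_coeffs=(0.9, 0.7, 0.6),
        noise_sd=0.02,
        seed=5,
    )
    return t.simulate_cohort(spec)


@pytest.fixture(scope="session")
def separable_cohort():
    """Cohort with planted group differences for classification."""
    spec = t.CohortSpec(
        n_per_group=25,
        group_effects={"CB->SC": -0.18, "MC->SC": -0.15},
        seed=7,
    )
    return t.simulate_cohort(spec)
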