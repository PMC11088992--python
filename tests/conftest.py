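import numpy as np
import pytest

from attrinf import CohortSpec, ModelParams, generate_cohort_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def m3_params():
    """Mid-range M3 parameter set used across tests."""
    return ModelParams.from_free(
        "M3", pHI0=0.3, pSI0=0.55, uPri=2.5, u_pi=1.8, eta=0.5,
        w0=-1.5, wHI=0.25, wSI=0.35,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Six-subject cohort with all three conditions (fast fixture)."""
    spec = CohortSpec(n_subjects=6, seed=77)
    dataset, truth = generate_cohort_dataset(spec, "M3", 77)
    return spec, dataset, truth


def random_m1_paramsets(n, seed):
    """Random full-model parameter draws in a broad plausible region."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        out.append(
            ModelParams.from_free(
                "M1",
                pHI0=rng.uniform(0.05, 0.95),
                pSI0=rng.uniform(0.05, 0.95),
                uPri_HI=rng.uniform(0.3, 8.0),
                uPri_SI=rng.uniform(0.3, 8.0),
                u_pi=rng.uniform(0.3, 6.0),
                eta=rng.uniform(0.0, 1.0),
                w0=rng.uniform(-3.0, 3.0),
                wHI=rng.uniform(-1.0, 1.0),
                wSI=rng.uniform(-1.0, 1.0),
            )
        )
    return out
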