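import numpy as np
import pytest
from hypothesis import settings, HealthCheck

import chdcortex as cc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def zero_noise_spec(**kw):
    """Simulation parameters with noise and site effects switched off."""
    base = dict(
        noise_sd={"ct": 0.0, "sa": 0.0, "gi": 0.0},
        batch_shift={"ct": 0.0, "sa": 0.0, "gi": 0.0},
        batch_var_scale={"ct": 1.0, "sa": 1.0, "gi": 1.0},
        batch_cov_strength={"ct": 0.0, "sa": 0.0, "gi": 0.0},
    )
    base.update(kw)
    return cc.SimulationSpec(**base)


@pytest.fixture(scope="session")
def small_cohort():
    """Default-condition cohort at a small grid: 40 subjects, 320 vertices."""
    spec = cc.SimulationSpec(n_per_group=20, grid_shape=(10, 16), k=4)
    return cc.simulate_cohort(spec, seed=7) + (spec,)


@pytest.fixture(scope="session")
def noiseless_cohort():
    spec = zero_noise_spec(n_per_group=20, grid_shape=(10, 16), k=4)
    return cc.simulate_cohort(spec, seed=3) + (spec,)


@pytest.fixture(scope="session")
def prepared_fit(small_cohort):
    """Masked + residualized + z-scored input and its k=4 factorization."""
    cohort, features, truth, spec = small_cohort
    masked = cc.apply_midline_mask(features)
    resid = cc.residualize_on_volume(
        masked.metrics, cohort["total_cgm_volume"].to_numpy()
    )
    inp = cc.build_opnmf_input(resid, masked.subject_order)
    fit = cc.fit_opnmf(inp.V, spec.k)
    return cohort, masked, inp, fit, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
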