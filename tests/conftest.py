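import numpy as np
import pytest

from coxscreen import SimulationConfig, generate_cohort


def surv(bundle):
    """(time, event) arrays from a simulated cohort bundle."""
    t = bundle.clinical["os_months"].to_numpy()
    e = (bundle.clinical["vital_status"] == "Dead").to_numpy().astype(float)
    return t, e


def make_cohort(seed=0, **kwargs):
    kwargs.setdefault("n_patients", 200)
    kwargs.setdefault("n_genes", 3)
    cfg = SimulationConfig(seed=seed, **kwargs)
    return generate_cohort(cfg)


def random_survival(rng, n, censor_frac=0.3, tied=False):
    """Small random survival dataset for oracle cross-checks."""
    if tied:
        t = rng.integers(1, 8, n).astype(float)
    else:
        t = rng.exponential(10.0, n) + 0.01
    e = (rng.random(n) > censor_frac).astype(float)
    if e.sum() == 0:
        e[rng.integers(n)] = 1.0
    return t, e


@pytest.fixture
def small_cohort():
    return make_cohort(seed=7, n_patients=120, n_genes=4,
                       planted_genes=((0, 0.5),),
                       methylation_targets=(("cg_test", 0, -0.5),))
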