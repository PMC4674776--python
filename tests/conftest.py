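import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_fit():
    """A scaled two-group fit shared across inference/diagnostics tests.

    8 mice per group and short chains keep it fast; everything checked on it
    is either structural or tolerant of the reduced draw count.
    """
    from mazelearn import GroupCurve, SamplerConfig, TrueParameters, fit_cohort, simulate_cohort

    truth = TrueParameters(
        groups=(("WT", "scr"), ("WT", "sh1")),
        curves=(GroupCurve(45.0, 1.5), GroupCurve(45.0, 0.8)),
        mice_per_group=(8, 8),
        seed=5,
    )
    cohort, _ = simulate_cohort(truth)
    result = fit_cohort(
        cohort,
        config=SamplerConfig(n_chains=2, burn_in=300, draws_per_chain=500, base_seed=5),
    )
    return truth, cohort, result


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
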