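import numpy as np
import pandas as pd
import pytest

from olivesig import synthetic_cohort as syn


@pytest.fixture(scope="session")
def small_config():
    # 300 participants, 40 metabolites in blocks of 10, one active block per
    # oil variety — small enough for fast unit tests, same structure as the
    # full-scale defaults
    return syn.SimConfig(
        n_participants=300, n_metabolites=40, n_active_per_exposure=10,
        signal_r2=0.3, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return syn.generate_cohort(small_config)


@pytest.fixture(scope="session")
def outcome_toolkit():
    """Minimal cohort/score/outcome builder for survival tests."""

    def build(n=400, seed=0, log_hr=np.log(0.79), censoring=0.8):
        cfg = syn.SimConfig(
            n_participants=n, n_metabolites=4, n_active_per_exposure=1,
            seed=seed, log_hr_per_sd=log_hr, censoring_rate=censoring,
        )
        rng = np.random.default_rng(seed)
        score = rng.standard_normal(n)
        cohort = pd.DataFrame({
            "participant_id": [f"P{i:05d}" for i in range(n)],
            "visit": "baseline",
        })
        outcomes = syn.generate_outcomes(cohort, score, cfg)
        return cohort, score, outcomes, cfg

    return build
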