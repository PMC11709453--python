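import dataclasses

import pandas as pd
import pytest

import snarcflex as sf


@pytest.fixture(scope="session")
def noiseless_exp2_bundle():
    """Small noiseless cohort run through simulate -> preprocess -> fit."""
    params = sf.PopulationParams.reference("exp2").with_noise_off()
    trials, meta = sf.simulate_cohort(params, "exp2", 12, seed=11)
    clean, report = sf.preprocess(trials, meta)
    drt = sf.compute_drt(clean)
    fits = sf.fit_all(drt, include_parity=True)
    return {"params": params, "trials": trials, "meta": meta, "clean": clean,
            "report": report, "drt": drt, "fits": fits, "seed": 11}


@pytest.fixture(scope="session")
def noisy_exp1_cohort():
    params = sf.PopulationParams.reference("exp1")
    trials, meta = sf.simulate_cohort(params, "exp1", 25, seed=7)
    return params, trials, meta


def cohort_true_params(params, n, seed):
    """The participant parameters a seeded simulate_cohort call realizes."""
    import numpy as np

    ss = np.random.SeedSequence(seed).spawn(n + 1)[0]
    return sf.sample_population(params, n, np.random.default_rng(ss))


@pytest.fixture
def compliant_meta():
    return pd.DataFrame({
        "participant_id": ["a"], "age": [25], "serious": [True],
        "environment": ["quiet"], "distractions": ["none"],
        "finger_compliance": [True],
    })
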