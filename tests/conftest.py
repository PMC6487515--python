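import numpy as np
import pandas as pd
import pytest

import ratarget as rt


@pytest.fixture(scope="session")
def tariff():
    return rt.example_tariff()


@pytest.fixture(scope="session")
def step_up():
    return rt.build_strategy("STEP_UP")


@pytest.fixture(scope="session")
def combo():
    return rt.build_strategy("INITIAL_COMBINATION")


@pytest.fixture(scope="session")
def truth_su():
    return rt.make_truth("STEP_UP_LIKE")


@pytest.fixture(scope="session")
def truth_combo():
    return rt.make_truth("COMBO_LIKE")


@pytest.fixture(scope="session")
def registry_visits(truth_su, truth_combo, step_up, combo):
    """Two synthetic 500-patient cohorts (one per strategy), concatenated."""
    v1 = rt.generate_cohort(truth_su, step_up, n_patients=500,
                            visits_per_patient=20, seed=11,
                            patient_prefix="SU")
    v2 = rt.generate_cohort(truth_combo, combo, n_patients=500,
                            visits_per_patient=20, seed=12,
                            patient_prefix="IC")
    return pd.concat([v1, v2], ignore_index=True)


@pytest.fixture(scope="session")
def fitted(registry_visits, tariff, step_up, combo):
    """Model fitted once for the whole session."""
    model = rt.CostEffectivenessModel(registry_visits, tariff,
                                      [step_up, combo])
    return model.fit()


def random_transition_model(rng, keys):
    """Random row-stochastic matrices (Dirichlet rows) for given keys."""
    probs = {k: rng.dirichlet(np.ones(4) * 2.0, size=4) for k in keys}
    return rt.TransitionModel.from_probs(probs)


def random_state_values(rng):
    utilities = dict(zip(rt.HealthState,
                         np.sort(rng.uniform(0.2, 1.0, 4))[::-1]))
    return rt.StateValues(
        utilities=utilities,
        sick_days_per_cycle=dict(zip(rt.HealthState,
                                     np.sort(rng.uniform(0, 10, 4)))),
        hc_cost_per_cycle=dict(zip(rt.HealthState,
                                   np.sort(rng.uniform(100, 1500, 4)))),
        workforce_participation=float(rng.uniform(0.4, 0.9)),
    )
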