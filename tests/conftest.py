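import numpy as np
import pandas as pd
import pytest

from corticorl.mdp import Trajectory
from corticorl.synthetic_ehr import SeverityMDP, SimConfig, generate_cohort


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig(n_admissions=300, seed=11)


@pytest.fixture(scope="session")
def cohort_data(sim_config):
    """A moderately sized synthetic cohort shared across tests."""
    admissions, events, ground_truth = generate_cohort(sim_config)
    return admissions, events, ground_truth


@pytest.fixture(scope="session")
def severity_mdp():
    return SeverityMDP(SimConfig(n_admissions=1, seed=0))


def make_events(rows):
    """Build an event table from (admission_id, variable, hour, value, cls)."""
    base = pd.Timestamp("2020-01-01")
    return pd.DataFrame(
        [(a, v, base + pd.Timedelta(hours=h), x, c) for a, v, h, x, c in rows],
        columns=["admission_id", "variable_name", "timestamp",
                 "numeric_value", "variable_class"])


def make_admissions(specs):
    """Build an admissions table from (admission_id, age, los_hours[, died])."""
    base = pd.Timestamp("2020-01-01")
    rows = []
    for spec in specs:
        adm_id, age, los_h = spec[:3]
        died = spec[3] if len(spec) > 3 else False
        rows.append((adm_id, f"pt_{adm_id}", age, "M", base,
                     base + pd.Timedelta(hours=los_h), died))
    return pd.DataFrame(rows, columns=["admission_id", "patient_id",
                                       "age_years", "sex", "admitted_at",
                                       "discharged_at", "died_in_icu"])


def paths_to_trajectories(paths, gamma=1.0):
    """Convert SeverityMDP.sample_paths output into Trajectory objects."""
    out = []
    for i, p in enumerate(paths):
        rewards = np.zeros(p["length"])
        rewards[-1] = p["reward"]
        out.append(Trajectory(admission_id=str(i), states=p["states"],
                              actions=p["actions"], rewards=rewards,
                              died_in_icu=p["reward"] < 0, gamma=gamma))
    return out
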