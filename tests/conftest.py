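import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from centrasim import choice_model, choice_sets, synthetic

settings.register_profile(
    "ci", derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_centers(flags, minutes=None, volumes=None):
    """Small centers table from a list of (robotic, teaching, media, radio) tuples."""
    n = len(flags)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "x_km": np.zeros(n),
            "y_km": np.zeros(n),
            "robotic": [f[0] for f in flags],
            "teaching": [f[1] for f in flags],
            "media": [f[2] for f in flags],
            "radiotherapy_on_site": [f[3] for f in flags],
            "annual_volume": volumes if volumes is not None else np.full(n, 100.0),
        }
    )


def make_patients(rows):
    """Patients from (age65, comorbidity, low_ses, residence, chosen_center) tuples."""
    return pd.DataFrame(
        {
            "id": np.arange(len(rows)),
            "x_km": np.zeros(len(rows)),
            "y_km": np.zeros(len(rows)),
            "age65": [r[0] for r in rows],
            "comorbidity": [r[1] for r in rows],
            "low_ses": [r[2] for r in rows],
            "residence": [r[3] for r in rows],
            "chosen_center": pd.array([r[4] for r in rows], dtype="Int64"),
        }
    )


def make_matrix(minutes, patient_ids=None, center_ids=None):
    minutes = np.asarray(minutes, dtype=float)
    n, m = minutes.shape
    return pd.DataFrame(
        minutes,
        index=pd.Index(patient_ids if patient_ids is not None else np.arange(n),
                       name="patient_id"),
        columns=pd.Index(center_ids if center_ids is not None else np.arange(m),
                         name="center_id"),
    )


@pytest.fixture(scope="session")
def table_params():
    """The national revealed-preference odds ratios as coefficients."""
    return choice_model.ChoiceParams.from_odds_ratios(choice_model.DEFAULT_CHOICE_ORS)


@pytest.fixture(scope="session")
def small_world(table_params):
    """A modest synthetic study: cohort, choice sets, and a fitted model."""
    cfg = synthetic.SyntheticConfig(seed=11, n_patients=1500, n_centers=20)
    patients, centers = synthetic.generate_population(cfg)
    matrix = synthetic.build_travel_matrix(patients, centers, cfg)
    patients = synthetic.simulate_choices(patients, centers, matrix,
                                          params=table_params, seed=12)
    patients = patients.dropna(subset=["chosen_center"]).reset_index(drop=True)
    matrix = matrix.loc[patients["id"]]
    sets = choice_sets.build_all_choice_sets(matrix)
    cohort, report = choice_sets.apply_exclusions(patients, sets)
    fit = choice_model.fit(cohort, sets, centers)
    return {
        "config": cfg,
        "patients": patients,
        "centers": centers,
        "matrix": matrix,
        "choice_sets": sets,
        "cohort": cohort,
        "report": report,
        "fit": fit,
    }
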