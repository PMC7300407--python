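"""Parameter-recovery experiments: simulate from known truth, refit, compare.

These experiments are the package's substitute for access to the
restricted national registry: if the machinery is correct, fitting the
choice model to a cohort simulated from known odds ratios must recover
them (truth inside the fitted 95% Wald CI), and likewise for the equity
regression on simulated travel-time deltas.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import choice_model, choice_sets, equity, synthetic

__all__ = ["EQUITY_TRUTH_VOLUME_SCENARIO", "run_choice_recovery",
           "run_equity_recovery"]

#: Ground-truth equity coefficients (minutes) for the volume-closure
#: scenario: base-case extra travel and adjusted group differences, used
#: as the data-generating truth for the equity recovery experiment.
EQUITY_TRUTH_VOLUME_SCENARIO = {
    "intercept": 29.10,
    "age65": -0.74,
    "low_ses": -0.80,
    "comorbidity": 2.86,
    "london": -23.25,
    "rural": 4.31,
}


def run_choice_recovery(seed: int, n_patients: int = 20_000, n_centers: int = 60,
                        true_ors: dict | None = None) -> pd.DataFrame:
    """Simulate a cohort from known odds ratios and refit the choice model.

    Returns one row per model term: the true OR, recovered OR, its 95%
    Wald CI, and whether the truth lies inside.
    """
    if true_ors is None:
        true_ors = choice_model.DEFAULT_CHOICE_ORS
    params = choice_model.ChoiceParams.from_odds_ratios(true_ors)
    cfg = synthetic.SyntheticConfig(seed=seed, n_patients=n_patients,
                                    n_centers=n_centers)
    patients, centers = synthetic.generate_population(cfg)
    matrix = synthetic.build_travel_matrix(patients, centers, cfg)
    patients = synthetic.simulate_choices(patients, centers, matrix,
                                          params=params, seed=seed + 1)
    patients = patients.dropna(subset=["chosen_center"]).reset_index(drop=True)
    sets = choice_sets.build_all_choice_sets(matrix)
    cohort, _ = choice_sets.apply_exclusions(patients, sets)
    fit = choice_model.fit(cohort, sets, centers)
    rows = []
    for term in choice_model.PARAM_NAMES:
        lo, hi = fit.ci(term)
        rows.append({
            "term": term,
            "true_or": true_ors[term],
            "recovered_or": fit.odds_ratio(term),
            "ci_low": lo,
            "ci_high": hi,
            "covered": lo <= true_ors[term] <= hi,
        })
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["fit"] = fit
    out.attrs["n_patients"] = fit.n_patients
    return out


def run_equity_recovery(seed: int, n: int = 4_000, noise_sd: float = 20.0,
                        truth: dict | None = None) -> pd.DataFrame:
    """Simulate affected-patient deltas from known coefficients and refit OLS."""
    if truth is None:
        truth = EQUITY_TRUTH_VOLUME_SCENARIO
    df = synthetic.simulate_equity_deltas(n, truth, noise_sd=noise_sd, seed=seed)
    records = pd.DataFrame({
        "patient_id": df["id"],
        "scenario": "A_volume",
        "delta_expected": df["delta_expected"],
        "stranded": False,
    })
    patients = df[["id", "age65", "low_ses", "comorbidity"]].copy()
    patients["residence"] = np.where(df["london"], "london",
                                     np.where(df["rural"], "rural", "other_urban"))
    efit = equity.fit_equity(records, patients, scenario="A_volume")
    table = efit.to_frame()
    name_map = {"const": "intercept", **{t: t for t in equity.EQUITY_TERMS}}
    rows = []
    for key, truth_name in name_map.items():
        est = table.loc[key]
        rows.append({
            "term": truth_name,
            "true_minutes": truth[truth_name],
            "estimate": est["estimate"],
            "ci_low": est["ci_low"],
            "ci_high": est["ci_high"],
            "covered": est["ci_low"] <= truth[truth_name] <= est["ci_high"],
        })
    out = pd.DataFrame(rows).set_index("term")
    out.attrs["n_patients"] = efit.n_patients
    return out
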