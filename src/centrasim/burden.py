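"""Post-centralization travel burden per displaced patient.

Two post-closure assignments are compared for every affected patient:

* **preference-weighted** — the expected travel time under the fitted
  conditional logit, i.e. choice probabilities renormalized over the
  surviving in-range centers used as weights on their travel times;
* **distance minimization** — the travel time to the nearest surviving
  center, ignoring preferences.

Since a weighted mean can never fall below the minimum of its support,
the nearest-center time bounds the expected time from below patient by
patient, so the distance-minimization comparator understates the burden
by construction.

Stranded patients (no surviving center within reach) have no weighted
prediction; they are summarized separately with the travel time to the
nearest open center regardless of the reach threshold.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .choice_model import ChoiceFit, ChoiceParams, PatientProfile, choice_probabilities
from .choice_sets import ChoiceSet, _canonical
from .scenarios import Scenario, affected_patients

__all__ = [
    "StrandedPatientError",
    "expected_post_travel",
    "nearest_post_travel",
    "compute_burden",
    "burden_summary",
    "plot_burden",
]


class StrandedPatientError(ValueError):
    """Requested a preference-weighted time for a patient with no open option."""


def _params(fit_or_params) -> ChoiceParams:
    return fit_or_params.params if isinstance(fit_or_params, ChoiceFit) else fit_or_params


def _open_subset(choice_set: ChoiceSet, scenario: Scenario) -> ChoiceSet:
    keep = np.array([c in scenario.open for c in choice_set.center_ids], dtype=bool)
    return _canonical(choice_set.patient_id,
                      choice_set.center_ids[keep], choice_set.minutes[keep])


def expected_post_travel(profile: PatientProfile, choice_set: ChoiceSet,
                         scenario: Scenario, fit, centers: pd.DataFrame) -> float:
    """Probability-weighted travel time over surviving in-range centers.

    By IIA, the softmax over the open subset equals the full-set
    probabilities renormalized over that subset.
    """
    sub = _open_subset(choice_set, scenario)
    if sub.empty:
        raise StrandedPatientError(
            f"patient {choice_set.patient_id} has no open center within reach")
    p = choice_probabilities(profile, sub, centers, _params(fit))
    return float(p.to_numpy() @ sub.minutes)


def nearest_post_travel(choice_set: ChoiceSet, scenario: Scenario,
                        matrix_row: pd.Series | None = None) -> float:
    """Minutes to the nearest surviving center.

    Restricted to the in-range choice set when it intersects the open
    centers; for a stranded patient the full matrix row must be supplied
    and the minimum is taken over all open centers, however far.
    """
    sub = _open_subset(choice_set, scenario)
    if not sub.empty:
        return float(sub.minutes.min())
    if matrix_row is None:
        raise StrandedPatientError(
            f"patient {choice_set.patient_id} is stranded; pass the matrix row "
            "for the unrestricted nearest-open time")
    open_ids = [c for c in matrix_row.index if c in scenario.open]
    return float(matrix_row.loc[open_ids].min())


def compute_burden(cohort: pd.DataFrame, choice_sets: dict, matrix: pd.DataFrame,
                   scenario: Scenario, fit, centers: pd.DataFrame) -> pd.DataFrame:
    """One burden record per affected patient under a scenario.

    Columns: pre-closure minutes (to the actually chosen center), the
    weighted and nearest post-closure times, their deltas, and a stranded
    flag.  Weighted fields are NaN for stranded patients, whose
    ``post_nearest_minutes`` is the unrestricted nearest-open time.
    Unaffected patients produce no record.
    """
    params = _params(fit)
    affected = affected_patients(cohort, scenario)
    rows = []
    for rec in affected.itertuples(index=False):
        cs = choice_sets[rec.id]
        profile = PatientProfile(
            age65=bool(rec.age65), low_ses=bool(rec.low_ses),
            comorbidity=bool(rec.comorbidity),
            london=rec.residence == "london", rural=rec.residence == "rural")
        pre = cs.minutes_to(rec.chosen_center)
        sub = _open_subset(cs, scenario)
        if sub.empty:
            post_exp = np.nan
            post_near = nearest_post_travel(cs, scenario, matrix.loc[rec.id])
            stranded = True
        else:
            post_exp = expected_post_travel(profile, cs, scenario, params, centers)
            post_near = float(sub.minutes.min())
            stranded = False
        rows.append((rec.id, scenario.name, pre, post_exp, post_near,
                     post_exp - pre, post_near - pre, stranded))
    return pd.DataFrame(
        rows,
        columns=["patient_id", "scenario", "pre_minutes", "post_expected_minutes",
                 "post_nearest_minutes", "delta_expected", "delta_nearest",
                 "stranded"],
    )


def burden_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-scenario aggregate travel burden.

    Means are over affected, non-stranded patients; relative increases
    are ratios of means (mean delta / mean pre).  Stranded patients are
    counted and summarized separately with their unrestricted
    nearest-open times.
    """
    out = []
    scenario_names = records["scenario"].unique() if len(records) else []
    for name in scenario_names:
        rec = records[records["scenario"] == name]
        ok = rec[~rec["stranded"]]
        st = rec[rec["stranded"]]
        row = {
            "scenario": name,
            "n_affected": len(rec),
            "n_stranded": len(st),
            "mean_pre": ok["pre_minutes"].mean(),
            "mean_post_expected": ok["post_expected_minutes"].mean(),
            "mean_post_nearest": ok["post_nearest_minutes"].mean(),
            "mean_delta_expected": ok["delta_expected"].mean(),
            "mean_delta_nearest": ok["delta_nearest"].mean(),
            "stranded_mean_pre": st["pre_minutes"].mean() if len(st) else np.nan,
            "stranded_mean_post_nearest":
                st["post_nearest_minutes"].mean() if len(st) else np.nan,
        }
        row["rel_increase_expected_pct"] = (
            100.0 * row["mean_delta_expected"] / row["mean_pre"]
            if len(ok) else np.nan)
        row["rel_increase_nearest_pct"] = (
            100.0 * row["mean_delta_nearest"] / row["mean_pre"]
            if len(ok) else np.nan)
        out.append(row)
    cols = ["scenario", "n_affected", "n_stranded", "mean_pre",
            "mean_post_expected", "mean_post_nearest", "mean_delta_expected",
            "mean_delta_nearest", "rel_increase_expected_pct",
            "rel_increase_nearest_pct", "stranded_mean_pre",
            "stranded_mean_post_nearest"]
    return pd.DataFrame(out, columns=cols)


def plot_burden(summary: pd.DataFrame, path=None):
    """Grouped bars of pre vs post (weighted and nearest) mean travel times."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    x = np.arange(len(summary))
    width = 0.27
    fig, ax = plt.subplots(figsize=(7, 4))
    ax.bar(x - width, summary["mean_pre"], width, label="pre-centralization")
    ax.bar(x, summary["mean_post_expected"], width,
           label="post (preference-weighted)")
    ax.bar(x + width, summary["mean_post_nearest"], width,
           label="post (nearest open)")
    ax.set_xticks(x, summary["scenario"])
    ax.set_ylabel("mean travel time (minutes)")
    ax.set_title("Travel burden of affected patients by closure scenario")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
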