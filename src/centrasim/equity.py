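"""Equity regression: who bears the extra travel after centralization.

Ordinary least squares of the per-patient change in travel time
(preference-weighted post minus pre, minutes) on the five patient
characteristics — age >= 65, low socioeconomic status, comorbidity, and
London/rural residence dummies against "other urban" — with an
intercept.  The intercept is the mean extra travel of the base-case
patient; each coefficient is the adjusted difference for that group, in
minutes.  Classical (homoskedastic) standard errors, 95% confidence
intervals and two-sided p-values.  Stranded patients carry no weighted
delta and are dropped before fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .choice_model import PatientProfile

__all__ = ["EQUITY_TERMS", "EquityFit", "RankDeficiencyError",
           "fit_equity", "predict_profile"]

EQUITY_TERMS = ("age65", "low_ses", "comorbidity", "london", "rural")


class RankDeficiencyError(ValueError):
    """The equity design matrix is not full rank; names the offending columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            f"equity design is rank deficient; collinear/constant columns: "
            f"{self.columns}")


@dataclass
class EquityFit:
    """Fitted equity regression for one scenario."""

    scenario: str
    n_patients: int
    estimates: pd.Series      # index: const + EQUITY_TERMS, minutes
    ci: pd.DataFrame          # columns ci_low, ci_high
    pvalues: pd.Series
    resid: np.ndarray
    exog: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"estimate": self.estimates})
        out[["ci_low", "ci_high"]] = self.ci
        out["p"] = self.pvalues
        out.index.name = "term"
        return out


def _design(df: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame({t: df[t].astype(float) for t in EQUITY_TERMS})
    return sm.add_constant(X, has_constant="add")


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy()
    rank = np.linalg.matrix_rank(arr)
    if rank == arr.shape[1]:
        return
    # identify offending columns: constant dummies first, then QR diagnostics
    bad = [c for c in X.columns if c != "const" and X[c].nunique() <= 1]
    if not bad:
        _, R = np.linalg.qr(arr)
        diag = np.abs(np.diag(R))
        bad = [X.columns[i] for i in np.flatnonzero(diag < 1e-8 * diag.max())]
    raise RankDeficiencyError(bad or list(X.columns))


def fit_equity(records: pd.DataFrame, patients: pd.DataFrame,
               scenario: str | None = None, min_n: int = 10) -> EquityFit:
    """OLS of the weighted travel-time delta on patient characteristics.

    ``records`` is the per-patient burden table for one scenario;
    ``patients`` supplies the covariates.  Requires at least ``min_n``
    affected non-stranded patients and a full-rank design.
    """
    rec = records[~records["stranded"]]
    if scenario is None:
        names = rec["scenario"].unique()
        if len(names) != 1:
            raise ValueError("records span multiple scenarios; pass `scenario`")
        scenario = names[0]
    else:
        rec = rec[rec["scenario"] == scenario]
    cov = patients.set_index("id")
    df = rec[["patient_id", "delta_expected"]].copy()
    for t in ("age65", "low_ses", "comorbidity"):
        df[t] = cov.loc[df["patient_id"], t].to_numpy()
    res_class = cov.loc[df["patient_id"], "residence"].to_numpy()
    df["london"] = res_class == "london"
    df["rural"] = res_class == "rural"

    if len(df) < min_n:
        raise ValueError(
            f"only {len(df)} affected non-stranded patients; need >= {min_n}")
    X = _design(df)
    _check_rank(X)
    res = sm.OLS(df["delta_expected"].to_numpy(), X).fit()
    ci = res.conf_int(alpha=0.05)
    ci.columns = ["ci_low", "ci_high"]
    return EquityFit(
        scenario=scenario,
        n_patients=len(df),
        estimates=res.params,
        ci=ci,
        pvalues=res.pvalues,
        resid=np.asarray(res.resid),
        exog=X.to_numpy(),
    )


def predict_profile(fit: EquityFit, profile: PatientProfile) -> float:
    """Predicted extra travel (minutes) for a profile: intercept + active terms."""
    extra = fit.estimates[list(EQUITY_TERMS)].to_numpy() @ np.array(
        [profile.age65, profile.low_ses, profile.comorbidity,
         profile.london, profile.rural], dtype=float)
    return float(fit.estimates["const"] + extra)
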