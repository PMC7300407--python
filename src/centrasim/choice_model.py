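"""Conditional logit model of hospital choice.

Each patient chooses a surgery center from the centers within reach of
their home.  The utility of center *j* for patient *i* is linear in the
car travel time t_ij (minutes), with the per-minute disutility shifted by
patient characteristics (age ≥ 65, low socioeconomic status, comorbidity,
London residence, rural residence — the latter two as dummies against
"other urban"), plus main effects of three center attributes (strong
media reputation, university teaching hospital, established robotic
center):

    U_ij = (beta_t + sum_k gamma_k z_ik) * t_ij + sum_a delta_a w_ja

There are no alternative-specific constants; center heterogeneity enters
only through the three attribute flags.  Choice probabilities are the
softmax of utilities over the patient's choice set (McFadden's
conditional logit), which implies the IIA property: probabilities over a
restricted set equal the full-set probabilities renormalized — the
mathematical basis of the post-closure predictions downstream.

Estimation is by direct maximization of the conditional log-likelihood
with analytic gradient and Hessian (Newton iteration with step-halving);
the covariance of the estimates is the inverse observed information at
the optimum, and confidence intervals are Wald intervals on the
coefficient scale, exponentiated to odds ratios.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_CHOICE_ORS",
    "ChoiceParams",
    "PatientProfile",
    "ChoiceFit",
    "utility",
    "utility_matrix",
    "choice_probabilities",
    "build_design",
    "log_likelihood",
    "gradient",
    "fit",
    "compose_travel_or",
    "SeparationError",
]

#: Canonical parameter order used everywhere (arrays, covariance, tables).
PARAM_NAMES = (
    "travel_time",
    "travel_time:age65",
    "travel_time:low_ses",
    "travel_time:comorbidity",
    "travel_time:london",
    "travel_time:rural",
    "media",
    "teaching",
    "robotic",
)

#: Default data-generating odds ratios for the synthetic cohort: the
#: revealed-preference estimates for English NHS radical prostatectomy
#: (2010-2014) that the generator emulates.  Travel-time terms are per
#: minute; center attributes are main-effect odds ratios.
DEFAULT_CHOICE_ORS = {
    "travel_time": 0.920,
    "travel_time:age65": 0.991,
    "travel_time:low_ses": 0.996,
    "travel_time:comorbidity": 0.987,
    "travel_time:london": 0.846,
    "travel_time:rural": 1.021,
    "media": 1.933,
    "teaching": 0.928,
    "robotic": 1.756,
}

CENTER_ATTRS = ("media", "teaching", "robotic")


class SeparationError(RuntimeError):
    """A coefficient diverged during estimation (quasi-complete separation)."""


@dataclass(frozen=True)
class ChoiceParams:
    """Coefficients of the choice model on the log-odds scale.

    ``travel_time`` is the base-case per-minute coefficient; the ``tt_*``
    fields are per-minute shifts for the five patient characteristics;
    ``media``/``teaching``/``robotic`` are center-attribute main effects.
    """

    travel_time: float
    tt_age65: float = 0.0
    tt_low_ses: float = 0.0
    tt_comorbidity: float = 0.0
    tt_london: float = 0.0
    tt_rural: float = 0.0
    media: float = 0.0
    teaching: float = 0.0
    robotic: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ChoiceParams":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (9,):
            raise ValueError(f"expected 9 coefficients, got shape {arr.shape}")
        return cls(*arr)

    @classmethod
    def from_odds_ratios(cls, ors: dict) -> "ChoiceParams":
        """Build coefficients from a mapping keyed by :data:`PARAM_NAMES`."""
        missing = set(PARAM_NAMES) - set(ors)
        if missing:
            raise KeyError(f"missing odds ratios for {sorted(missing)}")
        return cls.from_array([math.log(ors[name]) for name in PARAM_NAMES])

    def odds_ratios(self) -> pd.Series:
        """Elementwise exp view of the coefficients."""
        return pd.Series(np.exp(self.to_array()), index=list(PARAM_NAMES))


@dataclass(frozen=True)
class PatientProfile:
    """The five choice-relevant patient characteristics.

    The base case (all flags False) is a man under 65, with no recorded
    comorbidity, of high socioeconomic status, living in an urban area
    outside London.
    """

    age65: bool = False
    low_ses: bool = False
    comorbidity: bool = False
    london: bool = False
    rural: bool = False

    def __post_init__(self):
        if self.london and self.rural:
            raise ValueError("residence is one category: london and rural cannot both be set")

    def interaction_vector(self) -> np.ndarray:
        return np.array(
            [self.age65, self.low_ses, self.comorbidity, self.london, self.rural],
            dtype=float,
        )

    @classmethod
    def from_patient_row(cls, row) -> "PatientProfile":
        return cls(
            age65=bool(row["age65"]),
            low_ses=bool(row["low_ses"]),
            comorbidity=bool(row["comorbidity"]),
            london=row["residence"] == "london",
            rural=row["residence"] == "rural",
        )


def travel_slope(profile: PatientProfile, params: ChoiceParams) -> float:
    """Per-minute utility slope for a profile: beta_t plus active interactions."""
    gammas = np.array(
        [params.tt_age65, params.tt_low_ses, params.tt_comorbidity,
         params.tt_london, params.tt_rural]
    )
    return float(params.travel_time + gammas @ profile.interaction_vector())


def utility(profile: PatientProfile, center, minutes: float, params: ChoiceParams) -> float:
    """Deterministic utility of one center for one patient.

    ``center`` is any mapping with boolean ``media``, ``teaching`` and
    ``robotic`` entries (e.g. a row of the centers table).
    """
    if minutes < 0:
        raise ValueError("travel time must be nonnegative")
    attr = (
        params.media * bool(center["media"])
        + params.teaching * bool(center["teaching"])
        + params.robotic * bool(center["robotic"])
    )
    return travel_slope(profile, params) * minutes + attr


def utility_matrix(patients: pd.DataFrame, centers: pd.DataFrame,
                   minutes: np.ndarray, params: ChoiceParams) -> np.ndarray:
    """Vectorized utilities for every patient x center pair.

    ``minutes`` is an (n_patients, n_centers) array aligned with the row
    order of the two tables.
    """
    z = np.column_stack([
        patients["age65"].to_numpy(dtype=float),
        patients["low_ses"].to_numpy(dtype=float),
        patients["comorbidity"].to_numpy(dtype=float),
        (patients["residence"] == "london").to_numpy(dtype=float),
        (patients["residence"] == "rural").to_numpy(dtype=float),
    ])
    gammas = np.array([params.tt_age65, params.tt_low_ses, params.tt_comorbidity,
                       params.tt_london, params.tt_rural])
    slope = params.travel_time + z @ gammas           # (n_patients,)
    attr = (params.media * centers["media"].to_numpy(dtype=float)
            + params.teaching * centers["teaching"].to_numpy(dtype=float)
            + params.robotic * centers["robotic"].to_numpy(dtype=float))
    return slope[:, None] * minutes + attr[None, :]


def choice_probabilities(profile: PatientProfile, choice_set, centers: pd.DataFrame,
                         params: ChoiceParams) -> pd.Series:
    """Conditional-logit probabilities over the alternatives of a choice set.

    Computed as a max-subtracted softmax; sums to 1 to ~1e-16.
    """
    if choice_set.n_alternatives == 0:
        raise ValueError(f"empty choice set for patient {choice_set.patient_id}")
    cen = centers.set_index("id") if "id" in centers.columns else centers
    cen = cen.loc[choice_set.center_ids]
    attr = (params.media * cen["media"].to_numpy(dtype=float)
            + params.teaching * cen["teaching"].to_numpy(dtype=float)
            + params.robotic * cen["robotic"].to_numpy(dtype=float))
    u = travel_slope(profile, params) * choice_set.minutes + attr
    u -= u.max()
    e = np.exp(u)
    return pd.Series(e / e.sum(), index=pd.Index(choice_set.center_ids, name="center_id"))


# ---------------------------------------------------------------------------
# Estimation


@dataclass
class Design:
    """Stacked patient-alternative design for the likelihood.

    Rows are grouped contiguously by patient; ``starts`` indexes the first
    row of each group, ``chosen`` marks the observed alternative.
    """

    X: np.ndarray           # (n_rows, 9)
    groups: np.ndarray      # (n_rows,) patient index 0..G-1
    starts: np.ndarray      # (G,) first row of each group
    chosen: np.ndarray      # (G,) row index of the chosen alternative
    patient_ids: np.ndarray

    @property
    def n_patients(self) -> int:
        return len(self.starts)

    @property
    def n_observations(self) -> int:
        return self.X.shape[0]


def build_design(cohort: pd.DataFrame, choice_sets: dict, centers: pd.DataFrame) -> Design:
    """Assemble the stacked design matrix from a cohort and its choice sets."""
    cen = centers.set_index("id") if "id" in centers.columns else centers
    attr = cen[list(CENTER_ATTRS)].astype(float)

    X_parts, group_parts, chosen_rows, starts = [], [], [], []
    row0 = 0
    pids = cohort["id"].to_numpy()
    z_all = np.column_stack([
        cohort["age65"].to_numpy(dtype=float),
        cohort["low_ses"].to_numpy(dtype=float),
        cohort["comorbidity"].to_numpy(dtype=float),
        (cohort["residence"] == "london").to_numpy(dtype=float),
        (cohort["residence"] == "rural").to_numpy(dtype=float),
    ])
    chosen_all = cohort["chosen_center"].to_numpy()
    for i, pid in enumerate(pids):
        cs = choice_sets[pid]
        ids, mins = cs.center_ids, cs.minutes
        if len(np.unique(ids)) != len(ids):
            raise ValueError(f"duplicate center ids in choice set of patient {pid}")
        k = len(ids)
        mult = np.concatenate([[1.0], z_all[i]])          # (6,)
        Xi = np.empty((k, 9))
        Xi[:, :6] = mins[:, None] * mult[None, :]
        Xi[:, 6:] = attr.loc[ids].to_numpy()
        pos = np.flatnonzero(ids == chosen_all[i])
        if pos.size != 1:
            raise ValueError(
                f"chosen center {chosen_all[i]} not in choice set of patient {pid}")
        X_parts.append(Xi)
        group_parts.append(np.full(k, i))
        starts.append(row0)
        chosen_rows.append(row0 + pos[0])
        row0 += k
    return Design(
        X=np.concatenate(X_parts, axis=0),
        groups=np.concatenate(group_parts),
        starts=np.asarray(starts, dtype=np.intp),
        chosen=np.asarray(chosen_rows, dtype=np.intp),
        patient_ids=pids,
    )


def _eval(beta: np.ndarray, d: Design, order: int = 2):
    """Log-likelihood and, if requested, analytic score and Hessian."""
    eta = d.X @ beta
    m = np.maximum.reduceat(eta, d.starts)
    e = np.exp(eta - m[d.groups])
    denom = np.add.reduceat(e, d.starts)
    ll = float(eta[d.chosen].sum() - (m + np.log(denom)).sum())
    if order == 0:
        return ll, None, None
    p = e / denom[d.groups]
    pX = p[:, None] * d.X
    k = d.X.shape[1]
    xbar = np.empty((d.n_patients, k))
    for c in range(k):
        xbar[:, c] = np.add.reduceat(pX[:, c], d.starts)
    g = d.X[d.chosen].sum(axis=0) - xbar.sum(axis=0)
    if order == 1:
        return ll, g, None
    H = -(d.X.T @ pX - xbar.T @ xbar)
    return ll, g, H


def log_likelihood(params: ChoiceParams, cohort, choice_sets, centers) -> float:
    """Conditional log-likelihood of the observed choices; always <= 0."""
    d = build_design(cohort, choice_sets, centers)
    return _eval(params.to_array(), d, order=0)[0]


def gradient(params: ChoiceParams, cohort, choice_sets, centers) -> np.ndarray:
    """Analytic score vector of the log-likelihood, in :data:`PARAM_NAMES` order."""
    d = build_design(cohort, choice_sets, centers)
    return _eval(params.to_array(), d, order=1)[1]


@dataclass
class ChoiceFit:
    """Result of estimating the choice model (the published-table object)."""

    params: ChoiceParams
    covariance: np.ndarray
    table: pd.DataFrame              # term, coef, se, or, ci_low, ci_high, p
    log_likelihood: float
    n_patients: int
    n_observations: int
    converged: bool
    iterations: int
    message: str = ""

    def odds_ratio(self, term: str) -> float:
        return float(self.table.loc[term, "or"])

    def ci(self, term: str) -> tuple[float, float]:
        row = self.table.loc[term]
        return float(row["ci_low"]), float(row["ci_high"])


_DIVERGENCE_BOUND = 1e3  # |coef| beyond this on any term signals separation


def fit(cohort, choice_sets, centers, init=None, tol: float = 1e-6,
        max_iter: int = 100, terms=None) -> ChoiceFit:
    """Maximum-likelihood fit by Newton iteration with step-halving.

    Converged when the score max-norm drops below ``tol`` or the Newton
    decrement (the expected likelihood gain of the next step,
    g'H^{-1}g/2) falls below numerical precision of the log-likelihood —
    the standard stopping rule for self-concordant problems, robust to
    the floating-point noise floor of a large stacked likelihood.  The
    likelihood is globally concave, so Newton from the zero vector is
    reliable; a diverging coefficient (separation) raises
    :class:`SeparationError`.  Non-convergence within ``max_iter``
    returns partial results with ``converged=False``.

    ``terms`` optionally restricts estimation to a subset of
    :data:`PARAM_NAMES` (the rest fixed at zero) for designs where not
    every parameter is identified; the covariance and table then cover
    only the estimated terms.
    """
    d = build_design(cohort, choice_sets, centers)
    names = list(PARAM_NAMES) if terms is None else list(terms)
    if terms is not None:
        cols = [PARAM_NAMES.index(t) for t in names]
        d = Design(X=d.X[:, cols], groups=d.groups, starts=d.starts,
                   chosen=d.chosen, patient_ids=d.patient_ids)
    k = len(names)
    sizes = np.diff(np.append(d.starts, d.n_observations))
    if (sizes < 2).any():
        raise ValueError("every patient needs >= 2 alternatives to fit the model")
    beta = np.zeros(k) if init is None else np.asarray(init, dtype=float).copy()
    ll, g, H = _eval(beta, d)
    converged, it, message = False, 0, ""
    for it in range(1, max_iter + 1):
        if np.max(np.abs(g)) < tol:
            converged = True
            it -= 1
            break
        try:
            step = np.linalg.solve(-H, g)
        except np.linalg.LinAlgError as exc:
            raise SeparationError(f"singular information matrix: {exc}") from exc
        # expected gain of the full Newton step; once it is below the
        # floating-point noise of ll there is nothing left to optimize
        noise = 64.0 * np.finfo(float).eps * (1.0 + abs(ll))
        decrement = 0.5 * float(g @ step)
        if decrement < noise:
            converged = True
            it -= 1
            break
        t = 1.0
        for _ in range(40):
            beta_new = beta + t * step
            ll_new, g_new, H_new = _eval(beta_new, d)
            if np.isfinite(ll_new) and ll_new >= ll - noise:
                break
            t /= 2
        else:
            message = "step-halving failed to improve the likelihood"
            break
        beta, ll, g, H = beta_new, ll_new, g_new, H_new
        if np.max(np.abs(beta)) > _DIVERGENCE_BOUND:
            raise SeparationError(
                "a coefficient diverged; a covariate may perfectly predict choices")
        if np.max(np.abs(g)) < tol:
            converged = True
            break
    if not converged and not message:
        message = f"score max-norm {np.max(np.abs(g)):.3g} after {max_iter} iterations"

    cov = np.linalg.inv(-H)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    table = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "or": np.exp(beta),
            "ci_low": np.exp(beta - 1.96 * se),
            "ci_high": np.exp(beta + 1.96 * se),
            "p": 2 * norm.sf(np.abs(z)),
        },
        index=pd.Index(names, name="term"),
    )
    full = np.zeros(9)
    for name, b in zip(names, beta):
        full[PARAM_NAMES.index(name)] = b
    return ChoiceFit(
        params=ChoiceParams.from_array(full),
        covariance=cov,
        table=table,
        log_likelihood=ll,
        n_patients=d.n_patients,
        n_observations=d.n_observations,
        converged=converged,
        iterations=it,
        message=message,
    )


def compose_travel_or(fit_or_params, profile: PatientProfile) -> float:
    """Per-minute travel-time odds ratio for a patient profile.

    The base-case OR multiplied by the ORs of the profile's active
    interaction terms — equivalently exp of the summed coefficients.
    """
    params = fit_or_params.params if isinstance(fit_or_params, ChoiceFit) else fit_or_params
    return float(math.exp(travel_slope(profile, params)))
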