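"""Synthetic patients, centers, travel times and simulated hospital choices.

The generator reproduces the *structure* of the English radical-
prostatectomy study population on an abstract 2-D plane (km), not real
geography: one dense London-like cluster, several other-urban clusters,
and a uniform rural scatter.  Travel time is straight-line distance at a
constant driving speed, doubled (by default) when both endpoints lie in
the London cluster, which mimics the dense-but-slow character of
travel within a capital.  Chosen centers are drawn from the conditional
logit choice model itself, with the national revealed-preference odds
ratios as the data-generating truth, so that refitting the model is a
direct parameter-recovery check.

All randomness flows through an explicit integer seed; there is no
global random state, and identical configuration plus seed yields
bit-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

from .choice_model import ChoiceParams, DEFAULT_CHOICE_ORS, utility_matrix

__all__ = [
    "RESIDENCE_LEVELS",
    "SyntheticConfig",
    "generate_population",
    "build_travel_matrix",
    "simulate_choices",
    "simulate_equity_deltas",
]

RESIDENCE_LEVELS = ("london", "other_urban", "rural")
CENTER_FLAGS = ("robotic", "teaching", "media", "radiotherapy_on_site")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study-condition parameters of the synthetic cohort.

    Defaults mirror the national cohort the generator emulates: 19,029
    men and 65 centers; 14% London / 63% other-urban / 23% rural; flag
    prevalences 42% aged >= 65, 7% with comorbidity, 48% low
    socioeconomic status.  Center volumes are lognormal with median 58
    procedures/year and log-sd 0.9, so that ~43% of centers fall below
    the 50-per-year volume threshold.  Distances are converted to minutes
    at ``speed_kmh`` (default 60, i.e. km ≈ minutes), and trips with both
    endpoints within ``london_radius_km`` of the London centroid are
    multiplied by ``london_congestion_factor``.
    """

    seed: int
    n_patients: int = 19_029
    n_centers: int = 65
    region_weights: tuple = (0.14, 0.63, 0.23)        # london, other_urban, rural
    covariate_prevalences: tuple = (0.42, 0.07, 0.48)  # age65, comorbidity, low_ses
    center_attribute_prevalences: tuple = (0.40, 0.35, 0.15, 0.63)
    volume_median: float = 58.0
    volume_sigma: float = 0.9
    speed_kmh: float = 60.0
    london_congestion_factor: float = 2.0
    region_km: float = 500.0
    n_urban_clusters: int = 12
    urban_cluster_sd_km: float = 15.0
    london_sd_km: float = 12.0
    london_radius_km: float = 40.0
    london_center: tuple = (300.0, 160.0)
    center_rural_share: float = 0.10

    def validate(self) -> None:
        if self.n_centers < 2:
            raise ValueError("a choice model needs at least 2 centers")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        if abs(sum(self.region_weights) - 1.0) > 1e-9:
            raise ValueError("region_weights must sum to 1")
        for p in (*self.region_weights, *self.covariate_prevalences,
                  *self.center_attribute_prevalences):
            if not 0.0 <= p <= 1.0:
                raise ValueError("prevalences and weights must lie in [0, 1]")
        if self.speed_kmh <= 0:
            raise ValueError("speed_kmh must be positive")
        if self.london_congestion_factor < 1:
            raise ValueError("london_congestion_factor must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


def _cluster_centres(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = 0.08 * cfg.region_km, 0.92 * cfg.region_km
    return rng.uniform(lo, hi, size=(cfg.n_urban_clusters, 2))


def generate_population(config: SyntheticConfig):
    """Draw the patient and center tables; deterministic given the seed.

    Patients are placed in spatial clusters according to their residence
    class; covariates are independent Bernoulli draws at the configured
    prevalences.  Centers are placed preferentially in the same clusters
    (a small share uniformly, standing for remote district hospitals),
    with attribute flags and lognormal annual volumes.  The
    ``chosen_center`` column is left missing until
    :func:`simulate_choices` fills it.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    clusters = _cluster_centres(config, rng)
    n = config.n_patients

    residence_idx = rng.choice(3, size=n, p=np.asarray(config.region_weights))
    xy = np.empty((n, 2))
    is_lon = residence_idx == 0
    is_urb = residence_idx == 1
    is_rur = residence_idx == 2
    xy[is_lon] = np.asarray(config.london_center) + rng.normal(
        0.0, config.london_sd_km, size=(int(is_lon.sum()), 2))
    which = rng.integers(0, config.n_urban_clusters, size=int(is_urb.sum()))
    xy[is_urb] = clusters[which] + rng.normal(
        0.0, config.urban_cluster_sd_km, size=(int(is_urb.sum()), 2))
    xy[is_rur] = rng.uniform(0.0, config.region_km, size=(int(is_rur.sum()), 2))

    p_age, p_com, p_ses = config.covariate_prevalences
    patients = pd.DataFrame(
        {
            "id": np.arange(n),
            "x_km": xy[:, 0],
            "y_km": xy[:, 1],
            "age65": rng.random(n) < p_age,
            "comorbidity": rng.random(n) < p_com,
            "low_ses": rng.random(n) < p_ses,
            "residence": pd.Categorical.from_codes(residence_idx,
                                                   categories=list(RESIDENCE_LEVELS)),
            "chosen_center": pd.array([pd.NA] * n, dtype="Int64"),
        }
    )

    m = config.n_centers
    n_rural_c = int(round(config.center_rural_share * m))
    n_clustered = m - n_rural_c
    w_lon, w_urb, _ = config.region_weights
    p_lon_given_clustered = w_lon / (w_lon + w_urb) if (w_lon + w_urb) > 0 else 0.0
    cxy = np.empty((m, 2))
    in_london_cluster = np.zeros(m, dtype=bool)
    for j in range(n_clustered):
        if rng.random() < p_lon_given_clustered:
            cxy[j] = np.asarray(config.london_center) + rng.normal(
                0.0, 0.5 * config.london_sd_km, size=2)
            in_london_cluster[j] = True
        else:
            c = rng.integers(0, config.n_urban_clusters)
            cxy[j] = clusters[c] + rng.normal(0.0, 0.5 * config.urban_cluster_sd_km,
                                              size=2)
    cxy[n_clustered:] = rng.uniform(0.0, config.region_km, size=(n_rural_c, 2))

    p_rob, p_tea, p_med, p_rad = config.center_attribute_prevalences
    centers = pd.DataFrame(
        {
            "id": np.arange(m),
            "x_km": cxy[:, 0],
            "y_km": cxy[:, 1],
            "robotic": rng.random(m) < p_rob,
            "teaching": rng.random(m) < p_tea,
            "media": rng.random(m) < p_med,
            "radiotherapy_on_site": rng.random(m) < p_rad,
            "annual_volume": rng.lognormal(np.log(config.volume_median),
                                           config.volume_sigma, size=m),
        }
    )
    return patients, centers


def build_travel_matrix(patients: pd.DataFrame, centers: pd.DataFrame,
                        config: SyntheticConfig) -> pd.DataFrame:
    """Minutes by car for every patient x center pair.

    minutes = euclidean_km / speed_kmh * 60, multiplied by the congestion
    factor when both endpoints lie within the London cluster radius.
    """
    config.validate()
    km = cdist(patients[["x_km", "y_km"]].to_numpy(),
               centers[["x_km", "y_km"]].to_numpy())
    minutes = km / config.speed_kmh * 60.0
    centre = np.asarray(config.london_center)
    pat_lon = (np.linalg.norm(patients[["x_km", "y_km"]].to_numpy() - centre, axis=1)
               <= config.london_radius_km)
    cen_lon = (np.linalg.norm(centers[["x_km", "y_km"]].to_numpy() - centre, axis=1)
               <= config.london_radius_km)
    minutes[np.ix_(pat_lon, cen_lon)] *= config.london_congestion_factor
    return pd.DataFrame(minutes,
                        index=pd.Index(patients["id"].to_numpy(), name="patient_id"),
                        columns=pd.Index(centers["id"].to_numpy(), name="center_id"))


class NoChoiceSetsError(RuntimeError):
    """Every patient's choice set is empty; nothing can be simulated."""


def simulate_choices(patients: pd.DataFrame, centers: pd.DataFrame,
                     matrix: pd.DataFrame, params: ChoiceParams | None = None,
                     seed: int | None = None,
                     max_minutes: float = 180.0) -> pd.DataFrame:
    """Draw each patient's chosen center from the conditional logit.

    Sampling uses the Gumbel-max construction (argmax of utility plus iid
    Gumbel noise over the in-range alternatives), which draws exactly
    from the softmax probabilities.  Patients with no center within
    ``max_minutes`` keep a missing ``chosen_center`` — they are flagged,
    not assigned.  Returns a copy of the patient table.
    """
    if params is None:
        params = ChoiceParams.from_odds_ratios(DEFAULT_CHOICE_ORS)
    if seed is None:
        raise ValueError("an explicit integer seed is required")
    rng = np.random.default_rng(seed)
    minutes = matrix.to_numpy()
    in_range = minutes <= max_minutes
    has_option = in_range.any(axis=1)
    if not has_option.any():
        raise NoChoiceSetsError(
            f"no patient has any center within {max_minutes} minutes")
    u = utility_matrix(patients, centers, minutes, params)
    with np.errstate(invalid="ignore"):
        noisy = np.where(in_range, u + rng.gumbel(size=u.shape), -np.inf)
    pick = noisy.argmax(axis=1)
    out = patients.copy()
    chosen = matrix.columns.to_numpy()[pick]
    out["chosen_center"] = pd.array(
        [c if ok else pd.NA for c, ok in zip(chosen, has_option)], dtype="Int64")
    return out


def simulate_equity_deltas(n: int, truth: dict, prevalences: tuple = (0.42, 0.48, 0.07),
                           region_weights: tuple = (0.14, 0.63, 0.23),
                           noise_sd: float = 20.0, seed: int = 0) -> pd.DataFrame:
    """Synthetic affected-patient travel-time changes with known coefficients.

    ``truth`` maps ``intercept, age65, low_ses, comorbidity, london,
    rural`` to minutes.  Covariates are independent Bernoulli draws at the
    cohort prevalences (age65, low_ses, comorbidity), residence is a
    categorical draw, and the delta is the linear predictor plus Gaussian
    noise.  Used for coverage and recovery checks of the equity
    regression.
    """
    rng = np.random.default_rng(seed)
    p_age, p_ses, p_com = prevalences
    res = rng.choice(3, size=n, p=np.asarray(region_weights))
    df = pd.DataFrame(
        {
            "id": np.arange(n),
            "age65": rng.random(n) < p_age,
            "low_ses": rng.random(n) < p_ses,
            "comorbidity": rng.random(n) < p_com,
            "london": res == 0,
            "rural": res == 2,
        }
    )
    lp = (truth["intercept"]
          + truth["age65"] * df["age65"]
          + truth["low_ses"] * df["low_ses"]
          + truth["comorbidity"] * df["comorbidity"]
          + truth["london"] * df["london"]
          + truth["rural"] * df["rural"])
    df["delta_expected"] = lp + rng.normal(0.0, noise_sd, size=n)
    return df
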