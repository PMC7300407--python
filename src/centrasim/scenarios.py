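"""Center-closure scenarios and the patients they displace.

Three pragmatic closure rules are implemented:

* **A (volume)** — close centers performing fewer than a threshold number
  of procedures per year (default 50; a center at exactly the threshold
  stays open).
* **B (facilities)** — keep only comprehensive centers, i.e. those with
  radiotherapy on site alongside surgery, independent of volume.
* **C (capacity)** — keep the "winner" centers: those whose observed
  patient flow is at least the flow expected if every patient attended
  their nearest center (net gain >= 0); net-loss centers close.

Affected patients are those whose chosen center closes; stranded patients
are affected patients left with no surviving center within reach.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "Scenario",
    "ScenarioError",
    "scenario_volume",
    "scenario_facilities",
    "scenario_capacity",
    "flow_summary",
    "nearest_centers",
    "affected_patients",
    "stranded_patients",
]


class ScenarioError(RuntimeError):
    """A closure rule produced a degenerate configuration (e.g. no survivors)."""


@dataclass(frozen=True)
class Scenario:
    """A named partition of centers into closed and open sets."""

    name: str
    closed: frozenset
    open: frozenset

    def __post_init__(self):
        if self.closed & self.open:
            raise ValueError("closed and open sets overlap")
        if not self.open:
            raise ScenarioError(f"scenario {self.name} closes every center")

    @property
    def n_closed(self) -> int:
        return len(self.closed)

    def to_frame(self, centers: pd.DataFrame) -> pd.DataFrame:
        out = centers[["id"]].copy()
        out["status"] = np.where(out["id"].isin(list(self.closed)), "closed", "open")
        return out


def _make(name, centers, closed_mask) -> Scenario:
    ids = centers["id"].to_numpy()
    closed = frozenset(ids[closed_mask].tolist())
    if len(closed) == len(ids):
        raise ScenarioError(f"scenario {name} closes every center")
    return Scenario(name=name, closed=closed,
                    open=frozenset(ids[~closed_mask].tolist()))


def scenario_volume(centers: pd.DataFrame, threshold: float = 50.0) -> Scenario:
    """Close centers with annual volume strictly below the threshold."""
    if threshold <= 0:
        raise ValueError("volume threshold must be positive")
    return _make("A_volume", centers,
                 centers["annual_volume"].to_numpy() < threshold)


def scenario_facilities(centers: pd.DataFrame) -> Scenario:
    """Close centers without radiotherapy on site, independent of volume."""
    return _make("B_facilities", centers,
                 ~centers["radiotherapy_on_site"].to_numpy(dtype=bool))


def nearest_centers(matrix: pd.DataFrame) -> pd.Series:
    """Nearest center per patient; minute ties broken by lowest center id."""
    ordered = matrix[sorted(matrix.columns)]
    idx = ordered.to_numpy().argmin(axis=1)  # argmin keeps first = lowest id on ties
    return pd.Series(ordered.columns.to_numpy()[idx], index=matrix.index,
                     name="nearest_center")


def flow_summary(cohort: pd.DataFrame, matrix: pd.DataFrame) -> pd.DataFrame:
    """Observed versus nearest-center patient flow for every center.

    ``net_gain = n_treated - n_nearest``; the two columns each sum to the
    cohort size, so net gains sum to zero exactly.
    """
    all_ids = pd.Index(sorted(matrix.columns), name="center_id")
    treated = cohort["chosen_center"].value_counts().reindex(all_ids, fill_value=0)
    nearest = (nearest_centers(matrix.loc[cohort["id"]])
               .value_counts().reindex(all_ids, fill_value=0))
    out = pd.DataFrame({"n_treated": treated.astype(int),
                        "n_nearest": nearest.astype(int)})
    out["net_gain"] = out["n_treated"] - out["n_nearest"]
    return out


def scenario_capacity(cohort: pd.DataFrame, matrix: pd.DataFrame,
                      centers: pd.DataFrame) -> Scenario:
    """Close net-loss centers; a zero net gain counts as a winner."""
    flows = flow_summary(cohort, matrix)
    assert int(flows["net_gain"].sum()) == 0, "flow conservation violated"
    losers = flows.index[flows["net_gain"] < 0]
    closed_mask = centers["id"].isin(losers).to_numpy()
    return _make("C_capacity", centers, closed_mask)


def affected_patients(cohort: pd.DataFrame, scenario: Scenario) -> pd.DataFrame:
    """Patients whose chosen center closes under the scenario."""
    return cohort[cohort["chosen_center"].isin(list(scenario.closed))].reset_index(drop=True)


def stranded_patients(affected: pd.DataFrame, choice_sets: dict,
                      scenario: Scenario) -> pd.DataFrame:
    """Affected patients with no surviving center inside their choice set.

    These are reported separately (with unrestricted nearest-open travel
    times) and excluded from probability-weighted post-closure averages.
    """
    open_ids = np.array(sorted(scenario.open))
    mask = [not np.isin(choice_sets[pid].center_ids, open_ids).any()
            for pid in affected["id"]]
    return affected.loc[mask].reset_index(drop=True)
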