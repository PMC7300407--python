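"""Per-patient choice sets under the three-hour rule, and cohort exclusions.

A patient's choice set is every surgery center reachable within
``max_minutes`` by car (default 180 — "within 3 hours" read inclusively,
so exactly 180.0 minutes is inside).  Patients whose actually chosen
center lies beyond the threshold, and then patients left with a single
alternative, are excluded from the estimation cohort, in that order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_MAX_MINUTES",
    "ChoiceSet",
    "ExclusionReport",
    "build_choice_set",
    "build_all_choice_sets",
    "apply_exclusions",
]

DEFAULT_MAX_MINUTES = 180.0


@dataclass(frozen=True)
class ChoiceSet:
    """Alternatives within reach of one patient, sorted by minutes then id."""

    patient_id: object
    center_ids: np.ndarray
    minutes: np.ndarray

    @property
    def n_alternatives(self) -> int:
        return len(self.center_ids)

    @property
    def empty(self) -> bool:
        return self.n_alternatives == 0

    def contains(self, center_id) -> bool:
        return bool(np.isin(center_id, self.center_ids))

    def minutes_to(self, center_id) -> float:
        pos = np.flatnonzero(self.center_ids == center_id)
        if pos.size == 0:
            raise KeyError(f"center {center_id} not in choice set of {self.patient_id}")
        return float(self.minutes[pos[0]])


def _canonical(patient_id, center_ids, minutes) -> ChoiceSet:
    order = np.lexsort((center_ids, minutes))
    return ChoiceSet(
        patient_id=patient_id,
        center_ids=np.asarray(center_ids)[order],
        minutes=np.asarray(minutes, dtype=float)[order],
    )


def build_choice_set(patient_id, matrix: pd.DataFrame,
                     max_minutes: float = DEFAULT_MAX_MINUTES) -> ChoiceSet:
    """Centers within ``max_minutes`` of one patient, in canonical order.

    An empty result is a valid (flagged) outcome, not an error; an unknown
    patient id raises ``KeyError``.
    """
    if max_minutes <= 0:
        raise ValueError("max_minutes must be positive")
    row = matrix.loc[patient_id]
    keep = row.to_numpy() <= max_minutes
    return _canonical(patient_id, row.index.to_numpy()[keep], row.to_numpy()[keep])


def build_all_choice_sets(matrix: pd.DataFrame,
                          max_minutes: float = DEFAULT_MAX_MINUTES) -> dict:
    """Choice sets for every patient in the travel matrix, keyed by patient id."""
    if max_minutes <= 0:
        raise ValueError("max_minutes must be positive")
    vals = matrix.to_numpy()
    cols = matrix.columns.to_numpy()
    out = {}
    for pid, row in zip(matrix.index, vals):
        keep = row <= max_minutes
        out[pid] = _canonical(pid, cols[keep], row[keep])
    return out


@dataclass(frozen=True)
class ExclusionReport:
    """Bookkeeping of the two cohort exclusions; counts partition the input."""

    n_input: int
    n_excluded_far: int
    n_excluded_single: int

    @property
    def n_final(self) -> int:
        return self.n_input - self.n_excluded_far - self.n_excluded_single

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "quantity": ["input", "excluded_chosen_beyond_reach",
                             "excluded_single_option", "final"],
                "count": [self.n_input, self.n_excluded_far,
                          self.n_excluded_single, self.n_final],
            }
        )


def apply_exclusions(patients: pd.DataFrame, choice_sets: dict):
    """Drop far-travelling and single-option patients; return (cohort, report).

    First removes patients whose chosen center is not inside their own
    choice set (it was beyond the travel-time threshold), then patients
    with exactly one alternative.  Each patient is counted in exactly one
    bucket, in that order.
    """
    if patients["chosen_center"].isna().any():
        raise ValueError("every patient must have a chosen center before exclusions")
    cs = [choice_sets[pid] for pid in patients["id"]]
    chosen = patients["chosen_center"].to_numpy()
    far = np.array([not s.contains(c) for s, c in zip(cs, chosen)])
    single = np.array([s.n_alternatives == 1 for s in cs]) & ~far
    keep = ~far & ~single
    report = ExclusionReport(
        n_input=len(patients),
        n_excluded_far=int(far.sum()),
        n_excluded_single=int(single.sum()),
    )
    return patients.loc[keep].reset_index(drop=True), report
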