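"""Step 2: EBLUP projection of per-patient deviations from a reference course.

For a patient with in-window design matrix Z and SBP vector q, the deviation
(random-effects) vector is

    G Z' (Z G Z' + sigma2 I)^{-1} (q - Z alpha)

computed against a fitted :class:`~sbpcourse.course_model.ReferenceCourse`.
The course parameters never change across window scenarios; only the
patient's retained measurements do.  The same code path serves patients with
favourable and unfavourable outcomes.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve

from .course_model import ReferenceCourse, polynomial_design
from .synthetic_cohort import PatientRecord

__all__ = [
    "WINDOW_MIN_MEASUREMENTS",
    "WindowFilter",
    "RandomEffects",
    "SingularSystemError",
    "truncate_window",
    "apply_inclusion_filter",
    "compute_eblup",
    "compute_effects_table",
]

#: Minimum number of in-window measurements required per analysis window.
WINDOW_MIN_MEASUREMENTS = {24: 10, 18: 8, 12: 6, 6: 3}

# Above this condition number the shrinkage system is solved by least squares.
_COND_LIMIT = 1e12


class SingularSystemError(np.linalg.LinAlgError):
    """The shrinkage system Z G Z' + sigma2 I is singular (sigma2 = 0 case)."""


@dataclass(frozen=True)
class WindowFilter:
    """A measurement window (hours) and its minimum-measurement requirement."""

    window_hours: int
    min_measurements: int

    def __post_init__(self) -> None:
        if self.window_hours not in WINDOW_MIN_MEASUREMENTS:
            raise ValueError("window_hours must be one of 24, 18, 12, 6")
        expected = WINDOW_MIN_MEASUREMENTS[self.window_hours]
        if self.min_measurements != expected:
            raise ValueError(
                f"window of {self.window_hours} h requires min_measurements={expected}"
            )

    @classmethod
    def for_window(cls, window_hours: int) -> "WindowFilter":
        if window_hours not in WINDOW_MIN_MEASUREMENTS:
            raise ValueError("window_hours must be one of 24, 18, 12, 6")
        return cls(window_hours, WINDOW_MIN_MEASUREMENTS[window_hours])


@dataclass
class RandomEffects:
    """A patient's EBLUP deviation vector from one reference course."""

    patient_id: str
    spec: object  # CourseSpec
    effects: np.ndarray
    window_hours: int
    n_measurements_used: int

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (self.spec.degree + 1,):
            raise ValueError("effects length must equal degree + 1")
        if not np.all(np.isfinite(self.effects)):
            raise ValueError("effects must be finite")
        if self.window_hours not in WINDOW_MIN_MEASUREMENTS:
            raise ValueError("window_hours must be one of 24, 18, 12, 6")


def truncate_window(patient: PatientRecord, window_hours: int) -> PatientRecord:
    """Retain exactly the measurements with time <= window_hours (closed bound)."""
    if window_hours not in WINDOW_MIN_MEASUREMENTS:
        raise ValueError("window_hours must be one of 24, 18, 12, 6")
    keep = patient.times <= window_hours
    if keep.all():
        return patient
    return dataclasses.replace(
        patient, times=patient.times[keep], sbp=patient.sbp[keep]
    )


def apply_inclusion_filter(
    cohort: Sequence[PatientRecord], filter: WindowFilter
) -> tuple[list[PatientRecord], int]:
    """Keep patients with enough in-window measurements; return exclusion count."""
    included = [
        p
        for p in cohort
        if int((p.times <= filter.window_hours).sum()) >= filter.min_measurements
    ]
    return included, len(cohort) - len(included)


def compute_eblup(
    patient: PatientRecord, course: ReferenceCourse, window_hours: int = 24
) -> RandomEffects:
    """EBLUP deviation vector for one patient against a fitted course.

    The symmetric positive-definite system is solved via a Cholesky
    factorization; if it is singular (possible only with sigma2 = 0) an
    explicit :class:`SingularSystemError` is raised, and an ill-conditioned
    system (condition number above 1e12) falls back to a least-squares solve
    with a warning.
    """
    rec = truncate_window(patient, window_hours)
    if rec.n_measurements < 1:
        raise ValueError(
            f"patient {patient.patient_id} has no measurements within "
            f"{window_hours} hours"
        )
    Z = polynomial_design(rec.times, course.spec.degree)
    resid = rec.sbp - Z @ course.alpha
    ZG = Z @ course.G
    M = ZG @ Z.T + course.sigma2 * np.eye(len(Z))
    # eigenvalues of M lie in [sigma2, tr(Z G Z') + sigma2]; only compute the
    # exact condition number when this cheap upper bound is alarming
    cond_bound = (np.trace(M) - (len(Z) - 1) * course.sigma2) / course.sigma2
    try:
        if cond_bound > _COND_LIMIT and np.linalg.cond(M) > _COND_LIMIT:
            raise np.linalg.LinAlgError("condition number exceeds 1e12")
        solved = cho_solve(cho_factor(M, lower=True), resid)
    except np.linalg.LinAlgError as err:
        if course.sigma2 == 0:
            raise SingularSystemError(
                f"shrinkage system singular for patient {patient.patient_id}"
            ) from err
        warnings.warn(
            f"ill-conditioned shrinkage system for patient {patient.patient_id}; "
            "using least-squares fallback",
            RuntimeWarning,
            stacklevel=2,
        )
        solved = np.linalg.lstsq(M, resid, rcond=None)[0]
    effects = ZG.T @ solved
    return RandomEffects(
        patient_id=patient.patient_id,
        spec=course.spec,
        effects=effects,
        window_hours=window_hours,
        n_measurements_used=rec.n_measurements,
    )


def compute_effects_table(
    cohort: Sequence[PatientRecord], course: ReferenceCourse, window_hours: int = 24
) -> pd.DataFrame:
    """EBLUPs for a whole cohort as a table indexed by patient id.

    Columns: ``effect_0`` ... ``effect_degree``, ``window_hours``,
    ``n_measurements_used``.  Serializes naturally to CSV.
    """
    p = course.spec.degree + 1
    rows = np.empty((len(cohort), p))
    n_used = np.empty(len(cohort), dtype=int)
    ids = []
    for i, patient in enumerate(cohort):
        re = compute_eblup(patient, course, window_hours)
        rows[i] = re.effects
        n_used[i] = re.n_measurements_used
        ids.append(patient.patient_id)
    table = pd.DataFrame(
        rows, index=pd.Index(ids, name="patient_id"), columns=[f"effect_{k}" for k in range(p)]
    )
    table["window_hours"] = window_hours
    table["n_measurements_used"] = n_used
    return table
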