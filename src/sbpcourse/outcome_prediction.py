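"""Step 3 and evaluation: logistic outcome models on EBLUP deviations,
full-pipeline bootstrap confidence intervals, and the AUC stability grid.

All random-effect components enter one logistic model simultaneously,
alongside age, sex, baseline NIHSS, hypertension history and recanalisation
success.  Bootstrap resamples patients with replacement and reruns all three
pipeline steps per iteration; CIs are percentile 2.5/97.5.  The stability
grid recomputes EBLUPs under shortened measurement windows against the
*unchanged* course parameters and reports apparent AUCs.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .course_model import (
    ConvergenceError,
    CourseSpec,
    FitConfig,
    ReferenceCourse,
    fit_reference_course,
    select_favourable,
)
from .eblup_projection import WindowFilter, apply_inclusion_filter, compute_effects_table
from .synthetic_cohort import COVARIATE_NAMES, PatientRecord

__all__ = [
    "COVARIATE_NAMES",
    "SeparationError",
    "OutcomeModelFit",
    "BootstrapResult",
    "ScenarioResult",
    "covariates_frame",
    "labels_series",
    "fit_outcome_model",
    "compute_auc",
    "bootstrap_pipeline",
    "run_scenarios",
    "scenario_frame",
    "cohort_proportions",
]


class SeparationError(RuntimeError):
    """Perfect separation in a logistic fit; ``column`` names the separator when known."""

    def __init__(self, message: str, column: str | None = None):
        super().__init__(message)
        self.column = column


@dataclass
class OutcomeModelFit:
    """A fitted Step-3 logistic model (log-odds scale, with odds ratios)."""

    spec: CourseSpec | None
    coefficient_names: tuple[str, ...]
    coefficients: np.ndarray
    odds_ratios: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_used: int

    def __post_init__(self) -> None:
        self.coefficients = np.asarray(self.coefficients, dtype=float)
        self.odds_ratios = np.asarray(self.odds_ratios, dtype=float)
        if not np.allclose(
            self.odds_ratios, np.exp(self.coefficients), rtol=1e-12, atol=0
        ):
            raise ValueError("odds ratios must equal exp(coefficients)")
        finite = np.isfinite(self.ci_lower) & np.isfinite(self.ci_upper)
        if np.any(np.asarray(self.ci_lower)[finite] > np.asarray(self.ci_upper)[finite]):
            raise ValueError("CI lower bounds must not exceed upper bounds")

    def linear_predictor(self, X: pd.DataFrame) -> np.ndarray:
        """Score rows of ``X`` (columns matching the non-intercept coefficients)."""
        names = [n for n in self.coefficient_names if n != "intercept"]
        beta = dict(zip(self.coefficient_names, self.coefficients))
        lp = np.full(len(X), beta.get("intercept", 0.0))
        for name in names:
            lp = lp + beta[name] * X[name].to_numpy(dtype=float)
        return lp

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.coefficients,
                "odds_ratio": self.odds_ratios,
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
            },
            index=pd.Index(self.coefficient_names, name="term"),
        )


@dataclass
class BootstrapResult:
    """Percentile CIs from the full-pipeline bootstrap."""

    coefficient_names: tuple[str, ...]
    point_estimates: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    n_iterations: int
    seed: int
    n_failed_iterations: int
    samples: np.ndarray = field(repr=False, default=None)

    @property
    def flagged(self) -> bool:
        """True when at least 10% of iterations failed to fit."""
        return self.n_failed_iterations >= 0.1 * self.n_iterations

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "coefficient": self.point_estimates,
                "odds_ratio": np.exp(self.point_estimates),
                "ci_lower": self.ci_lower,
                "ci_upper": self.ci_upper,
                "or_ci_lower": np.exp(self.ci_lower),
                "or_ci_upper": np.exp(self.ci_upper),
            },
            index=pd.Index(self.coefficient_names, name="term"),
        )


@dataclass
class ScenarioResult:
    """Apparent AUC for one (outcome, degree, window) cell of the stability grid."""

    outcome_name: str
    degree: int
    window_hours: int
    auc: float
    n_included: int
    missing: bool = False

    def __post_init__(self) -> None:
        if not self.missing and not 0.0 <= self.auc <= 1.0:
            raise ValueError("auc must lie in [0, 1]")


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def covariates_frame(
    cohort: Sequence[PatientRecord], names: Sequence[str] = COVARIATE_NAMES
) -> pd.DataFrame:
    """Covariate table indexed by patient id."""
    return pd.DataFrame(
        {name: [p.covariate(name) for p in cohort] for name in names},
        index=pd.Index([p.patient_id for p in cohort], name="patient_id"),
    )


def labels_series(cohort: Sequence[PatientRecord], outcome_name: str) -> pd.Series:
    """Outcome labels indexed by patient id; missing labels become NaN."""
    values = [
        np.nan if p.outcomes.get(outcome_name) is None else float(p.outcomes[outcome_name])
        for p in cohort
    ]
    return pd.Series(
        values, index=pd.Index([p.patient_id for p in cohort], name="patient_id"),
        name=outcome_name,
    )


def _check_separation(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> None:
    for j, name in enumerate(names):
        x1, x0 = X[y == 1, j], X[y == 0, j]
        if x1.max() < x0.min() or x0.max() < x1.min():
            raise SeparationError(
                f"column {name!r} perfectly separates the outcome", column=name
            )


def _logit_ml(X: np.ndarray, y: np.ndarray, names: Sequence[str]) -> np.ndarray:
    """Maximum-likelihood logistic coefficients (design already has intercept)."""
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except (PerfectSeparationError, PerfectSeparationWarning) as err:
            _check_separation(X[:, 1:], y, names[1:])
            raise SeparationError(str(err)) from err
    if not res.mle_retvals.get("converged", False):
        raise ConvergenceError("logistic fit did not converge")
    return np.asarray(res.params, dtype=float)


def fit_outcome_model(
    effects: pd.DataFrame | None,
    covariates: pd.DataFrame | None,
    labels: pd.Series,
    spec: CourseSpec | None = None,
) -> OutcomeModelFit:
    """Fit the Step-3 logistic model on complete cases.

    ``effects`` columns (all random-effect components, entered simultaneously)
    and ``covariates`` columns are aligned to ``labels`` by patient id; rows
    with any missing value are dropped (listwise deletion).  Requires at
    least 10 events and 10 non-events.  Perfect separation raises
    :class:`SeparationError`, naming the separating column when a single
    column is responsible.  CIs are left NaN (use :func:`bootstrap_pipeline`).
    """
    parts = [df for df in (effects, covariates) if df is not None and df.shape[1]]
    if not parts:
        raise ValueError("at least one of effects/covariates must be provided")
    X_df = pd.concat(parts, axis=1, join="inner")
    data = X_df.join(labels.rename("_y"), how="inner").dropna()
    y = data.pop("_y").to_numpy(dtype=float)
    if y.size and not np.isin(y, (0.0, 1.0)).all():
        raise ValueError("labels must be binary")
    n_events = int(y.sum())
    if n_events < 10 or y.size - n_events < 10:
        raise ValueError(
            f"need >= 10 events and >= 10 non-events, got {n_events} and "
            f"{y.size - n_events}"
        )
    names = ("intercept", *data.columns)
    X = np.column_stack([np.ones(len(data)), data.to_numpy(dtype=float)])
    _check_separation(X[:, 1:], y, names[1:])
    beta = _logit_ml(X, y, names)
    nan = np.full(beta.size, np.nan)
    return OutcomeModelFit(
        spec=spec,
        coefficient_names=names,
        coefficients=beta,
        odds_ratios=np.exp(beta),
        ci_lower=nan.copy(),
        ci_upper=nan.copy(),
        n_used=int(y.size),
    )


def compute_auc(scores, labels) -> float:
    """Area under the ROC curve as the Mann-Whitney probability (ties count 1/2)."""
    from scipy.stats import rankdata

    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be 1-d and of equal length")
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 + n0 != y.size:
        raise ValueError("labels must be binary")
    if n1 == 0 or n0 == 0:
        raise ValueError("labels must contain both classes")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


# ---------------------------------------------------------------------------
# pipeline drivers
# ---------------------------------------------------------------------------


def _single_pass(
    cohort: Sequence[PatientRecord],
    spec: CourseSpec,
    covariate_names: Sequence[str],
    fit_config: FitConfig | None,
    window_hours: int = 24,
):
    """Steps 1-3 on one (already filtered) cohort; returns (model fit, course)."""
    favourable = select_favourable(cohort, spec.outcome_name)
    course = fit_reference_course(favourable, spec, fit_config)
    labelled = [p for p in cohort if p.outcomes.get(spec.outcome_name) is not None]
    effects = compute_effects_table(labelled, course, window_hours)
    eff_cols = effects[[c for c in effects.columns if c.startswith("effect_")]]
    covs = covariates_frame(labelled, covariate_names) if covariate_names else None
    labels = labels_series(labelled, spec.outcome_name)
    fit = fit_outcome_model(eff_cols, covs, labels, spec=spec)
    return fit, course


def bootstrap_pipeline(
    cohort: Sequence[PatientRecord],
    spec: CourseSpec,
    n_iterations: int = 1000,
    seed: int = 0,
    covariate_names: Sequence[str] = COVARIATE_NAMES,
    fit_config: FitConfig | None = None,
    _identity_resample: bool = False,
) -> BootstrapResult:
    """Bootstrap all three pipeline steps, resampling patients with replacement.

    The cohort must already pass the 24-hour inclusion filter.  Each
    iteration re-identifies the favourable subgroup in the resample, refits
    the reference course (warm-started at the point estimate), recomputes
    EBLUPs and refits the logistic model.  Iteration-level failures are
    recorded, not fatal, unless they exceed 10% (then ``flagged``).
    Identical seed implies identical result.
    """
    patients = list(cohort)
    base_config = fit_config or FitConfig()
    point_fit, point_course = _single_pass(patients, spec, covariate_names, base_config)
    # warm-start bootstrap refits at the point estimate; the identity resample
    # keeps the point-fit configuration so it reproduces the estimates exactly
    boot_config = (
        base_config
        if _identity_resample
        else dataclasses.replace(base_config, start=point_course.theta, n_restarts=0, tol=1e-6)
    )
    rng = np.random.default_rng(seed)
    n = len(patients)
    samples = np.full((n_iterations, len(point_fit.coefficients)), np.nan)
    n_failed = 0
    for it in range(n_iterations):
        idx = np.arange(n) if _identity_resample else rng.integers(0, n, n)
        resample = [
            dataclasses.replace(patients[i], patient_id=f"b{j:05d}")
            for j, i in enumerate(idx)
        ]
        try:
            fit, _ = _single_pass(resample, spec, covariate_names, boot_config)
            if fit.coefficient_names != point_fit.coefficient_names:
                raise RuntimeError("coefficient set changed in resample")
            samples[it] = fit.coefficients
        except Exception:
            n_failed += 1
    ok = samples[~np.isnan(samples).any(axis=1)]
    if len(ok):
        ci_lower, ci_upper = np.percentile(ok, [2.5, 97.5], axis=0)
    else:
        ci_lower = ci_upper = np.full(len(point_fit.coefficients), np.nan)
    if n_failed >= 0.1 * n_iterations:
        warnings.warn(
            f"{n_failed}/{n_iterations} bootstrap iterations failed",
            RuntimeWarning,
            stacklevel=2,
        )
    return BootstrapResult(
        coefficient_names=point_fit.coefficient_names,
        point_estimates=point_fit.coefficients,
        ci_lower=ci_lower,
        ci_upper=ci_upper,
        n_iterations=n_iterations,
        seed=seed,
        n_failed_iterations=n_failed,
        samples=samples,
    )


def run_scenarios(
    cohort: Sequence[PatientRecord],
    degrees: Sequence[int] = (1, 2, 3),
    windows: Sequence[int] = (24, 18, 12, 6),
    outcome_names: Sequence[str] = ("functional_independence",),
    covariate_names: Sequence[str] = COVARIATE_NAMES,
    fit_config: FitConfig | None = None,
    courses: dict | None = None,
) -> list[ScenarioResult]:
    """The AUC stability grid: degrees x windows x outcomes.

    Reference courses are fitted once per (outcome, degree) on the full
    24-hour data of the 24-hour-included cohort; each window cell then
    recomputes EBLUPs on truncated data against the *identical* course
    (asserted by parameter fingerprint), refits the Step-3 logistic model
    and reports the apparent AUC with the cell's included count.  Cells
    whose outcome becomes single-class (or otherwise unfittable) after
    filtering are flagged as missing, not fatal.

    Pre-fitted courses may be supplied as ``courses[(outcome, degree)]``.
    """
    results: list[ScenarioResult] = []
    base24, _ = apply_inclusion_filter(cohort, WindowFilter.for_window(24))
    for outcome in outcome_names:
        labelled = [p for p in base24 if p.outcomes.get(outcome) is not None]
        for degree in degrees:
            spec = CourseSpec(degree=degree, outcome_name=outcome)
            if courses and (outcome, degree) in courses:
                course = courses[(outcome, degree)]
            else:
                course = fit_reference_course(
                    select_favourable(labelled, outcome), spec, fit_config
                )
            fingerprint = (course.alpha.tobytes(), course.G.tobytes(), course.sigma2)
            for window in windows:
                assert (
                    course.alpha.tobytes(),
                    course.G.tobytes(),
                    course.sigma2,
                ) == fingerprint, "course parameters must not change across windows"
                included, _ = apply_inclusion_filter(
                    labelled, WindowFilter.for_window(window)
                )
                try:
                    effects = compute_effects_table(included, course, window)
                    eff_cols = effects[
                        [c for c in effects.columns if c.startswith("effect_")]
                    ]
                    covs = (
                        covariates_frame(included, covariate_names)
                        if covariate_names
                        else None
                    )
                    labels = labels_series(included, outcome)
                    fit = fit_outcome_model(eff_cols, covs, labels, spec=spec)
                    X = pd.concat(
                        [df for df in (eff_cols, covs) if df is not None], axis=1
                    ).loc[labels.dropna().index]
                    auc = compute_auc(
                        fit.linear_predictor(X), labels.dropna().to_numpy()
                    )
                    results.append(
                        ScenarioResult(outcome, degree, window, auc, len(included))
                    )
                except (ValueError, SeparationError, ConvergenceError):
                    results.append(
                        ScenarioResult(
                            outcome, degree, window, np.nan, len(included), missing=True
                        )
                    )
    return results


def scenario_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Pivot the grid into outcome x degree rows and window columns."""
    df = pd.DataFrame(
        {
            "outcome": [r.outcome_name for r in results],
            "degree": [r.degree for r in results],
            "window_hours": [r.window_hours for r in results],
            "auc": [r.auc for r in results],
            "n_included": [r.n_included for r in results],
        }
    )
    return df.pivot_table(
        index=["outcome", "degree"], columns="window_hours", values="auc", sort=False
    )


def cohort_proportions(cohort: Sequence[PatientRecord], outcome_name: str) -> float:
    """Percentage of the registered cohort with the favourable outcome value.

    Uses the full registered denominator (missing labels count as
    non-favourable), rounded to one decimal for reporting.
    """
    if not len(cohort):
        raise ValueError("cohort is empty")
    favourable = sum(1 for p in cohort if p.outcomes.get(outcome_name) == 1)
    return round(100.0 * favourable / len(cohort), 1)
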