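"""Synthetic cohort generator.

Emulates the structure of a 24-hour post-procedure blood-pressure monitoring
dataset: a fixed measurement protocol (21 scheduled readings plus 8 optional
odd-hour readings), polynomial population SBP courses with patient-level
random effects and residual noise, per-measurement dropout, and binary
outcome labels drawn from a logistic model on the random effects and
clinical covariates.

Covariate coefficients of :class:`OutcomeCoefficients` apply to *centred*
covariates (age minus 71, NIHSS minus 15, binary indicators minus 0.5) so
that the intercept is approximately the logit of the outcome prevalence.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit
from scipy.stats import truncnorm

__all__ = [
    "OUTCOME_NAMES",
    "COVARIATE_NAMES",
    "MeasurementSchedule",
    "OutcomeCoefficients",
    "SyntheticConfig",
    "PatientRecord",
    "default_schedule",
    "default_outcome_coefficients",
    "default_config",
    "generate_cohort",
]

#: Binary outcome labels carried by every patient record.
OUTCOME_NAMES = ("functional_independence", "alive", "no_sich", "no_ich")

#: Clinical covariates entering the outcome models.
COVARIATE_NAMES = ("age", "sex", "nihss_baseline", "hypertension", "mtici_success")

# Centring constants for the generative logistic model (see module docstring).
_COVARIATE_CENTERS = {
    "age": 71.0,
    "sex": 0.5,
    "nihss_baseline": 15.0,
    "hypertension": 0.5,
    "mtici_success": 0.5,
}

# Marginal covariate distributions for the default generator: a typical
# large-artery-occlusion thrombectomy cohort (mean age 71, median NIHSS 15,
# 53% male, ~44% hypertension history, ~74% successful recanalisation).
_AGE_MEAN, _AGE_SD, _AGE_LO, _AGE_HI = 71.0, 13.0, 18.0, 100.0
_NIHSS_SHAPE, _NIHSS_SCALE = 5.0, 3.3
_P_MALE, _P_HYPERTENSION, _P_MTICI = 0.532, 0.436, 0.736


@dataclass(frozen=True)
class MeasurementSchedule:
    """The monitoring protocol: scheduled and optional measurement times (hours)."""

    scheduled_times: tuple[float, ...]
    optional_times: tuple[float, ...]

    def __post_init__(self) -> None:
        for name, times in (
            ("scheduled_times", self.scheduled_times),
            ("optional_times", self.optional_times),
        ):
            arr = np.asarray(times, dtype=float)
            if arr.size and (arr.min() < 0.0 or arr.max() > 24.0):
                raise ValueError(f"{name} must lie within [0, 24]")
            if np.any(np.diff(arr) <= 0):
                raise ValueError(f"{name} must be strictly increasing")
        union = set(self.scheduled_times) | set(self.optional_times)
        if len(union) != len(self.scheduled_times) + len(self.optional_times):
            raise ValueError("scheduled and optional times must not overlap")

    @property
    def all_times(self) -> tuple[float, ...]:
        return tuple(sorted(set(self.scheduled_times) | set(self.optional_times)))


def default_schedule() -> MeasurementSchedule:
    """The 24-hour protocol: every 30 min for 0-4 h, hourly 4-8 h, every
    2 h 8-24 h (21 scheduled readings), plus optional readings at the odd
    hours 9-23 (8 readings)."""
    scheduled = (
        [i * 0.5 for i in range(9)]  # 0, 0.5, ..., 4.0
        + [5.0, 6.0, 7.0, 8.0]
        + [float(t) for t in range(10, 25, 2)]  # 10, 12, ..., 24
    )
    optional = [float(t) for t in range(9, 24, 2)]  # 9, 11, ..., 23
    return MeasurementSchedule(tuple(scheduled), tuple(optional))


@dataclass(frozen=True)
class OutcomeCoefficients:
    """Generative logistic coefficients for one binary outcome.

    ``effects`` has one entry per random-effect component (length degree+1);
    ``covariates`` maps covariate names to coefficients on centred values.
    """

    intercept: float
    effects: tuple[float, ...]
    covariates: Mapping[str, float] = field(default_factory=dict)

    def linear_predictor(self, effects: np.ndarray, covariates: Mapping[str, float]) -> float:
        lp = self.intercept + float(np.dot(self.effects, effects))
        for name, beta in self.covariates.items():
            lp += beta * (covariates[name] - _COVARIATE_CENTERS[name])
        return lp


@dataclass
class SyntheticConfig:
    """Full description of one synthetic cohort draw."""

    n_patients: int
    true_alpha: np.ndarray
    true_G: np.ndarray
    true_sigma2: float
    outcome_coefficients: Mapping[str, OutcomeCoefficients]
    optional_measurement_prob: float = 0.0
    dropout_prob: float = 0.0
    low_count_fraction: float = 0.0
    time_jitter_minutes: float = 0.0
    missing_outcome_prob: float = 0.0
    seed: int = 0
    schedule: MeasurementSchedule = field(default_factory=default_schedule)

    def __post_init__(self) -> None:
        self.true_alpha = np.asarray(self.true_alpha, dtype=float)
        self.true_G = np.asarray(self.true_G, dtype=float)

    @property
    def degree(self) -> int:
        return len(self.true_alpha) - 1

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be at least 2")
        p = len(self.true_alpha)
        if self.true_G.shape != (p, p):
            raise ValueError(
                f"true_G shape {self.true_G.shape} incompatible with "
                f"true_alpha length {p}"
            )
        if not np.allclose(self.true_G, self.true_G.T, atol=1e-10):
            raise ValueError("true_G must be symmetric")
        eigvals = np.linalg.eigvalsh(self.true_G)
        if eigvals.min() < -1e-8 * max(1.0, eigvals.max()):
            raise ValueError("true_G must be positive semidefinite")
        if np.any(np.diag(self.true_G) < 0):
            raise ValueError("true_G diagonal must be non-negative")
        if not self.true_sigma2 > 0:
            raise ValueError("true_sigma2 must be positive")
        for prob_name in (
            "optional_measurement_prob",
            "dropout_prob",
            "low_count_fraction",
            "missing_outcome_prob",
        ):
            prob = getattr(self, prob_name)
            if not 0.0 <= prob <= 1.0:
                raise ValueError(f"{prob_name} must lie in [0, 1]")
        for name, oc in self.outcome_coefficients.items():
            if len(oc.effects) != p:
                raise ValueError(
                    f"outcome_coefficients[{name!r}].effects must have length {p}"
                )
            unknown = set(oc.covariates) - set(COVARIATE_NAMES)
            if unknown:
                raise ValueError(f"unknown covariates {sorted(unknown)} for {name!r}")


@dataclass
class PatientRecord:
    """One patient's irregular SBP series plus covariates and outcome labels."""

    patient_id: str
    times: np.ndarray
    sbp: np.ndarray
    age: float
    sex: int
    nihss_baseline: float
    hypertension: int
    mtici_success: int
    outcomes: dict

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.sbp = np.asarray(self.sbp, dtype=float)
        if self.times.shape != self.sbp.shape or self.times.ndim != 1:
            raise ValueError("times and sbp must be 1-d arrays of equal length")
        if self.times.size:
            if self.times.min() < 0.0 or self.times.max() > 24.0:
                raise ValueError("measurement times must lie within [0, 24] hours")
            if np.any(np.diff(self.times) <= 0):
                raise ValueError("measurement times must be strictly increasing")
            if np.any(self.sbp <= 0):
                raise ValueError("SBP values must be positive")
        for name, value in self.outcomes.items():
            if value is not None and value not in (0, 1):
                raise ValueError(f"outcome {name!r} must be 0, 1 or missing")

    @property
    def n_measurements(self) -> int:
        return int(self.times.size)

    def covariate(self, name: str) -> float:
        return float(getattr(self, name))


def default_outcome_coefficients(degree: int) -> dict[str, OutcomeCoefficients]:
    """Default generative outcome models, one per outcome label.

    Intercepts target prevalences of roughly 45 / 78 / 95 / 86 per cent;
    the primary outcome loads on the trend random effect, the others more
    weakly.  Effect coefficients beyond the trend component are zero.
    """
    p = degree + 1

    def eff(trend_beta: float) -> tuple[float, ...]:
        v = [0.0] * p
        if p > 1:
            v[1] = trend_beta
        return tuple(v)

    return {
        "functional_independence": OutcomeCoefficients(
            intercept=-0.2,
            effects=eff(-2.0),
            covariates={"age": -0.05, "nihss_baseline": -0.1, "mtici_success": 1.0},
        ),
        "alive": OutcomeCoefficients(
            intercept=1.4,
            effects=eff(-1.0),
            covariates={"age": -0.04, "nihss_baseline": -0.08},
        ),
        "no_sich": OutcomeCoefficients(intercept=3.0, effects=eff(-0.5)),
        "no_ich": OutcomeCoefficients(intercept=1.9, effects=eff(-0.5)),
    }


def default_config(n_patients: int, degree: int = 1, seed: int = 0) -> SyntheticConfig:
    """A ready-to-run configuration with a plausible linear (or higher) course."""
    alpha = {
        1: [130.0, -0.28],
        2: [132.5, -1.24, 0.044],
        3: [133.5, -1.94, 0.126, -0.0024],
    }[degree]
    g_diag = {1: [100.0, 0.25], 2: [100.0, 1.0, 0.002], 3: [100.0, 2.0, 0.01, 1e-5]}[degree]
    return SyntheticConfig(
        n_patients=n_patients,
        true_alpha=np.asarray(alpha),
        true_G=np.diag(g_diag),
        true_sigma2=64.0,
        outcome_coefficients=default_outcome_coefficients(degree),
        optional_measurement_prob=0.3,
        dropout_prob=0.05,
        low_count_fraction=0.1,
        seed=seed,
    )


def _psd_factor(G: np.ndarray) -> np.ndarray:
    """Square-root factor of a PSD matrix, tolerant of zero eigenvalues."""
    vals, vecs = np.linalg.eigh(G)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def _draw_covariates(rng: np.random.Generator) -> dict[str, float]:
    a = (_AGE_LO - _AGE_MEAN) / _AGE_SD
    b = (_AGE_HI - _AGE_MEAN) / _AGE_SD
    age = float(truncnorm.rvs(a, b, loc=_AGE_MEAN, scale=_AGE_SD, random_state=rng))
    nihss = float(np.clip(np.round(rng.gamma(_NIHSS_SHAPE, _NIHSS_SCALE)), 0, 42))
    return {
        "age": age,
        "sex": int(rng.random() < _P_MALE),
        "nihss_baseline": nihss,
        "hypertension": int(rng.random() < _P_HYPERTENSION),
        "mtici_success": int(rng.random() < _P_MTICI),
    }


def _draw_times(config: SyntheticConfig, rng: np.random.Generator, force_low: bool) -> np.ndarray:
    sched = np.asarray(config.schedule.scheduled_times)
    opt = np.asarray(config.schedule.optional_times)
    keep = sched[rng.random(sched.size) >= config.dropout_prob]
    keep_opt = opt[rng.random(opt.size) < config.optional_measurement_prob]
    times = np.sort(np.concatenate([keep, keep_opt]))
    if force_low and times.size >= 10:
        k = int(rng.integers(3, 10))
        times = np.sort(rng.choice(times, size=k, replace=False))
    if config.time_jitter_minutes > 0 and times.size:
        jitter = rng.uniform(-config.time_jitter_minutes, config.time_jitter_minutes, times.size)
        times = np.clip(times + jitter / 60.0, 0.0, 24.0)
        times = np.unique(times)
    return times


def generate_cohort(
    config: SyntheticConfig, return_effects: bool = False
) -> list[PatientRecord] | tuple[list[PatientRecord], np.ndarray]:
    """Draw a cohort of :class:`PatientRecord` from the generative model.

    Per patient: random-effect vector ~ MVN(0, ``true_G``); SBP at retained
    protocol times = polynomial(``true_alpha`` + effects) + N(0, ``true_sigma2``)
    noise (clipped to the physiological range 30-300 mm Hg); covariates from
    the documented marginal distributions; outcomes ~ Bernoulli(logistic(...)).

    Reproducible: the same config (including seed) yields an identical cohort.
    Per-patient substreams are spawned from the master seed, so cohorts of
    different sizes share their common prefix of patients.

    When ``return_effects`` is true, also return the (n_patients, degree+1)
    matrix of latent random-effect draws (useful for validation; the latent
    effects are deliberately not stored on the records).
    """
    config.validate()
    p = config.degree + 1
    factor = _psd_factor(config.true_G)
    sd_e = float(np.sqrt(config.true_sigma2))
    n_low = int(round(config.low_count_fraction * config.n_patients))
    children = np.random.SeedSequence(config.seed).spawn(config.n_patients)

    cohort: list[PatientRecord] = []
    latent = np.empty((config.n_patients, p))
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        effects = factor @ rng.standard_normal(p)
        latent[i] = effects
        times = _draw_times(config, rng, force_low=i < n_low)
        design = times[:, None] ** np.arange(p)
        sbp = design @ (config.true_alpha + effects) + rng.normal(0.0, sd_e, times.size)
        sbp = np.clip(sbp, 30.0, 300.0)
        covs = _draw_covariates(rng)
        outcomes: dict[str, int | None] = {}
        for name, oc in config.outcome_coefficients.items():
            label: int | None = int(rng.random() < expit(oc.linear_predictor(effects, covs)))
            if config.missing_outcome_prob and rng.random() < config.missing_outcome_prob:
                label = None
            outcomes[name] = label
        cohort.append(
            PatientRecord(
                patient_id=f"P{i:04d}",
                times=times,
                sbp=sbp,
                outcomes=outcomes,
                **covs,
            )
        )
    if return_effects:
        return cohort, latent
    return cohort
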