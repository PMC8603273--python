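"""Step 1: polynomial mixed-effects reference SBP courses.

The reference course for an outcome is a degree-1/2/3 polynomial in hours
since end of procedure, fitted by maximum (or restricted maximum) likelihood
on the favourable-outcome subcohort, with a random effect on every
coefficient including the intercept.  The random-effect covariance G is
parameterized through its Cholesky factor with log-transformed diagonal,
which enforces positive semidefiniteness and a strictly positive diagonal.

The marginal likelihood is evaluated from per-patient sufficient statistics
(Z'Z, Z'q, q'q) via the Woodbury identity, so one evaluation costs a few
batched (degree+1)-dimensional linear-algebra calls regardless of the number
of measurements — fast enough to refit thousands of bootstrap resamples.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from .synthetic_cohort import PatientRecord

__all__ = [
    "CourseSpec",
    "FitConfig",
    "ReferenceCourse",
    "ConvergenceError",
    "polynomial_design",
    "evaluate_course",
    "fit_reference_course",
    "select_favourable",
    "marginal_covariance",
]

_LOG_2PI = float(np.log(2.0 * np.pi))
_LOG_BOUND = 16.0  # bounds on log-scale parameters during optimisation


class ConvergenceError(RuntimeError):
    """Raised when the likelihood optimiser fails after all restarts."""


@dataclass(frozen=True)
class CourseSpec:
    """Which polynomial degree and which outcome define a reference course."""

    degree: int
    outcome_name: str

    def __post_init__(self) -> None:
        if self.degree not in (1, 2, 3):
            raise ValueError("degree must be 1, 2 or 3")


@dataclass
class FitConfig:
    """Controls for the marginal-likelihood optimisation."""

    method: str = "ml"  # "ml" or "reml"
    n_restarts: int = 3
    tol: float = 1e-8
    max_iter: int = 500
    start: np.ndarray | None = None  # warm-start parameter vector
    seed: int = 0
    check_outcome: bool = True

    def __post_init__(self) -> None:
        if self.method not in ("ml", "reml"):
            raise ValueError("method must be 'ml' or 'reml'")


@dataclass
class ReferenceCourse:
    """A fitted reference course: fixed effects, G matrix and residual variance."""

    spec: CourseSpec
    alpha: np.ndarray
    G: np.ndarray
    sigma2: float
    log_likelihood: float = np.nan
    n_patients_fit: int = 0
    method: str = "ml"
    converged: bool = True
    boundary_warning: bool = False
    theta: np.ndarray | None = None  # internal optimiser state, for warm starts

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        p = self.spec.degree + 1
        if self.alpha.shape != (p,):
            raise ValueError(f"alpha must have length {p}")
        if self.G.shape != (p, p):
            raise ValueError(f"G must be {p}x{p}")
        if not np.allclose(self.G, self.G.T, atol=1e-8):
            raise ValueError("G must be symmetric")
        if np.any(np.diag(self.G) <= 0):
            raise ValueError("G diagonal must be strictly positive")
        if np.linalg.eigvalsh(self.G).min() < -1e-8 * max(1.0, np.abs(self.G).max()):
            raise ValueError("G must be positive semidefinite")
        if not self.sigma2 > 0:
            raise ValueError("sigma2 must be positive")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "spec": {"degree": self.spec.degree, "outcome_name": self.spec.outcome_name},
            "alpha": self.alpha.tolist(),
            "G": self.G.tolist(),
            "sigma2": self.sigma2,
            "log_likelihood": self.log_likelihood,
            "n_patients_fit": self.n_patients_fit,
            "method": self.method,
            "converged": self.converged,
            "boundary_warning": self.boundary_warning,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceCourse":
        return cls(
            spec=CourseSpec(**d["spec"]),
            alpha=np.asarray(d["alpha"]),
            G=np.asarray(d["G"]),
            sigma2=float(d["sigma2"]),
            log_likelihood=float(d.get("log_likelihood", np.nan)),
            n_patients_fit=int(d.get("n_patients_fit", 0)),
            method=d.get("method", "ml"),
            converged=bool(d.get("converged", True)),
            boundary_warning=bool(d.get("boundary_warning", False)),
        )

    @classmethod
    def from_json(cls, path) -> "ReferenceCourse":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def polynomial_design(times: Sequence[float], degree: int) -> np.ndarray:
    """Design matrix with columns time^0 ... time^degree (exact powers)."""
    if degree not in (1, 2, 3):
        raise ValueError("degree must be 1, 2 or 3")
    t = np.asarray(times, dtype=float)
    if t.ndim != 1 or t.size == 0:
        raise ValueError("times must be a non-empty 1-d sequence")
    if t.min() < 0.0 or t.max() > 24.0:
        raise ValueError("times must lie within [0, 24]")
    return t[:, None] ** np.arange(degree + 1)


def evaluate_course(course: ReferenceCourse, t):
    """Reference-course SBP at time ``t`` (fixed effects only).

    ``t`` may be a scalar or array; values outside [0, 24] are rejected
    because the course is not modelled beyond the monitoring window.
    """
    t_arr = np.asarray(t, dtype=float)
    if t_arr.size and (t_arr.min() < 0.0 or t_arr.max() > 24.0):
        raise ValueError("t must lie within [0, 24] hours")
    value = t_arr[..., None] ** np.arange(course.spec.degree + 1) @ course.alpha
    return float(value) if np.isscalar(t) or t_arr.ndim == 0 else value


def select_favourable(cohort: Sequence[PatientRecord], outcome_name: str) -> list[PatientRecord]:
    """Patients with the favourable (=1) value of the outcome."""
    return [p for p in cohort if p.outcomes.get(outcome_name) == 1]


def marginal_covariance(course: ReferenceCourse, times: Sequence[float]) -> np.ndarray:
    """Model-implied covariance of one patient's measurements: Z G Z' + sigma2 I."""
    Z = polynomial_design(times, course.spec.degree)
    return Z @ course.G @ Z.T + course.sigma2 * np.eye(len(Z))


# ---------------------------------------------------------------------------
# marginal likelihood machinery
# ---------------------------------------------------------------------------


class _SuffStats:
    """Per-patient sufficient statistics for the marginal likelihood."""

    def __init__(self, patients: Sequence[PatientRecord], degree: int):
        p = degree + 1
        A, b, c, n = [], [], [], []
        for rec in patients:
            if rec.n_measurements == 0:
                raise ValueError(f"patient {rec.patient_id} has no measurements")
            Z = polynomial_design(rec.times, degree)
            A.append(Z.T @ Z)
            b.append(Z.T @ rec.sbp)
            c.append(float(rec.sbp @ rec.sbp))
            n.append(rec.n_measurements)
        self.A = np.asarray(A)  # (P, p, p)
        self.b = np.asarray(b)  # (P, p)
        self.c = np.asarray(c)  # (P,)
        self.n = np.asarray(n)  # (P,)
        # canonical patient order makes every summation (and hence the whole
        # fit) bit-identical under permutation of the input cohort
        order = np.lexsort((self.b[:, 0], self.c, self.n))
        self.A, self.b, self.c, self.n = (
            self.A[order], self.b[order], self.c[order], self.n[order]
        )
        self.N = int(self.n.sum())
        self.P = len(patients)
        self.p = p


def _n_params(p: int) -> int:
    return p + p * (p - 1) // 2 + 1


def _unpack(theta: np.ndarray, p: int) -> tuple[np.ndarray, float]:
    """theta -> (Cholesky factor L of G, sigma2)."""
    L = np.zeros((p, p))
    L[np.diag_indices(p)] = np.exp(np.clip(theta[:p], -_LOG_BOUND, _LOG_BOUND))
    if p > 1:
        L[np.tril_indices(p, -1)] = theta[p:-1]
    sigma2 = float(np.exp(np.clip(theta[-1], -_LOG_BOUND, _LOG_BOUND)))
    return L, sigma2


def _neg2ll(theta: np.ndarray, st: _SuffStats, reml: bool):
    """-2 log (restricted) marginal likelihood, with GLS fixed effects profiled out.

    Returns (criterion, alpha) — alpha is the profiled GLS estimate.
    """
    p = st.p
    L, sigma2 = _unpack(theta, p)
    eye = np.eye(p)
    AL = st.A @ L  # (P, p, p)
    W = L.T @ AL + sigma2 * eye  # (P, p, p); PD for sigma2 > 0
    try:
        chol = np.linalg.cholesky(W)
    except np.linalg.LinAlgError:
        return 1e13, None
    logdet_W = 2.0 * np.log(np.einsum("pii->pi", chol)).sum()
    Ltb = st.b @ L  # (P, p) rows = (L' b_i)'
    Winv_Ltb = np.linalg.solve(W, Ltb[..., None])  # (P, p, 1)
    Winv_ALt = np.linalg.solve(W, np.swapaxes(AL, 1, 2))  # (P, p, p)
    ZVZ = (st.A - AL @ Winv_ALt) / sigma2
    ZVq = (st.b - (AL @ Winv_Ltb)[..., 0]) / sigma2
    qVq = (st.c - np.einsum("pi,pi->p", Ltb, Winv_Ltb[..., 0])) / sigma2
    S = ZVZ.sum(axis=0)
    s = ZVq.sum(axis=0)
    sign, logdet_S = np.linalg.slogdet(S)
    if sign <= 0:
        return 1e13, None
    try:
        alpha = np.linalg.solve(S, s)
    except np.linalg.LinAlgError:
        return 1e13, None
    quad = qVq.sum() - alpha @ s
    logdet_V = (st.N - st.P * p) * np.log(sigma2) + logdet_W
    crit = st.N * _LOG_2PI + logdet_V + quad
    if reml:
        crit += logdet_S - p * _LOG_2PI
    if not np.isfinite(crit):
        return 1e13, None
    return float(crit), alpha


def _start_values(st: _SuffStats) -> np.ndarray:
    """Moment-based start: per-patient OLS coefficients pooled into alpha/G/sigma2."""
    p = st.p
    coefs, resvar = [], []
    for i in range(st.P):
        if st.n[i] < p + 1:
            continue
        try:
            beta = np.linalg.solve(st.A[i] + 1e-10 * np.eye(p), st.b[i])
        except np.linalg.LinAlgError:
            continue
        rss = max(st.c[i] - st.b[i] @ beta, 0.0)
        coefs.append(beta)
        resvar.append(rss / (st.n[i] - p))
    if len(coefs) >= 2:
        coefs_arr = np.asarray(coefs)
        G0 = np.atleast_2d(np.cov(coefs_arr, rowvar=False))
        sigma20 = max(float(np.median(resvar)), 1e-6)
    else:  # too few long series for moments; fall back to a generic start
        G0 = np.eye(p)
        sigma20 = 1.0
    vals, vecs = np.linalg.eigh((G0 + G0.T) / 2.0)
    vals = np.clip(vals, 1e-6 * max(1.0, vals.max()), None)
    L0 = np.linalg.cholesky((vecs * vals) @ vecs.T)
    theta0 = np.empty(_n_params(p))
    theta0[:p] = np.log(np.diag(L0))
    if p > 1:
        theta0[p:-1] = L0[np.tril_indices(p, -1)]
    theta0[-1] = np.log(sigma20)
    return theta0


def _optimise(st: _SuffStats, config: FitConfig):
    reml = config.method == "reml"
    theta0 = np.asarray(config.start, dtype=float) if config.start is not None else _start_values(st)
    if theta0.shape != (_n_params(st.p),):
        raise ValueError("start vector has wrong length")
    bounds = [(-_LOG_BOUND, _LOG_BOUND)] * st.p
    bounds += [(None, None)] * (st.p * (st.p - 1) // 2)
    bounds += [(-_LOG_BOUND, _LOG_BOUND)]
    rng = np.random.default_rng(config.seed)

    def objective(theta):
        return _neg2ll(theta, st, reml)[0]

    best = None
    for restart in range(config.n_restarts + 1):
        t0 = theta0 if restart == 0 else theta0 + rng.normal(scale=0.5, size=theta0.size)
        res = minimize(
            objective,
            t0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": config.max_iter, "ftol": config.tol * 1e-4, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e12:
        raise ConvergenceError(
            f"likelihood optimisation failed after {config.n_restarts + 1} starts "
            f"(status={getattr(best, 'status', 'n/a')}, "
            f"message={getattr(best, 'message', 'n/a')})"
        )
    return best


def fit_reference_course(
    favorable_patients: Sequence[PatientRecord],
    spec: CourseSpec,
    fit_config: FitConfig | None = None,
) -> ReferenceCourse:
    """Fit the reference course for ``spec`` on the favourable subcohort.

    All patients must carry the favourable (=1) value of ``spec.outcome_name``
    (checked unless ``fit_config.check_outcome`` is disabled for low-level use).
    Raises :class:`ConvergenceError` with optimiser diagnostics on failure;
    degenerate boundary fits (a variance estimate at its lower bound) are
    returned with ``boundary_warning`` set rather than failing.
    """
    config = fit_config or FitConfig()
    p = spec.degree + 1
    patients = list(favorable_patients)
    if len(patients) < 2 * p:
        raise ValueError(
            f"need at least {2 * p} patients to fit a degree-{spec.degree} course, "
            f"got {len(patients)}"
        )
    if config.check_outcome:
        bad = [q.patient_id for q in patients if q.outcomes.get(spec.outcome_name) != 1]
        if bad:
            raise ValueError(
                f"patients without favourable {spec.outcome_name!r}: {bad[:5]}"
            )
    st = _SuffStats(patients, spec.degree)
    if st.N <= p:
        raise ValueError("fewer total measurements than fixed-effect parameters")
    best = _optimise(st, config)
    crit, alpha = _neg2ll(best.x, st, reml=config.method == "reml")
    L, sigma2 = _unpack(best.x, p)
    G = L @ L.T
    # degenerate boundary fit: a variance estimate collapsed to ~0 on the
    # mm Hg scale of the data
    boundary = bool(np.diag(G).min() < 1e-4 or sigma2 < 1e-4)
    if boundary:
        warnings.warn(
            "variance component at its lower bound; estimates are degenerate",
            RuntimeWarning,
            stacklevel=2,
        )
    return ReferenceCourse(
        spec=spec,
        alpha=alpha,
        G=G,
        sigma2=sigma2,
        log_likelihood=-0.5 * crit,
        n_patients_fit=len(patients),
        method=config.method,
        converged=bool(best.success),
        boundary_warning=boundary,
        theta=best.x.copy(),
    )
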