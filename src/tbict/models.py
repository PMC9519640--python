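"""Logistic models for 6-month mortality.

Implements the model set used to validate admission-CT scores on an ICU
traumatic-brain-injury cohort:

* *first-level customization* of each CT score — refitting the logistic
  link of the score against the new population's outcome without changing
  the score itself (Marshall and NIRIS as dummy-coded categorical
  predictors, Helsinki as a single numeric term);
* a clinical *base model* — age, GCS, a modified SAPS II (the score
  without its age, GCS and chronic-comorbidity components) and a
  chronic-comorbidity flag, all entered untransformed;
* *combined models* — the base covariates plus one CT-score coding.

Fitting is plain maximum likelihood via iteratively reweighted least
squares (IRLS), no shrinkage. Convergence is declared when the relative
change in log-likelihood falls below 1e-10 (at most 100 iterations);
complete separation is detected by coefficient divergence (|beta| > 30 on
the log-odds scale) and raised as :class:`SeparationError` rather than
returning unstable estimates.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .scoring import CTFindings, MARSHALL_CLASSES, ScoreResult, score_all

__all__ = [
    "PatientRecord",
    "LogisticFit",
    "ModelError",
    "SeparationError",
    "fit_logistic",
    "customize_ct_model",
    "build_base_model",
    "build_combined_model",
    "CT_SYSTEMS",
]

logger = logging.getLogger(__name__)

CT_SYSTEMS = ("marshall", "helsinki", "niris")

BASE_COVARIATES = ("age_years", "gcs", "saps2_modified", "chronic_comorbidity")

#: IRLS convergence: relative log-likelihood change below this stops iteration.
CONVERGENCE_TOL = 1e-10
MAX_ITER = 100
#: |log-odds coefficient| beyond this is treated as complete separation.
SEPARATION_BOUND = 30.0


class ModelError(ValueError):
    """Invalid model specification or data for fitting."""


class SeparationError(ModelError):
    """Complete (or quasi-complete) separation: the MLE does not exist."""


@dataclass(frozen=True)
class PatientRecord:
    """One patient: clinical covariates, CT findings and 6-month vital status.

    Clinical covariates may be ``None`` for records expanded from printed
    contingency tables, which carry only a CT category and the outcome;
    models requiring a missing covariate refuse to fit.
    """

    patient_id: object
    findings: CTFindings
    age_years: Optional[float] = None
    gcs: Optional[int] = None
    saps2_modified: Optional[float] = None
    chronic_comorbidity: Optional[bool] = None
    dead_6mo: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age_years is not None and not (
                math.isfinite(self.age_years) and self.age_years >= 18):
            raise ModelError(f"age_years must be >= 18 (adult cohort), "
                             f"got {self.age_years!r}")
        if self.gcs is not None and not (3 <= self.gcs <= 15):
            raise ModelError(f"gcs out of range [3, 15]: {self.gcs!r}")
        if self.saps2_modified is not None and not (
                math.isfinite(self.saps2_modified) and self.saps2_modified >= 0):
            raise ModelError(f"saps2_modified must be non-negative, "
                             f"got {self.saps2_modified!r}")


@dataclass
class LogisticFit:
    """A converged maximum-likelihood logistic fit.

    ``predictor_spec`` names the design columns in order, starting with the
    intercept. ``fitted_probabilities`` are per-patient predicted
    probabilities of death in (0, 1), aligned with the input order.
    """

    predictor_spec: list[str]
    coefficients: np.ndarray
    log_likelihood: float
    null_log_likelihood: float
    n: int
    fitted_probabilities: np.ndarray
    standard_errors: Optional[np.ndarray] = None
    n_iter: int = 0

    @property
    def expected_events(self) -> float:
        """Sum of fitted probabilities; equals the observed event count for
        any intercept model at convergence (score equation)."""
        return float(np.sum(self.fitted_probabilities))

    def predict(self, design: np.ndarray) -> np.ndarray:
        X = np.column_stack([np.ones(len(design)), np.asarray(design, float)])
        return _expit(X @ self.coefficients)


def _expit(eta: np.ndarray) -> np.ndarray:
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


def _bernoulli_ll(y: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-300, 1 - 1e-16)
    return float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))


def fit_logistic(
    outcome: Sequence[bool],
    design: Optional[np.ndarray] = None,
    names: Optional[Sequence[str]] = None,
) -> LogisticFit:
    """Fit ``P(death) = expit(b0 + X b)`` by IRLS maximum likelihood.

    ``design`` is the covariate matrix *without* an intercept column (or
    ``None``/empty for an intercept-only model); an intercept is always
    included. Returns both the model log-likelihood and the intercept-only
    log-likelihood on the same data (closed form from the event rate), so
    pseudo-R² statistics can be computed downstream.

    Raises
    ------
    ModelError
        If the outcome is single-class, the design is under-determined
        (n < number of parameters) or rank-deficient.
    SeparationError
        If coefficients diverge (complete separation).
    """
    y = np.asarray(outcome, dtype=float)
    n = y.size
    if design is None:
        X = np.ones((n, 1))
        col_names = ["intercept"]
    else:
        D = np.asarray(design, dtype=float)
        if D.ndim == 1:
            D = D[:, None]
        if D.shape[0] != n:
            raise ModelError(f"design has {D.shape[0]} rows for {n} outcomes")
        X = np.column_stack([np.ones(n), D])
        if names is None:
            names = [f"x{j}" for j in range(D.shape[1])]
        col_names = ["intercept"] + list(names)

    p_params = X.shape[1]
    n_events = int(y.sum())
    if n_events == 0 or n_events == n:
        raise ModelError("outcome is single-class; logistic MLE undefined")
    if n < p_params:
        raise ModelError(f"under-determined fit: n={n} < {p_params} parameters")
    if np.linalg.matrix_rank(X) < p_params:
        raise ModelError("design matrix is rank-deficient (collinear or "
                         "constant covariate)")

    rate = n_events / n
    ll_null = n_events * math.log(rate) + (n - n_events) * math.log(1 - rate)

    beta = np.zeros(p_params)
    beta[0] = math.log(rate / (1 - rate))
    ll_old = -np.inf
    ll = _bernoulli_ll(y, _expit(X @ beta))
    n_iter = 0
    for n_iter in range(1, MAX_ITER + 1):
        p = _expit(X @ beta)
        w = np.clip(p * (1 - p), 1e-10, None)
        z = X @ beta + (y - p) / w
        sw = np.sqrt(w)
        beta, *_ = np.linalg.lstsq(X * sw[:, None], z * sw, rcond=None)
        ll_old, ll = ll, _bernoulli_ll(y, _expit(X @ beta))
        # |beta| divergence, or a likelihood driven to its supremum of 0
        # (perfect prediction): either way the MLE sits at infinity.
        if np.max(np.abs(beta)) > SEPARATION_BOUND or ll > -1e-8:
            raise SeparationError(
                "coefficients diverged (|beta| > "
                f"{SEPARATION_BOUND:g} or perfect fit); data are "
                "(quasi-)separated")
        if abs(ll - ll_old) <= CONVERGENCE_TOL * (abs(ll_old) + CONVERGENCE_TOL):
            break
    else:
        logger.warning("IRLS reached max_iter=%d without convergence", MAX_ITER)

    fitted = _expit(X @ beta)
    w = fitted * (1 - fitted)
    info = X.T @ (X * w[:, None])
    try:
        se = np.sqrt(np.diag(np.linalg.inv(info)))
    except np.linalg.LinAlgError:  # pragma: no cover - near-singular info
        se = np.full(p_params, np.nan)
    return LogisticFit(
        predictor_spec=col_names,
        coefficients=beta,
        log_likelihood=ll,
        null_log_likelihood=ll_null,
        n=n,
        fitted_probabilities=fitted,
        standard_errors=se,
        n_iter=n_iter,
    )


# ---------------------------------------------------------------------------
# Design-matrix builders
# ---------------------------------------------------------------------------

def _outcomes(records: Sequence[PatientRecord]) -> np.ndarray:
    missing = [r.patient_id for r in records if r.dead_6mo is None]
    if missing:
        raise ModelError(f"{len(missing)} record(s) lack the dead_6mo outcome "
                         f"(first: {missing[0]!r})")
    return np.array([bool(r.dead_6mo) for r in records])


def ct_design(
    scores: Sequence[ScoreResult], system: str
) -> tuple[np.ndarray, list[str]]:
    """Design columns for one CT system.

    Marshall and NIRIS are dummy-coded over the *observed* levels with the
    lowest class (I / category 0) as reference; absent levels are dropped
    with a logged warning. Helsinki enters as a single numeric term.
    """
    if system not in CT_SYSTEMS:
        raise ModelError(f"unknown CT system {system!r}; expected one of "
                         f"{CT_SYSTEMS}")
    if system == "helsinki":
        x = np.array([s.helsinki for s in scores], dtype=float)
        return x[:, None], ["helsinki"]

    if system == "marshall":
        values = [s.marshall for s in scores]
        all_levels = list(MARSHALL_CLASSES)
    else:
        values = [s.niris for s in scores]
        all_levels = [0, 1, 2, 3, 4]
    observed = [lv for lv in all_levels if lv in set(values)]
    absent = [lv for lv in all_levels if lv not in set(values)]
    if absent:
        logger.warning("%s level(s) %s absent from data; dummies dropped",
                       system, absent)
    if len(observed) < 2:
        raise ModelError(f"{system} takes a single value in these data; "
                         "cannot customize")
    ref, rest = observed[0], observed[1:]
    cols = np.column_stack([[float(v == lv) for v in values] for lv in rest])
    names = [f"{system}[{lv}]" for lv in rest]
    logger.debug("%s dummy coding: reference level %r", system, ref)
    return cols, names


def customize_ct_model(
    records: Sequence[PatientRecord], system: str
) -> LogisticFit:
    """First-level customization: refit the logistic link of one CT score.

    The score itself is computed from each record's findings; only the
    mapping from score to mortality probability is re-estimated.
    """
    y = _outcomes(records)
    scores = score_all(records)
    X, names = ct_design(scores, system)
    return fit_logistic(y, X, names)


def _base_design(
    records: Sequence[PatientRecord],
) -> tuple[np.ndarray, list[str]]:
    for col in BASE_COVARIATES:
        if any(getattr(r, col) is None for r in records):
            raise ModelError(f"missing covariate column: {col}")
    X = np.column_stack([
        [float(r.age_years) for r in records],
        [float(r.gcs) for r in records],
        [float(r.saps2_modified) for r in records],
        [float(r.chronic_comorbidity) for r in records],
    ])
    names = list(BASE_COVARIATES)
    # A comorbidity flag constant in the sample is collinear with the
    # intercept; drop it rather than fail the whole base model.
    if np.ptp(X[:, 3]) == 0:
        logger.warning("chronic_comorbidity is constant; term dropped")
        X = X[:, :3]
        names = names[:3]
    return X, names


def build_base_model(records: Sequence[PatientRecord]) -> LogisticFit:
    """Clinical base model: age + GCS + modified SAPS II + chronic comorbidity."""
    y = _outcomes(records)
    X, names = _base_design(records)
    return fit_logistic(y, X, names)


def build_combined_model(
    records: Sequence[PatientRecord], system: str
) -> LogisticFit:
    """Base covariates plus one CT-score coding in a single logit fit."""
    y = _outcomes(records)
    Xb, base_names = _base_design(records)
    Xc, ct_names = ct_design(score_all(records), system)
    return fit_logistic(y, np.column_stack([Xb, Xc]), base_names + ct_names)
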