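"""Discrimination and calibration statistics for risk models.

The validation battery applied to every mortality model:

* Mann–Whitney AUC with the half-weight tie correction and a Wald 95% CI
  on the DeLong variance;
* the DeLong test for comparing two correlated AUCs (same patients, two
  models) via structural components;
* Nagelkerke's rescaled Cox–Snell pseudo-R²;
* the Hosmer–Lemeshow chi-square over risk-ordered groups (deciles of
  risk by default), applicable only when the model produces at least as
  many distinct risk levels as groups;
* the integrated discrimination improvement (IDI): the difference in
  discrimination slopes between a new and an old model,

  .. math::

     \\widehat{IDI} = (\\bar p_{new,events} - \\bar p_{old,events})
                    - (\\bar p_{new,nonevents} - \\bar p_{old,nonevents}),

  equivalently ``(IS_new - IS_old) - (IP_new - IP_old)`` where
  ``IS = ∫ sensitivity`` and ``IP = ∫ (1 - specificity)`` over the risk
  axis; both representations are computed and cross-checked;
* the Pearson chi-square test of independence for printed contingency
  tables.

All internal values are kept at full precision; rounding to the printed
precision happens only in the reporting layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .models import LogisticFit

__all__ = [
    "CrossTab",
    "AUCResult",
    "DeLongResult",
    "IDIResult",
    "PerformanceReport",
    "MetricError",
    "auc_mann_whitney",
    "delong_compare",
    "nagelkerke_r2",
    "hosmer_lemeshow",
    "idi",
    "chi_square_independence",
]


class MetricError(ValueError):
    """Invalid input for a performance statistic."""


@dataclass(frozen=True)
class CrossTab:
    """Ordered categories with per-category event / non-event counts."""

    labels: tuple
    events: tuple[int, ...]
    nonevents: tuple[int, ...]

    def __post_init__(self) -> None:
        if not (len(self.labels) == len(self.events) == len(self.nonevents)):
            raise MetricError("labels, events, nonevents must have equal length")
        if any(e < 0 for e in self.events) or any(a < 0 for a in self.nonevents):
            raise MetricError("counts must be non-negative")

    @property
    def totals(self) -> tuple[int, ...]:
        return tuple(e + a for e, a in zip(self.events, self.nonevents))

    @property
    def n(self) -> int:
        return sum(self.totals)

    @property
    def n_events(self) -> int:
        return sum(self.events)

    def as_array(self) -> np.ndarray:
        return np.column_stack([self.events, self.nonevents]).astype(float)


@dataclass(frozen=True)
class AUCResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float


@dataclass(frozen=True)
class DeLongResult:
    auc_a: float
    auc_b: float
    covariance: np.ndarray  # 2x2 covariance of (auc_a, auc_b)
    z: float
    p_value: float


@dataclass(frozen=True)
class IDIResult:
    mean_p_new_events: float
    mean_p_old_events: float
    mean_p_new_nonevents: float
    mean_p_old_nonevents: float
    idi: float
    is_new: float
    is_old: float
    ip_new: float
    ip_old: float
    ci_low: float
    ci_high: float


@dataclass
class PerformanceReport:
    """One row of the validation table for one model."""

    model: str
    auc: Optional[float] = None
    auc_ci_low: Optional[float] = None
    auc_ci_high: Optional[float] = None
    delong_p: Optional[float] = None
    hl_chi2: Optional[float] = None
    hl_p: Optional[float] = None
    nagelkerke_r2: Optional[float] = None
    idi: Optional[float] = None
    idi_ci_low: Optional[float] = None
    idi_ci_high: Optional[float] = None
    reference: Optional[str] = None


# ---------------------------------------------------------------------------
# AUC and the DeLong machinery
# ---------------------------------------------------------------------------

def _split(probabilities, outcomes) -> tuple[np.ndarray, np.ndarray]:
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if p.shape != y.shape:
        raise MetricError(f"length mismatch: {p.shape} probabilities vs "
                          f"{y.shape} outcomes")
    pos, neg = p[y], p[~y]
    if pos.size == 0 or neg.size == 0:
        raise MetricError("both outcome classes must be present")
    return pos, neg


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components.

    ``v10[i]`` is the placement of event i among non-events (fraction of
    non-events scored below it, ties half-weighted); ``v01[j]`` likewise
    for non-event j among events. ``mean(v10) = mean(v01) = AUC`` exactly.
    """
    neg_sorted = np.sort(neg)
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + hi) / (2.0 * neg.size)
    pos_sorted = np.sort(pos)
    lo = np.searchsorted(pos_sorted, neg, side="left")
    hi = np.searchsorted(pos_sorted, neg, side="right")
    # placement of a non-event = fraction of events scored ABOVE it
    v01 = 1.0 - (lo + hi) / (2.0 * pos.size)
    return v10, v01


def auc_mann_whitney(probabilities, outcomes) -> AUCResult:
    """Ties-corrected pairwise-concordance AUC with a DeLong-variance CI.

    AUC = (concordant pairs + 0.5 * tied pairs) / (n_events * n_nonevents);
    the 95% CI is Wald on the AUC scale using the DeLong variance,
    truncated to [0, 1].
    """
    pos, neg = _split(probabilities, outcomes)
    v10, v01 = _placements(pos, neg)
    auc = float(v10.mean())
    var = _delong_var(v10, v01)
    se = math.sqrt(var)
    half = stats.norm.ppf(0.975) * se
    return AUCResult(auc=auc, ci_low=max(0.0, auc - half),
                     ci_high=min(1.0, auc + half), se=se)


def _delong_var(v10: np.ndarray, v01: np.ndarray) -> float:
    s10 = v10.var(ddof=1) if v10.size > 1 else 0.0
    s01 = v01.var(ddof=1) if v01.size > 1 else 0.0
    return float(s10 / v10.size + s01 / v01.size)


def delong_compare(p_model_a, p_model_b, outcomes) -> DeLongResult:
    """DeLong test for two correlated AUCs measured on the same patients.

    Returns both AUCs, the 2x2 covariance of the AUC estimators built from
    the structural components, and the two-sided normal z / p for
    AUC_a − AUC_b. Comparing a model with itself gives difference 0 and
    p = 1 by convention.
    """
    pa = np.asarray(p_model_a, dtype=float)
    pb = np.asarray(p_model_b, dtype=float)
    if pa.shape != pb.shape:
        raise MetricError(f"length mismatch between models: {pa.shape} vs "
                          f"{pb.shape}")
    y = np.asarray(outcomes, dtype=bool)
    pos_a, neg_a = _split(pa, y)
    pos_b, neg_b = _split(pb, y)
    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = v10a.size, v01a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 0:
        z = 0.0 if diff == 0 else math.inf * math.copysign(1, diff)
    else:
        z = diff / math.sqrt(var_diff)
    p = 1.0 if not math.isfinite(z) and diff == 0 else float(
        2 * stats.norm.sf(abs(z)))
    return DeLongResult(auc_a=auc_a, auc_b=auc_b, covariance=cov,
                        z=float(z), p_value=p)


# ---------------------------------------------------------------------------
# Pseudo-R² and calibration
# ---------------------------------------------------------------------------

def nagelkerke_r2(fit: Union[LogisticFit, tuple[float, float, int]]) -> float:
    """Nagelkerke's rescaled Cox–Snell R² for a fitted logistic model.

    ``R²_CS = 1 − exp(2(LL₀ − LL₁)/n)`` divided by its maximum attainable
    value ``1 − exp(2 LL₀ / n)``; ranges over [0, 1], with 1 a model that
    fully explains the outcome.
    """
    if isinstance(fit, LogisticFit):
        ll1, ll0, n = fit.log_likelihood, fit.null_log_likelihood, fit.n
    else:
        ll1, ll0, n = fit
    if ll1 < ll0 - 1e-8:
        raise MetricError(
            f"model log-likelihood {ll1:.6g} below null {ll0:.6g}; "
            "the null model must be nested in the fitted model")
    r2_cs = 1.0 - math.exp(2.0 * (ll0 - min(ll1, 0.0)) / n)
    max_cs = 1.0 - math.exp(2.0 * ll0 / n)
    return float(min(1.0, max(0.0, r2_cs / max_cs)))


def hosmer_lemeshow(probabilities, outcomes, groups: int = 10
                    ) -> tuple[float, int, float]:
    """Hosmer–Lemeshow calibration test over risk-ordered groups.

    Patients are split into ``groups`` quantile bins of predicted risk
    (ties assigned to the lower bin); the statistic sums
    ``(obs − exp)² / (exp · (1 − exp/n_bin))`` over bins and is referred to
    a chi-square with ``groups − 2`` degrees of freedom.

    The test is not applicable to models with fewer distinct risk levels
    than groups (e.g. few-category CT scores); this raises
    :class:`MetricError`.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if p.shape != y.shape:
        raise MetricError("length mismatch between probabilities and outcomes")
    n = p.size
    if n < groups:
        raise MetricError(f"n={n} smaller than groups={groups}")
    if np.unique(p).size < groups:
        raise MetricError(
            f"only {np.unique(p).size} distinct predicted probabilities for "
            f"{groups} groups; the Hosmer-Lemeshow test is not applicable to "
            "models with fewer risk levels than groups")

    order = np.argsort(p, kind="stable")
    ps, ys = p[order], y[order]
    bins = (np.arange(n) * groups) // n
    # ties: every copy of a value joins the bin of its first occurrence
    first = np.zeros(n, dtype=int)
    _, start_idx = np.unique(ps, return_index=True)
    first[start_idx] = 1
    group_of_value = bins[np.maximum.accumulate(np.where(first, np.arange(n), 0))]
    bins = group_of_value

    chi2 = 0.0
    used = 0
    for g in range(groups):
        mask = bins == g
        nb = int(mask.sum())
        if nb == 0:
            continue
        used += 1
        obs = float(ys[mask].sum())
        exp = float(ps[mask].sum())
        denom = exp * (1.0 - exp / nb)
        if denom <= 0:
            if abs(obs - exp) > 1e-12:
                chi2 = math.inf
            continue
        chi2 += (obs - exp) ** 2 / denom
    df = used - 2
    if df < 1:
        raise MetricError("fewer than 3 non-empty risk groups; test undefined")
    pval = float(stats.chi2.sf(chi2, df))
    return float(chi2), df, pval


# ---------------------------------------------------------------------------
# Integrated discrimination improvement
# ---------------------------------------------------------------------------

def _step_integral(values: np.ndarray, exceed_fraction) -> float:
    """∫₀¹ F(c) dc for the step function F(c) = fraction of `values` > c."""
    cuts = np.concatenate([[0.0], np.unique(values), [1.0]])
    total = 0.0
    for left, right in zip(cuts[:-1], cuts[1:]):
        if right <= left:
            continue
        total += exceed_fraction(left) * (right - left)
    return total


def idi(p_new, p_old, outcomes, ci_method: str = "analytic",
        n_boot: int = 2000, seed: int = 0) -> IDIResult:
    """Integrated discrimination improvement of a new model over an old one.

    Computes the four group means of predicted risk (events / non-events ×
    new / old model) and the difference-of-differences estimate; also the
    integrated sensitivity (IS) and one-minus-specificity (IP) integrals
    over the risk axis, whose difference representation is verified to
    agree with the group-mean form to numerical tolerance. Theoretical
    range [−2, 2].

    ``ci_method``: ``"analytic"`` uses the normal approximation on the
    per-patient differences ``p_new − p_old`` within events and within
    non-events; ``"bootstrap"`` resamples patients (``n_boot`` replicates,
    seeded) and takes the percentile interval.
    """
    pn = np.asarray(p_new, dtype=float)
    po = np.asarray(p_old, dtype=float)
    y = np.asarray(outcomes, dtype=bool)
    if not (pn.shape == po.shape == y.shape):
        raise MetricError("p_new, p_old, outcomes must have equal length")
    if not (y.any() and (~y).any()):
        raise MetricError("both outcome classes must be present")

    ev, nev = y, ~y
    m_ne, m_oe = float(pn[ev].mean()), float(po[ev].mean())
    m_nn, m_on = float(pn[nev].mean()), float(po[nev].mean())
    estimate = (m_ne - m_oe) - (m_nn - m_on)

    # Second representation: IS = ∫ sensitivity dc equals the event-group
    # mean risk for step-function integration over [0, 1]; IP likewise.
    def frac_above(values):
        s = np.sort(values)
        return lambda c: 1.0 - np.searchsorted(s, c, side="right") / s.size

    is_new = _step_integral(pn, frac_above(pn[ev]))
    is_old = _step_integral(po, frac_above(po[ev]))
    ip_new = _step_integral(pn, frac_above(pn[nev]))
    ip_old = _step_integral(po, frac_above(po[nev]))
    alt = (is_new - is_old) - (ip_new - ip_old)
    if abs(alt - estimate) > 1e-8:
        raise AssertionError(
            f"IDI representations disagree: {estimate} vs {alt}")

    if ci_method == "analytic":
        d_ev = pn[ev] - po[ev]
        d_nev = pn[nev] - po[nev]
        var = (d_ev.var(ddof=1) / d_ev.size if d_ev.size > 1 else 0.0) + \
              (d_nev.var(ddof=1) / d_nev.size if d_nev.size > 1 else 0.0)
        half = stats.norm.ppf(0.975) * math.sqrt(var)
        lo, hi = estimate - half, estimate + half
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        n = y.size
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            yb = y[idx]
            if not (yb.any() and (~yb).any()):
                reps[b] = np.nan
                continue
            pnb, pob = pn[idx], po[idx]
            reps[b] = ((pnb[yb].mean() - pob[yb].mean())
                       - (pnb[~yb].mean() - pob[~yb].mean()))
        lo, hi = np.nanpercentile(reps, [2.5, 97.5])
    else:
        raise MetricError(f"unknown ci_method {ci_method!r}")

    return IDIResult(
        mean_p_new_events=m_ne, mean_p_old_events=m_oe,
        mean_p_new_nonevents=m_nn, mean_p_old_nonevents=m_on,
        idi=float(estimate), is_new=float(is_new), is_old=float(is_old),
        ip_new=float(ip_new), ip_old=float(ip_old),
        ci_low=float(lo), ci_high=float(hi))


# ---------------------------------------------------------------------------
# Contingency-table chi-square
# ---------------------------------------------------------------------------

def chi_square_independence(table: Union[CrossTab, np.ndarray]
                            ) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on a contingency table.

    Accepts a :class:`CrossTab` (categories × event/non-event) or any 2-D
    count array. No continuity correction; df = (r−1)(c−1).
    """
    counts = table.as_array() if isinstance(table, CrossTab) else \
        np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise MetricError("need a table with at least 2 rows and 2 columns")
    if (counts.sum(axis=0) == 0).any() or (counts.sum(axis=1) == 0).any():
        raise MetricError("zero marginal total; expected counts undefined")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)
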