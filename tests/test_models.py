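"""Logistic fitting: IRLS, score customization, base and combined models."""

import logging
import math

import numpy as np
import pytest

from tbict.cohort import CohortParams, generate_cohort
from tbict.models import (ModelError, PatientRecord, SeparationError,
                          build_base_model, build_combined_model,
                          customize_ct_model, fit_logistic)
from tbict.scoring import CTFindings

F = CTFindings


def _records(findings_list, dead, **clinical):
    return [PatientRecord(patient_id=i, findings=f, dead_6mo=bool(d),
                          **clinical)
            for i, (f, d) in enumerate(zip(findings_list, dead))]


def test_intercept_only_closed_form():
    """MLE intercept of an empty model is the logit of the event rate
    (here the source cohort's 710 deaths of 3031)."""
    y = np.r_[np.ones(710), np.zeros(2321)]
    fit = fit_logistic(y)
    assert fit.coefficients[0] == pytest.approx(math.log(710 / 2321),
                                                abs=1e-8)
    assert fit.log_likelihood == pytest.approx(fit.null_log_likelihood,
                                               abs=1e-6)


def test_saturated_dummy_fit_reproduces_cell_rates(table_records,
                                                   table_outcomes):
    fit = customize_ct_model(table_records, "niris")
    rates = np.array([27 / 320, 12 / 225, 220 / 1297, 142 / 526, 309 / 663])
    fitted_by_cat = np.unique(np.round(fit.fitted_probabilities, 10))
    assert np.allclose(np.sort(fitted_by_cat), np.sort(rates), atol=1e-8)
    # score equation: expected events equal observed events
    assert fit.fitted_probabilities.sum() == pytest.approx(
        table_outcomes.sum(), abs=1e-6)


def test_complete_separation_is_flagged():
    x = np.r_[-np.ones(10), np.ones(10)]
    y = np.r_[np.zeros(10), np.ones(10)]
    with pytest.raises(SeparationError):
        fit_logistic(y, x[:, None], ["x"])


def test_single_class_outcome_rejected():
    with pytest.raises(ModelError, match="single-class"):
        fit_logistic(np.zeros(20), np.arange(20.0)[:, None])


def test_under_determined_fit_rejected():
    y = np.array([0, 1, 0, 1, 1.0])
    X = np.eye(5)
    with pytest.raises(ModelError, match="under-determined"):
        fit_logistic(y, X)


def test_two_class_marshall_dummy_closed_form():
    """Dummy coefficient for a two-class cross-tab is the difference of
    group logits."""
    findings = [F()] * 20 + [F(sdh_volume_cm3=40)] * 20
    dead = [1] * 2 + [0] * 18 + [1] * 10 + [0] * 10  # rates 0.1 and 0.5
    fit = customize_ct_model(_records(findings, dead), "marshall")
    expected = 0.0 - math.log(0.1 / 0.9)
    assert fit.predictor_spec == ["intercept", "marshall[VI]"]
    assert fit.coefficients[1] == pytest.approx(expected, abs=1e-6)


def test_constant_helsinki_score_rejected():
    recs = _records([F(sah_present=True)] * 30, [1] * 10 + [0] * 20)
    with pytest.raises(ModelError, match="rank-deficient|collinear"):
        customize_ct_model(recs, "helsinki")


def test_unknown_system_rejected(table_records):
    with pytest.raises(ModelError, match="unknown CT system"):
        customize_ct_model(table_records, "rotterdam")


def test_base_model_mean_fitted_equals_death_rate(default_cohort):
    fit = build_base_model(default_cohort.records)
    y = np.array([r.dead_6mo for r in default_cohort.records])
    assert fit.fitted_probabilities.sum() == pytest.approx(y.sum(), abs=1e-6)
    assert fit.log_likelihood >= fit.null_log_likelihood
    assert np.all((fit.fitted_probabilities > 0)
                  & (fit.fitted_probabilities < 1))


def test_missing_covariate_error_names_column(default_cohort):
    import dataclasses
    broken = [dataclasses.replace(r, saps2_modified=None)
              for r in default_cohort.records[:100]]
    with pytest.raises(ModelError, match="saps2_modified"):
        build_base_model(broken)


def test_constant_comorbidity_dropped_with_warning(caplog):
    rng = np.random.default_rng(5)
    n = 400
    age = rng.uniform(20, 90, n)
    dead = rng.random(n) < 1 / (1 + np.exp(-(age - 55) / 10))
    if dead.all() or not dead.any():  # pragma: no cover
        dead[0] = not dead[0]
    gcs = rng.integers(3, 16, n)
    saps = rng.uniform(0, 60, n)
    recs = [PatientRecord(patient_id=i, findings=F(), age_years=float(a),
                          gcs=int(g), saps2_modified=float(s),
                          chronic_comorbidity=False, dead_6mo=bool(d))
            for i, (a, g, s, d) in enumerate(zip(age, gcs, saps, dead))]
    with caplog.at_level(logging.WARNING, logger="tbict.models"):
        fit = build_base_model(recs)
    assert "chronic_comorbidity" not in fit.predictor_spec
    assert any("constant" in m for m in caplog.messages)


def test_combined_model_nests_base(default_cohort):
    base = build_base_model(default_cohort.records)
    comb = build_combined_model(default_cohort.records, "helsinki")
    assert comb.log_likelihood >= base.log_likelihood - 1e-8
    # predictor order: base covariates first, CT terms last
    assert comb.predictor_spec[:5] == ["intercept", "age_years", "gcs",
                                       "saps2_modified",
                                       "chronic_comorbidity"]
    assert comb.predictor_spec[-1] == "helsinki"


def test_irls_matches_statsmodels_reference(default_cohort):
    """Independent cross-check of the IRLS fitter against statsmodels."""
    sm = pytest.importorskip("statsmodels.api")
    recs = default_cohort.records[:1500]
    fit = build_base_model(recs)
    y = np.array([r.dead_6mo for r in recs], dtype=float)
    X = np.column_stack([
        np.ones(len(recs)),
        [r.age_years for r in recs],
        [r.gcs for r in recs],
        [r.saps2_modified for r in recs],
        [float(r.chronic_comorbidity) for r in recs]])
    ref = sm.Logit(y, X).fit(disp=0)
    assert np.allclose(fit.coefficients, ref.params, atol=1e-6)
    assert fit.log_likelihood == pytest.approx(ref.llf, abs=1e-6)
    assert np.allclose(fit.standard_errors, ref.bse, rtol=1e-4)


def test_uninformative_ct_term_gives_chi2_likelihood_ratio():
    """With NIRIS assigned independently of outcome, the likelihood-ratio
    statistic of combined-vs-base follows chi-square with 4 df."""
    from scipy import stats
    import dataclasses

    cohort = generate_cohort(CohortParams(n=2000, seed=202))
    base = build_base_model(cohort.records)
    rng = np.random.default_rng(99)
    findings = [r.findings for r in cohort.records]
    lrs = []
    for _ in range(400):
        perm = rng.permutation(len(findings))
        shuffled = [dataclasses.replace(r, findings=findings[j])
                    for r, j in zip(cohort.records, perm)]
        comb = build_combined_model(shuffled, "niris")
        lrs.append(2 * (comb.log_likelihood - base.log_likelihood))
    lrs = np.array(lrs)
    assert lrs.mean() == pytest.approx(4.0, abs=0.6)
    ks = stats.kstest(lrs, stats.chi2(df=4).cdf)
    assert ks.pvalue > 1e-3
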