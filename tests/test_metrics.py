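"""Discrimination and calibration statistics."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tbict.metrics import (CrossTab, MetricError, auc_mann_whitney,
                           chi_square_independence, delong_compare,
                           hosmer_lemeshow, idi, nagelkerke_r2)
from tbict.cohort import niris_outcome_crosstab
from tbict.models import customize_ct_model


def _auc_brute(p, y):
    """Explicit enumeration over all event/non-event pairs."""
    pos, neg = p[y], p[~y]
    wins = sum((a > b) + 0.5 * (a == b) for a in pos for b in neg)
    return wins / (pos.size * neg.size)


def test_auc_perfect_and_chance():
    y = np.array([0, 0, 1, 1], bool)
    assert auc_mann_whitney([0.1, 0.2, 0.8, 0.9], y).auc == 1.0
    assert auc_mann_whitney([0.5] * 4, y).auc == 0.5


def test_auc_single_class_rejected():
    with pytest.raises(MetricError):
        auc_mann_whitney([0.1, 0.2], [True, True])


def test_auc_matches_brute_force_pair_counting():
    rng = np.random.default_rng(12)
    p = rng.choice([0.1, 0.2, 0.2, 0.5, 0.8], size=150)  # deliberate ties
    y = rng.random(150) < p
    if not (y.any() and (~y).any()):  # pragma: no cover
        y[0] = ~y[0]
    res = auc_mann_whitney(p, y)
    assert res.auc == pytest.approx(_auc_brute(p, y), abs=1e-12)
    skl = pytest.importorskip("sklearn.metrics")
    assert res.auc == pytest.approx(skl.roc_auc_score(y, p), abs=1e-12)


def test_niris_table_auc_and_ci(table_records, table_outcomes):
    """The customized NIRIS model on the printed cross-tab reproduces the
    published discrimination: AUC 0.70 (0.68-0.72)."""
    fit = customize_ct_model(table_records, "niris")
    res = auc_mann_whitney(fit.fitted_probabilities, table_outcomes)
    assert round(res.auc, 2) == 0.70
    assert round(res.ci_low, 2) == 0.68
    assert round(res.ci_high, 2) == 0.72
    assert res.auc == pytest.approx(
        _auc_brute(np.round(fit.fitted_probabilities, 12), table_outcomes),
        abs=1e-9)


@settings(max_examples=100, derandomize=True)
@given(seed=st.integers(0, 10_000),
       transform=st.sampled_from(["affine", "expit", "cube"]))
def test_auc_invariant_under_increasing_transforms(seed, transform):
    rng = np.random.default_rng(seed)
    p = rng.random(60)
    y = rng.random(60) < 0.4
    if not (y.any() and (~y).any()):
        return
    f = {"affine": lambda x: 3 * x + 1,
         "expit": lambda x: 1 / (1 + np.exp(-x)),
         "cube": lambda x: x ** 3}[transform]
    assert auc_mann_whitney(f(p), y).auc == pytest.approx(
        auc_mann_whitney(p, y).auc, abs=1e-12)


def test_delong_self_comparison_is_null():
    rng = np.random.default_rng(3)
    p = rng.random(100)
    y = rng.random(100) < p
    res = delong_compare(p, p, y)
    assert res.auc_a == res.auc_b
    assert res.z == 0.0
    assert res.p_value == 1.0


def test_delong_symmetry_and_estimator_identity():
    rng = np.random.default_rng(8)
    y = rng.random(300) < 0.3
    pa = np.clip(0.3 + 0.3 * y + 0.2 * rng.standard_normal(300), 0.01, 0.99)
    pb = np.clip(0.3 + 0.15 * y + 0.2 * rng.standard_normal(300), 0.01, 0.99)
    ab = delong_compare(pa, pb, y)
    ba = delong_compare(pb, pa, y)
    assert ab.z == pytest.approx(-ba.z, abs=1e-12)
    assert ab.p_value == pytest.approx(ba.p_value, abs=1e-12)
    # structural-component means reproduce the Mann-Whitney estimator
    assert ab.auc_a == pytest.approx(auc_mann_whitney(pa, y).auc, abs=1e-12)
    assert ab.auc_b == pytest.approx(auc_mann_whitney(pb, y).auc, abs=1e-12)


def test_delong_length_mismatch_rejected():
    with pytest.raises(MetricError, match="mismatch"):
        delong_compare([0.1, 0.2], [0.1], [True, False])


def test_nagelkerke_degenerate_and_closed_form():
    assert nagelkerke_r2((-100.0, -100.0, 50)) == 0.0
    assert nagelkerke_r2((0.0, -80.0, 200)) == 1.0
    with pytest.raises(MetricError):
        nagelkerke_r2((-120.0, -100.0, 50))


def test_nagelkerke_niris_table_value(table_records):
    fit = customize_ct_model(table_records, "niris")
    assert round(nagelkerke_r2(fit), 3) == 0.147


def test_nagelkerke_depends_on_duplication_only_through_n():
    """Duplicating every observation k times scales both log-likelihoods
    and n by k; the closed form then changes only through the stated n
    dependence."""
    ll0, ll1, n = -400.0, -350.0, 600
    base = nagelkerke_r2((ll1, ll0, n))
    for k in (2, 5):
        assert nagelkerke_r2((k * ll1, k * ll0, k * n)) == pytest.approx(
            base, abs=1e-12)


def test_hosmer_lemeshow_exact_calibration():
    """If every risk bin's observed rate equals its mean prediction, the
    statistic is 0 and p = 1."""
    p, y = [], []
    for i in range(1, 11):
        pi = i / 20
        p += [pi] * 20
        y += [1] * int(pi * 20) + [0] * (20 - int(pi * 20))
    chi2, df, pval = hosmer_lemeshow(np.array(p), np.array(y))
    assert chi2 == pytest.approx(0.0, abs=1e-10)
    assert df == 8
    assert pval == pytest.approx(1.0)


def test_hosmer_lemeshow_not_applicable_to_few_level_models():
    rng = np.random.default_rng(0)
    p = rng.choice(np.linspace(0.1, 0.9, 9), 200)  # 9 < 10 risk levels
    y = rng.random(200) < p
    with pytest.raises(MetricError, match="not applicable"):
        hosmer_lemeshow(p, y, groups=10)


def test_idi_identity_and_printed_arithmetic():
    y = np.array([True, True, False, False])
    same = idi([0.6, 0.4, 0.3, 0.1], [0.6, 0.4, 0.3, 0.1], y)
    assert same.idi == 0.0
    res = idi(p_new=[0.7, 0.5, 0.2, 0.2], p_old=[0.6, 0.4, 0.3, 0.1],
              outcomes=y)
    assert res.idi == pytest.approx(0.1, abs=1e-12)
    assert res.mean_p_new_events == pytest.approx(0.6)
    assert res.mean_p_old_nonevents == pytest.approx(0.2)


@settings(max_examples=100, derandomize=True)
@given(seed=st.integers(0, 10_000))
def test_idi_antisymmetric_and_representations_agree(seed):
    rng = np.random.default_rng(seed)
    n = 80
    pn, po = rng.random(n), rng.random(n)
    y = rng.random(n) < 0.35
    if not (y.any() and (~y).any()):
        return
    fwd = idi(pn, po, y)
    rev = idi(po, pn, y)
    assert fwd.idi == pytest.approx(-rev.idi, abs=1e-12)
    assert -2.0 <= fwd.idi <= 2.0
    # the IS/IP integral representation agrees with the group-mean form
    assert (fwd.is_new - fwd.is_old) - (fwd.ip_new - fwd.ip_old) == \
        pytest.approx(fwd.idi, abs=1e-8)


def test_idi_bootstrap_ci_brackets_estimate():
    rng = np.random.default_rng(21)
    n = 300
    y = rng.random(n) < 0.3
    po = np.clip(0.3 + 0.2 * y + 0.15 * rng.standard_normal(n), 0.01, 0.99)
    pn = np.clip(po + 0.05 * y + 0.05 * rng.standard_normal(n), 0.01, 0.99)
    res = idi(pn, po, y, ci_method="bootstrap", n_boot=500, seed=7)
    assert res.ci_low <= res.idi <= res.ci_high


def test_idi_validates_inputs():
    with pytest.raises(MetricError):
        idi([0.1], [0.1, 0.2], [True, False])
    with pytest.raises(MetricError):
        idi([0.1, 0.2], [0.1, 0.2], [True, True])


def test_chi_square_identical_rows_and_hand_example():
    chi2, df, p = chi_square_independence(np.array([[10, 30], [20, 60]]))
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    chi2, df, p = chi_square_independence(np.array([[10, 10], [20, 0]]))
    assert chi2 == pytest.approx(13.33, abs=5e-3)
    assert df == 1


def test_chi_square_niris_mortality_dependence():
    chi2, df, p = chi_square_independence(niris_outcome_crosstab())
    assert df == 4
    assert p < 0.01


def test_chi_square_zero_marginal_rejected():
    with pytest.raises(MetricError, match="marginal"):
        chi_square_independence(np.array([[0, 0], [5, 5]]))


def test_crosstab_validation():
    with pytest.raises(MetricError):
        CrossTab(labels=(0, 1), events=(1,), nonevents=(1, 2))
    with pytest.raises(MetricError):
        CrossTab(labels=(0,), events=(-1,), nonevents=(2,))
    t = niris_outcome_crosstab()
    assert t.n == 3031 and t.n_events == 710
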