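"""Survival kernels against hand-computed values and independent oracles."""

import warnings

import numpy as np
import pytest
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from lifelines.utils import concordance_index
from statsmodels.stats.multitest import multipletests
import pandas as pd

from mrix import survival
from mrix.exceptions import FitError, MRIxError


def _censored_sample(rng, n, lam=0.02, beta=None, X=None):
    lp = X @ beta if beta is not None else np.zeros(n)
    t = rng.exponential(1.0 / (lam * np.exp(lp)))
    c = rng.uniform(10, 80, n)
    return np.minimum(t, c), (t <= c).astype(int)


# ---------------------------------------------------------------------------
# Kaplan-Meier
# ---------------------------------------------------------------------------

def test_km_hand_example_all_events():
    km = survival.km_estimate([1.0, 2.0, 3.0], [1, 1, 1])
    assert np.allclose(km.survival, [2 / 3, 1 / 3, 0.0])
    # Greenwood at the first step: S^2 * d / (n (n - d))
    assert km.greenwood_var[0] == pytest.approx((2 / 3) ** 2 / 6)


def test_km_all_censored_is_flat():
    km = survival.km_estimate([5.0, 7.0, 9.0], [0, 0, 0])
    assert km.event_times.size == 0
    assert km.survival_at(100.0) == 1.0


def test_km_single_event():
    km = survival.km_estimate([1.0, 2.0, 3.0, 4.0], [1, 0, 0, 0])
    assert km.survival_at(1.0) == pytest.approx(1 - 1 / 4)


def test_km_no_censoring_equals_empirical(rng):
    t = rng.exponential(10, 300)
    km = survival.km_estimate(t, np.ones(300))
    for q in np.quantile(t, [0.1, 0.5, 0.9]):
        assert km.survival_at(q) == pytest.approx((t > q).mean(), abs=1e-12)


def test_km_matches_lifelines(rng):
    t, e = _censored_sample(rng, 200)
    km = survival.km_estimate(t, e)
    kmf = KaplanMeierFitter().fit(t, e)
    for q in np.quantile(t, [0.25, 0.5, 0.75]):
        assert km.survival_at(q) == pytest.approx(
            float(kmf.survival_function_at_times(q).iloc[0]), abs=1e-10
        )


def test_km_empty_rejected():
    with pytest.raises(MRIxError):
        survival.km_estimate([], [])


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------

def test_logrank_identical_groups_is_null():
    t = np.array([1.0, 2, 3, 4, 1, 2, 3, 4])
    e = np.array([1, 1, 0, 1, 1, 1, 0, 1])
    g = np.array([0, 0, 0, 0, 1, 1, 1, 1])
    chi2, df, p = survival.logrank_test(t, e, g)
    assert chi2 == pytest.approx(0.0, abs=1e-12)
    assert (df, p) == (1, 1.0)


def test_logrank_two_group_hand_computation():
    # group A: (1, event), (3, event); group B: (2, event), (4, censored)
    t = np.array([1.0, 3.0, 2.0, 4.0])
    e = np.array([1, 1, 1, 0])
    g = np.array(["A", "A", "B", "B"])
    chi2, df, p = survival.logrank_test(t, e, g)
    # O_A = 2, E_A = 1/2 + 1/3 + 1/2 = 4/3, V = 1/4 + 2/9 + 1/4 = 13/18
    assert chi2 == pytest.approx((2 - 4 / 3) ** 2 / (13 / 18), rel=1e-12)
    assert df == 1


def test_logrank_three_groups_matches_lifelines(rng):
    t, e = _censored_sample(rng, 120)
    g = rng.integers(0, 3, 120)
    chi2, df, p = survival.logrank_test(t, e, g)
    res = multivariate_logrank_test(t, g, e)
    assert chi2 == pytest.approx(res.test_statistic, rel=1e-9)
    assert p == pytest.approx(res.p_value, rel=1e-9)
    assert df == 2


def test_logrank_powered_detects_large_effect(rng):
    hits = 0
    for _ in range(20):
        n = 500
        x = rng.integers(0, 2, n)
        t, e = _censored_sample(rng, n, beta=np.array([np.log(4.0)]), X=x[:, None])
        hits += survival.logrank_test(t, e, x)[2] < 0.001
    assert hits >= 19


def test_logrank_single_group_rejected():
    with pytest.raises(MRIxError):
        survival.logrank_test([1.0, 2.0], [1, 1], ["a", "a"])


# ---------------------------------------------------------------------------
# Cox
# ---------------------------------------------------------------------------

def test_cox_null_design_loglik_bookkeeping(rng):
    t, e = _censored_sample(rng, 100)
    fit = survival.fit_cox(t, e, np.empty((100, 0)))
    assert fit.loglik == fit.loglik_null
    assert fit.aic == pytest.approx(-2 * fit.loglik)
    assert fit.k == 0


def test_cox_matches_lifelines_efron(rng):
    n = 400
    X = np.column_stack([rng.integers(0, 2, n), rng.normal(0, 1, n)]).astype(float)
    t, e = _censored_sample(rng, n, beta=np.array([0.7, -0.3]), X=X)
    t = np.round(t, 0) + 1.0  # force heavy ties to exercise Efron weights
    fit = survival.fit_cox(t, e, X)
    df = pd.DataFrame({"x0": X[:, 0], "x1": X[:, 1], "T": t, "E": e})
    cph = CoxPHFitter().fit(df, "T", "E")
    assert np.abs(fit.coef - cph.params_.values).max() < 1e-6
    assert np.abs(fit.se - cph.standard_errors_.values).max() < 1e-6
    assert fit.loglik == pytest.approx(cph.log_likelihood_, abs=1e-6)
    assert fit.aic == pytest.approx(cph.AIC_partial_, abs=1e-5)


def test_cox_recovers_simulated_hr(rng):
    n = 10_000
    x = rng.integers(0, 2, n).astype(float)
    t, e = _censored_sample(rng, n, lam=0.005, beta=np.array([np.log(2.0)]), X=x[:, None])
    fit = survival.fit_cox(t, e, x[:, None])
    assert abs(fit.coef[0] - np.log(2.0)) < 0.08
    lo, hi = fit.hr_ci[0]
    assert lo < 2.0 < hi


def test_cox_efron_equals_breslow_without_ties(rng):
    n = 150
    X = rng.normal(size=(n, 2))
    t, e = _censored_sample(rng, n, beta=np.array([0.5, 0.2]), X=X)
    assert np.unique(t).size == n  # continuous times: no ties
    fe = survival.fit_cox(t, e, X, ties="efron")
    fb = survival.fit_cox(t, e, X, ties="breslow")
    assert fe.loglik == pytest.approx(fb.loglik, abs=1e-8)
    assert np.allclose(fe.coef, fb.coef, atol=1e-6)


def test_cox_validation_errors(rng):
    t, e = _censored_sample(rng, 50)
    with pytest.raises(FitError, match="no events"):
        survival.fit_cox(t, np.zeros(50), np.ones((50, 1)) * np.arange(50)[:, None])
    with pytest.raises(FitError, match="constant"):
        survival.fit_cox(t, e, np.ones((50, 1)))
    x = np.arange(50.0)
    with pytest.raises(FitError, match="rank"):
        survival.fit_cox(t, e, np.column_stack([x, 2 * x]))


def test_cox_wald_ci_coverage(rng):
    """~95% of Wald intervals cover the generating log-HR over replicates."""
    beta = np.log(2.0)
    cover = 0
    reps = 200
    for _ in range(reps):
        n = 1000
        x = rng.integers(0, 2, n).astype(float)
        t, e = _censored_sample(rng, n, lam=0.01, beta=np.array([beta]), X=x[:, None])
        fit = survival.fit_cox(t, e, x[:, None])
        lo, hi = fit.hr_ci[0]
        cover += lo <= 2.0 <= hi
    assert 0.90 <= cover / reps <= 0.99


# ---------------------------------------------------------------------------
# Harrell's C
# ---------------------------------------------------------------------------

def test_c_perfect_ordering_no_censoring():
    t = np.array([1.0, 2.0, 3.0, 4.0])
    risk = np.array([4.0, 3.0, 2.0, 1.0])
    assert survival.harrell_c(risk, t, np.ones(4)) == 1.0


def test_c_constant_score_is_half(rng):
    t, e = _censored_sample(rng, 50)
    assert survival.harrell_c(np.zeros(50), t, e) == 0.5


@pytest.mark.parametrize("n", [20, 75, 200])
def test_c_fast_path_equals_pair_enumeration(rng, n):
    """Fenwick-tree path reproduces brute-force pair counts exactly,
    including tied times and tied scores."""
    for _ in range(10):
        t = np.round(rng.exponential(30, n)) + 1
        e = rng.integers(0, 2, n)
        if e.sum() == 0:
            e[0] = 1
        risk = rng.integers(0, 5, n).astype(float)
        assert survival._c_pairs_brute(risk, t, e) == survival._c_pairs_fast(risk, t, e)


def test_c_matches_lifelines_on_tie_free_data(rng):
    t, e = _censored_sample(rng, 300)
    risk = rng.normal(size=300)
    ours = survival.harrell_c(risk, t, e)
    theirs = concordance_index(t, -risk, e)
    assert ours == pytest.approx(theirs, abs=1e-12)


def test_c_no_usable_pairs_rejected():
    with pytest.raises(MRIxError):
        survival.harrell_c([1.0, 2.0], [5.0, 5.0], [1, 1])  # tied double event


# ---------------------------------------------------------------------------
# LRT / AIC
# ---------------------------------------------------------------------------

def test_lrt_model_vs_itself_null(rng):
    n = 100
    X = rng.normal(size=(n, 2))
    t, e = _censored_sample(rng, n)
    fit = survival.fit_cox(t, e, X, names=("a", "b"))
    chi2, df, p = survival.lrt(fit, fit)
    assert (chi2, df, p) == (0.0, 0, 1.0)


def test_lrt_strong_covariate_significant(rng):
    n = 1000
    x = rng.integers(0, 2, n).astype(float)
    t, e = _censored_sample(rng, n, lam=0.01, beta=np.array([1.2]), X=x[:, None])
    null = survival.fit_cox(t, e, np.empty((n, 0)))
    full = survival.fit_cox(t, e, x[:, None], names=("grp",))
    chi2, df, p = survival.lrt(null, full)
    assert df == 1 and p < 0.001
    assert full.aic == pytest.approx(-2 * full.loglik + 2)


def test_lrt_nonnegative_over_random_nested_fits(rng):
    for _ in range(25):
        n = 120
        X = rng.normal(size=(n, 3))
        t, e = _censored_sample(rng, n)
        nested = survival.fit_cox(t, e, X[:, :1], names=("a",))
        full = survival.fit_cox(t, e, X, names=("a", "b", "c"))
        chi2, df, p = survival.lrt(nested, full)
        assert chi2 >= 0.0 and df == 2


def test_lrt_non_nested_rejected(rng):
    n = 80
    X = rng.normal(size=(n, 2))
    t, e = _censored_sample(rng, n)
    f1 = survival.fit_cox(t, e, X[:, :1], names=("a",))
    f2 = survival.fit_cox(t, e, X[:, 1:], names=("b",))
    with pytest.raises(MRIxError, match="nested"):
        survival.lrt(f1, f2)


# ---------------------------------------------------------------------------
# Baseline hazard / prediction
# ---------------------------------------------------------------------------

def test_breslow_baseline_recovers_exponential(rng):
    n, lam = 10_000, 0.02
    t, e = _censored_sample(rng, n, lam=lam)
    fit = survival.fit_cox(t, e, np.empty((n, 0)))
    bl = survival.breslow_baseline(fit, t, e, np.empty((n, 0)))
    for q in (10.0, 25.0, 40.0):
        assert bl.at(q) == pytest.approx(lam * q, rel=0.05)


def test_predict_survival_properties(rng):
    n = 500
    x = rng.normal(size=(n, 1))
    t, e = _censored_sample(rng, n, beta=np.array([0.6]), X=x)
    fit = survival.fit_cox(t, e, x)
    bl = survival.breslow_baseline(fit, t, e, x)
    assert survival.predict_survival(bl, 0.0, 0.0) == 1.0
    s_low = survival.predict_survival(bl, -1.0, 30.0)
    s_high = survival.predict_survival(bl, 1.0, 30.0)
    assert s_high < s_low  # higher risk, lower survival
    with pytest.warns(UserWarning, match="extrapolat|exceeds"):
        survival.predict_survival(bl, 0.0, t.max() + 10)


# ---------------------------------------------------------------------------
# Hosmer-Lemeshow
# ---------------------------------------------------------------------------

def test_hl_group_validation(rng):
    t, e = _censored_sample(rng, 100)
    with pytest.raises(MRIxError):
        survival.hosmer_lemeshow_survival(np.full(100, 0.3), t, e, 36.0, n_groups=1)


def test_hl_df_bookkeeping(rng):
    n = 800
    lam = 0.01
    lp = rng.normal(0, 0.5, n)
    t = rng.exponential(1 / (lam * np.exp(lp)))
    c = rng.uniform(40, 80, n)
    tt, e = np.minimum(t, c), (t <= c).astype(int)
    pred = 1 - np.exp(-lam * np.exp(lp) * 36.0)
    cal = survival.hosmer_lemeshow_survival(pred, tt, e, 36.0, n_groups=10)
    assert cal.hl_df == len(cal.groups) - 2
    assert cal.groups["n"].sum() == n
    assert ((cal.groups["mean_predicted"] >= 0) & (cal.groups["mean_predicted"] <= 1)).all()


def test_hl_rejects_gross_miscalibration(rng):
    n = 2000
    lam = 0.01
    lp = rng.normal(0, 0.7, n)
    t = rng.exponential(1 / (lam * np.exp(lp)))
    c = rng.uniform(40, 80, n)
    tt, e = np.minimum(t, c), (t <= c).astype(int)
    pred = (1 - np.exp(-lam * np.exp(lp) * 36.0)) / 2.0  # systematically halved
    cal = survival.hosmer_lemeshow_survival(pred, tt, e, 36.0)
    assert cal.hl_p < 0.001


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_bh_hand_step_up():
    out = survival.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])


def test_bh_trivial_cases():
    assert survival.bh_adjust([0.37]) == pytest.approx([0.37])
    assert np.allclose(survival.bh_adjust([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])


def test_bh_matches_statsmodels(rng):
    p = rng.uniform(0, 1, 40)
    ours = survival.bh_adjust(p)
    theirs = multipletests(p, method="fdr_bh")[1]
    assert np.allclose(ours, theirs)


def test_bh_order_invariant(rng):
    p = rng.uniform(0, 1, 15)
    perm = rng.permutation(15)
    assert np.allclose(survival.bh_adjust(p)[perm], survival.bh_adjust(p[perm]))


def test_bh_invalid_rejected():
    with pytest.raises(MRIxError):
        survival.bh_adjust([0.5, 1.2])
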