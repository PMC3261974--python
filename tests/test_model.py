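"""The bilinear stunting model: beta percentiles, attribution, OLS fit,
prediction and holdout validation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stuntcast.development import calibrate_anchors, development_score
from stuntcast.model import (
    BetaEstimate,
    attribute_food,
    estimate_beta,
    fit_model,
    fit_nonfood,
    predict_stunting,
    ratio_distribution,
    residual_nonfood,
    validate_model,
)
from stuntcast.panel import CountryYearRecord, split_dataset
from stuntcast.synthetic import SyntheticConfig, generate_panel


def _rec(y2, x, y3=0.05, gdp=500.0, gini=0.4):
    return CountryYearRecord("C", "R", 2000, y2, y3, x, gdp, gini, 1e6)


# --- ratio distribution and beta ---------------------------------------


def test_ratio_distribution_divides_and_sorts():
    dist = ratio_distribution([_rec(0.2, 0.4), _rec(0.1, 0.5)], level=2)
    assert np.allclose(dist.ratios, [0.2, 0.5])
    assert dist.n_excluded == 0


def test_zero_undernourishment_records_are_excluded():
    dist = ratio_distribution([_rec(0.2, 0.4), _rec(0.1, 0.0)], level=2)
    assert len(dist.ratios) == 1 and dist.n_excluded == 1
    with pytest.raises(ValueError):
        ratio_distribution([_rec(0.2, 0.0)], level=2)


def test_model_generated_ratios_concentrate_near_beta():
    """When stunting is generated as y = 0.3 x + noise, the low percentiles
    of y/x sit near 0.3."""
    rng = np.random.default_rng(5)
    x = rng.uniform(0.2, 0.7, 500)
    y = np.clip(0.3 * x + rng.normal(0.0, 0.005, 500), 0.0, 1.0)
    panel = [_rec(yi, xi) for yi, xi in zip(y, x)]
    beta = estimate_beta(ratio_distribution(panel, 2), level=2)
    assert beta.central == pytest.approx(0.3, abs=0.03)
    assert beta.low < beta.central < beta.high


def _percentile_oracle(sorted_vals, q):
    # brute-force order-statistic interpolation: h = (n - 1) q, linear between
    h = (len(sorted_vals) - 1) * q / 100.0
    lo, hi = int(math.floor(h)), int(math.ceil(h))
    return sorted_vals[lo] + (h - lo) * (sorted_vals[hi] - sorted_vals[lo])


def test_beta_percentiles_match_order_statistic_oracle():
    ratios = np.arange(1, 101) / 100.0  # 0.01 ... 1.00
    beta = estimate_beta(ratios, level=2)
    for attr, q in (("low", 1), ("central", 5), ("high", 10)):
        assert getattr(beta, attr) == pytest.approx(_percentile_oracle(ratios, q), rel=1e-12)
    rng = np.random.default_rng(17)
    for _ in range(5):
        r = np.sort(rng.uniform(0.05, 1.0, rng.integers(5, 60)))
        b = estimate_beta(r, level=3)
        assert b.central == pytest.approx(_percentile_oracle(r, 5), rel=1e-12)


def test_zero_percentiles_reduce_to_the_minimum_ratio():
    beta = estimate_beta(np.sort([0.5, 0.4, 0.3, 0.2, 0.6]), level=2,
                         percentiles=(0.0, 0.0, 0.0))
    assert beta.central == 0.2 and beta.low == 0.2 and beta.high == 0.2


def test_beta_needs_at_least_two_ratios():
    with pytest.raises(ValueError):
        estimate_beta(np.array([0.3]), level=2)
    with pytest.raises(ValueError):
        BetaEstimate(level=2, central=0.3, low=0.4, high=0.5, n_ratios=10)


# --- attribution -------------------------------------------------------


@pytest.mark.parametrize("beta, x, expected", [
    (0.35, 0.01, 0.0035),
    (0.35, 0.0, 0.0),
    (0.18, 0.5, 0.09),
])
def test_food_attribution_is_beta_times_x(beta, x, expected):
    assert attribute_food(beta, x) == pytest.approx(expected, rel=1e-12)


def test_residual_is_the_exact_complement():
    assert residual_nonfood(0.23, 0.077) == pytest.approx(0.153)
    assert residual_nonfood(0.1, 0.1) == 0.0
    assert residual_nonfood(0.05, 0.08) == pytest.approx(-0.03)  # retained, not truncated


@settings(deadline=None, max_examples=100)
@given(beta=st.floats(0.01, 1.0), x=st.floats(0.0, 1.0), y=st.floats(0.0, 1.0))
def test_attribution_reconstructs_observed_stunting(beta, x, y):
    """r + s = y exactly, for any record: the stepwise split conserves stunting."""
    r = attribute_food(beta, x)
    assert r + residual_nonfood(y, r) == pytest.approx(y, abs=1e-15)


# --- nonfood fit -------------------------------------------------------


def test_noiseless_surface_is_recovered_exactly(noiseless_panel):
    records, truth = noiseless_panel
    anchors = truth.anchors
    params = fit_nonfood(records, truth.params.moderate.beta, truth.params.severe.beta, anchors)
    for k in (2, 3):
        est, true = params.level(k), truth.params.level(k)
        assert est.alpha.value == pytest.approx(true.alpha.value, abs=1e-10)
        assert est.gamma.value == pytest.approx(true.gamma.value, abs=1e-10)
        assert est.theta.value == pytest.approx(true.theta.value, abs=1e-10)


def test_fit_matches_normal_equations_oracle():
    """On random small designs the OLS step equals a hand-rolled
    normal-equations solve."""
    rng = np.random.default_rng(23)
    for _ in range(5):
        n = int(rng.integers(8, 20))
        recs = [_rec(float(rng.uniform(0.05, 0.4)), float(rng.uniform(0.1, 0.7)),
                     y3=float(rng.uniform(0.02, 0.3)),
                     gdp=float(rng.uniform(100, 5000)), gini=float(rng.uniform(0.2, 0.7)))
                for _ in range(n)]
        anchors = calibrate_anchors(recs)
        beta = BetaEstimate(level=2, central=0.3, low=0.2, high=0.4, n_ratios=n)
        beta3 = BetaEstimate(level=3, central=0.15, low=0.1, high=0.2, n_ratios=n)
        params = fit_nonfood(recs, beta, beta3, anchors)
        w = np.array([development_score(r.gdp_pc, r.gini, anchors) for r in recs])
        x = np.array([r.pou for r in recs])
        for k, b in ((2, beta), (3, beta3)):
            y = np.array([r.stunting_moderate if k == 2 else r.stunting_severe for r in recs])
            X = np.column_stack([np.ones(n), w, x * w])
            coef = np.linalg.solve(X.T @ X, X.T @ (y - b.central * x))
            est = params.level(k)
            assert est.alpha.value == pytest.approx(coef[0], abs=1e-8)
            assert est.gamma.value == pytest.approx(coef[1], abs=1e-8)
            assert est.theta.value == pytest.approx(coef[2], abs=1e-8)


def test_rank_deficient_design_is_fatal():
    recs = [_rec(0.2, 0.3, gdp=20000.0, gini=0.1) for _ in range(10)]  # w constant at 0
    anchors = calibrate_anchors([_rec(0.2, 0.3, gdp=100.0, gini=0.5)] + recs)
    beta = BetaEstimate(level=2, central=0.3, low=0.2, high=0.4, n_ratios=10)
    beta3 = BetaEstimate(level=3, central=0.15, low=0.1, high=0.2, n_ratios=10)
    with pytest.raises(ValueError, match="rank deficient"):
        fit_nonfood(recs, beta, beta3, anchors)


def test_betas_pass_through_the_fit_unchanged(default_panel):
    records, truth = default_panel
    params = fit_nonfood(records, truth.params.moderate.beta,
                         truth.params.severe.beta, truth.anchors)
    assert params.moderate.beta == truth.params.moderate.beta
    assert params.severe.beta == truth.params.severe.beta


# --- prediction --------------------------------------------------------


def test_prediction_worked_example(table_params):
    y1, y2, y3 = predict_stunting(table_params, x=0.2, w=0.5)
    assert y2 == pytest.approx(0.182, abs=1e-12)
    assert y3 == pytest.approx(0.136, abs=1e-12)
    assert y1 == pytest.approx(0.682, abs=1e-12)


def test_prediction_at_origin_returns_intercepts(table_params):
    _, y2, y3 = predict_stunting(table_params, x=0.0, w=0.0)
    assert y2 == table_params.moderate.alpha.value
    assert y3 == table_params.severe.alpha.value


@settings(deadline=None, max_examples=100)
@given(x=st.floats(0.0, 1.0), w=st.floats(0.0, 1.0))
def test_levels_sum_to_one_by_construction(table_params, x, w):
    y1, y2, y3 = predict_stunting(table_params, x, w)
    assert y1 + y2 + y3 == pytest.approx(1.0, abs=1e-12)


def test_worsening_conditions_shift_moderate_into_severe(table_params):
    """There are (x, w) regions where a worse development score lowers
    moderate stunting while raising severe stunting — the moderate-to-severe
    shift the fitted surface implies."""
    found = False
    for x in np.linspace(0.0, 1.0, 21):
        for w in np.linspace(0.0, 0.95, 20):
            _, y2a, y3a = predict_stunting(table_params, x, w)
            _, y2b, y3b = predict_stunting(table_params, x, w + 0.05)
            if y2b < y2a and y3b > y3a:
                found = True
                break
        if found:
            break
    assert found


# --- validation --------------------------------------------------------


def _surface_panel(params, anchors, n=40, seed=3):
    rng = np.random.default_rng(seed)
    recs = []
    for i in range(n):
        gdp, gini = float(rng.uniform(100, 5000)), float(rng.uniform(0.2, 0.7))
        x = float(rng.uniform(0.05, 0.6))
        w = development_score(gdp, gini, anchors)
        _, y2, y3 = predict_stunting(params, x, w)
        recs.append(CountryYearRecord(f"C{i}", "R", 2000, y2, y3, x, gdp, gini, 1e6))
    return recs


def test_perfect_holdout_gives_unit_correlations(default_panel):
    _, truth = default_panel
    holdout = _surface_panel(truth.params, truth.anchors)
    report = validate_model(truth.params, holdout, truth.anchors)
    for k in (1, 2, 3):
        assert report.corr[k] == pytest.approx(1.0, abs=1e-9)
    assert report.undefined == ()


def test_shuffled_observations_decorrelate(default_panel):
    _, truth = default_panel
    holdout = _surface_panel(truth.params, truth.anchors, n=37, seed=4)
    rng = np.random.default_rng(8)
    obs = [(r.stunting_moderate, r.stunting_severe) for r in holdout]
    perm = rng.permutation(len(obs))
    shuffled = [
        CountryYearRecord(r.country_id, r.region_id, r.year, obs[perm[i]][0],
                          obs[perm[i]][1], r.pou, r.gdp_pc, r.gini, r.pop_u5)
        for i, r in enumerate(holdout)
    ]
    report = validate_model(truth.params, shuffled, truth.anchors)
    assert abs(report.corr[2]) < 0.3 and abs(report.corr[3]) < 0.3


def test_zero_variance_flags_undefined_correlation(default_panel):
    _, truth = default_panel
    holdout = [_rec(0.2, 0.3) for _ in range(5)]  # identical observations
    report = validate_model(truth.params, holdout, truth.anchors)
    assert 1 in report.undefined and math.isnan(report.corr[1])


def test_full_pipeline_recovers_the_generating_surface():
    """End-to-end: the percentile beta lands inside its generating band,
    the regression step recovers (alpha, gamma, theta) within 2 SE when
    the attribution uses the generating beta, and the fully estimated
    pipeline predicts the holdout well. (An error in the estimated beta
    propagates into alpha by construction of the stepwise attribution,
    so parameter recovery is judged at the generating beta.)"""
    records, truth = generate_panel(SyntheticConfig(seed=19))
    fit = fit_model(records, holdout_fraction=0.2, seed=19)
    for k in (2, 3):
        est, true = fit.params.level(k), truth.params.level(k)
        assert true.beta.low <= est.beta.central <= true.beta.high
    train, _ = split_dataset(records, 0.2, seed=19)
    refit = fit_nonfood(train, truth.params.moderate.beta,
                        truth.params.severe.beta, truth.anchors)
    for k in (2, 3):
        for name in ("alpha", "gamma", "theta"):
            e = getattr(refit.level(k), name)
            t = getattr(truth.params.level(k), name)
            assert abs(e.value - t.value) <= 2 * e.se
    # holdout correlations are strong when the generator matches the model
    assert all(fit.validation.corr[k] > 0.5 for k in (1, 2, 3))
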