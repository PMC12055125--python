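"""Lag bases, DLM reductions to known regressions, window extraction."""

import numpy as np
import pandas as pd
import pytest
from scipy.interpolate import CubicSpline

from gestwin import assoc, dlm, synth


# ---------------------------------------------------------------------------
# bases

def test_degree_zero_is_single_constant_column():
    b = dlm.build_lag_basis("polynomial", 0)
    assert b.matrix.shape == (48, 1)
    assert np.allclose(b.matrix, 1.0)


def test_degree_two_basis_has_rank_three():
    b = dlm.build_lag_basis("polynomial", 2)
    assert b.matrix.shape == (48, 3)
    assert np.linalg.matrix_rank(b.matrix) == 3


def test_spline_basis_spans_natural_cubics():
    # a natural cubic interpolant on the same knots must lie in the span
    df = 4
    b = dlm.build_lag_basis("natural_cubic_spline", df)
    lag = np.arange(1, 49, dtype=float)
    knots = np.concatenate([[1.0], np.quantile(lag, np.linspace(0, 1, df)[1:-1]),
                            [48.0]])
    rng = np.random.default_rng(0)
    for _ in range(5):
        cs = CubicSpline(knots, rng.normal(0, 1, len(knots)), bc_type="natural")
        target = cs(lag)
        coef, res, *_ = np.linalg.lstsq(b.matrix, target, rcond=None)
        assert np.allclose(b.matrix @ coef, target, atol=1e-8)


def test_out_of_range_orders_rejected():
    with pytest.raises(ValueError):
        dlm.build_lag_basis("polynomial", 7)
    with pytest.raises(ValueError):
        dlm.build_lag_basis("natural_cubic_spline", 9)
    with pytest.raises(ValueError):
        dlm.build_lag_basis("fourier", 3)


# ---------------------------------------------------------------------------
# fit reductions

def _iid_world(n=200, seed=1, beta_l=None, noise=1.0):
    rng = np.random.default_rng(seed)
    x = rng.normal(20, 5, (n, 48))
    y = rng.normal(0, noise, n)
    if beta_l is not None:
        y = y + x @ beta_l
    return x, y


def test_degree_zero_equals_cumulative_exposure_regression():
    x, y = _iid_world()
    fit = dlm.fit_dlm(y, x, None, dlm.build_lag_basis("polynomial", 0))
    s = x.sum(axis=1)
    m = np.column_stack([np.ones(len(y)), s])
    slope = np.linalg.solve(m.T @ m, m.T @ y)[1]
    assert np.allclose(fit.theta, slope * 10.0, atol=1e-8)
    assert np.ptp(fit.theta) == 0.0


def test_theta_is_exactly_basis_times_eta():
    x, y = _iid_world(seed=2)
    fit = dlm.fit_dlm(y, x, None, dlm.build_lag_basis("polynomial", 3))
    assert np.array_equal(fit.theta, (fit.basis.matrix @ fit.eta) * 10.0)
    assert (np.einsum("ij,jk,ik->i", fit.basis.matrix, fit.cov_eta,
                      fit.basis.matrix) >= 0).all()


def test_identity_basis_recovers_per_week_ols_on_orthogonal_fixture():
    rng = np.random.default_rng(3)
    raw = rng.normal(0, 1, (200, 48))
    q, _ = np.linalg.qr(raw - raw.mean(axis=0))
    x = q[:, :48]  # orthonormal zero-mean weekly exposures
    beta_l = rng.normal(0, 0.5, 48)
    y = x @ beta_l + rng.normal(0, 0.1, 200)
    identity = dlm.LagBasis("identity", 48, np.eye(48))
    fit = dlm.fit_dlm(y, x, None, identity)
    per_week = np.array([x[:, l] @ y / (x[:, l] @ x[:, l]) for l in range(48)])
    assert np.allclose(fit.theta, per_week * 10.0, atol=1e-8)


def test_pointwise_ci_coverage_under_null():
    cover = []
    for s in range(300):
        x, y = _iid_world(n=150, seed=500 + s)
        fit = dlm.fit_dlm(y, x, None, dlm.build_lag_basis("polynomial", 3))
        cover.append(((fit.ci_low <= 0) & (0 <= fit.ci_high)).mean())
    assert np.mean(cover) >= 0.92


def test_too_small_sample_rejected():
    x, y = _iid_world(n=20)
    with pytest.raises(ValueError, match="complete participants"):
        dlm.fit_dlm(y, x, np.ones((20, 15)), dlm.build_lag_basis("polynomial", 4))


def test_missing_weeks_drop_participants():
    x, y = _iid_world(n=100, seed=4)
    x[3, 7] = np.nan
    x[11, 40] = np.nan
    fit = dlm.fit_dlm(y, x, None, dlm.build_lag_basis("polynomial", 2))
    assert fit.n == 98 and fit.n_dropped == 2


# ---------------------------------------------------------------------------
# selection

def test_quadratic_truth_selects_degree_at_least_two():
    lag = np.arange(1, 49)
    z = (lag - lag.mean()) / lag.std()
    beta_l = 0.02 * (z ** 2 - 0.5)
    chosen = []
    for s in range(100):
        x, y = _iid_world(n=200, seed=2000 + s, beta_l=beta_l, noise=0.5)
        fit = dlm.select_basis(y, x, None,
                               [("polynomial", o) for o in (1, 2, 3, 4)])
        chosen.append(fit.basis.order)
    assert np.mean(np.array(chosen) >= 2) >= 0.90


def test_true_basis_beats_misspecified_smaller_one_on_average():
    lag = np.arange(1, 49)
    z = (lag - lag.mean()) / lag.std()
    beta_l = 0.02 * (z ** 2 - 0.5)
    aic1, aic2 = [], []
    for s in range(40):
        x, y = _iid_world(n=200, seed=4000 + s, beta_l=beta_l, noise=0.5)
        aic1.append(dlm.fit_dlm(y, x, None, dlm.build_lag_basis("polynomial", 1)).aic)
        aic2.append(dlm.fit_dlm(y, x, None, dlm.build_lag_basis("polynomial", 2)).aic)
    assert np.mean(aic2) < np.mean(aic1)


def test_duplicate_candidates_first_returned():
    x, y = _iid_world(seed=5)
    fit = dlm.select_basis(y, x, None, [("polynomial", 2), ("polynomial", 2)])
    assert fit.basis.order == 2
    assert len(fit.selection_log) == 2


def test_single_candidate_returned_unconditionally():
    x, y = _iid_world(seed=6)
    fit = dlm.select_basis(y, x, None, [("polynomial", 1)])
    assert fit.basis.order == 1


# ---------------------------------------------------------------------------
# window extraction

def _fit_with_theta(theta, se):
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    return dlm.DLMFit(basis=dlm.LagBasis("identity", len(theta), np.eye(len(theta))),
                      eta=theta / 10.0, cov_eta=np.eye(len(theta)),
                      theta=theta, se_theta=se,
                      ci_low=theta - 1.96 * se, ci_high=theta + 1.96 * se,
                      aic=0.0, n=1000, n_dropped=0, df_resid=970)


def test_all_cis_covering_zero_yield_empty_summary():
    fit = _fit_with_theta(np.zeros(48), np.ones(48))
    assert dlm.extract_windows(fit).runs == []


def test_isolated_significant_weeks_become_unit_runs():
    theta = np.zeros(48)
    se = np.ones(48)
    theta[4] = 5.0   # week 5
    theta[6] = -5.0  # week 7
    se[4] = se[6] = 0.1
    runs = dlm.extract_windows(_fit_with_theta(theta, se)).runs
    assert [(r.start_week, r.end_week, r.sign) for r in runs] == [
        (5, 5, 1), (7, 7, -1)]


def test_run_segmentation_and_peaks():
    theta = np.zeros(48)
    se = np.full(48, 0.1)
    theta[33:44] = -np.linspace(0.5, 1.5, 11)  # unified weeks 34-44
    runs = dlm.extract_windows(_fit_with_theta(theta, se)).runs
    assert len(runs) == 1
    r = runs[0]
    assert (r.start_week, r.end_week, r.sign) == (34, 44, -1)
    assert r.peak_week == 44
    assert r.pregnancy_weeks == (21, 31)


def test_preconception_only_run_has_no_pregnancy_weeks():
    theta = np.zeros(48)
    se = np.full(48, 0.1)
    theta[2:5] = 1.0
    r = dlm.extract_windows(_fit_with_theta(theta, se)).runs[0]
    assert r.pregnancy_weeks is None


# ---------------------------------------------------------------------------
# full-term restriction

def test_full_term_threshold_is_inclusive():
    df = pd.DataFrame({"participant_id": ["a", "b", "c"],
                       "ga_weeks": [37.0, 36.9, 40.0]})
    out = dlm.full_term_restrict(df)
    assert list(out["participant_id"]) == ["a", "c"]
    with pytest.raises(ValueError, match="full-term"):
        dlm.full_term_restrict(df[df["ga_weeks"] < 37])


def test_no_preterm_cohort_unchanged():
    df = pd.DataFrame({"participant_id": list("abc"),
                       "ga_weeks": [38.0, 39.0, 41.0]})
    pd.testing.assert_frame_equal(dlm.full_term_restrict(df), df)


# ---------------------------------------------------------------------------
# window recovery power

def test_window_detection_power_nondecreasing_in_effect_size():
    rates = []
    for gamma in (-0.5, -1.5, -3.0):
        hits = 0
        n_sim = 40
        for s in range(n_sim):
            x, cov, y = synth.simulate_weekly_cohort(150, gamma, (34, 44),
                                                     seed=6000 + s)
            design = assoc.build_covariate_design(cov).to_numpy()
            fit = dlm.select_basis(y, x, design,
                                   [("polynomial", o) for o in (1, 2, 3, 4)])
            runs = dlm.extract_windows(fit).runs
            hits += any(r.sign == -1 and r.start_week <= 44 and r.end_week >= 34
                        for r in runs)
        rates.append(hits / n_sim)
    assert rates[0] <= rates[1] + 0.05 <= rates[2] + 0.10
    assert rates[2] >= 0.9
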