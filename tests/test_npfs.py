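"""Nested particle filter and backward smoother."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import cfdyn as c
from cfdyn.npfs import (
    FilterConfig,
    FilterHistory,
    backward_smooth,
    initialize_ensemble,
    multinomial_indices,
    point_estimates,
    systematic_indices,
)
from _oracles import (
    filtered_means_from_history,
    inner_ess,
    kalman_rts,
    make_ar1_system,
    simulate_ar1,
)


# ---------------------------------------------------------------------------
# initialization and resampling
# ---------------------------------------------------------------------------

def test_initialization_prior_support_and_determinism(logistic_system):
    cfg = FilterConfig(M=30, N=20, seed=123)
    noise = c.NoiseConfig(sigma_u=0.01, sigma_w=1.0)
    a = initialize_ensemble(logistic_system, cfg, [10.0], noise)
    b = initialize_ensemble(logistic_system, cfg, [10.0], noise)
    low, high = logistic_system.prior_bounds.T
    assert np.all(a.theta >= low) and np.all(a.theta <= high)
    assert a.theta.shape == (30, 2) and a.states.shape == (30, 20, 1)
    np.testing.assert_array_equal(a.theta, b.theta)
    np.testing.assert_array_equal(a.states, b.states)
    # state prior anchors on the first observation
    assert abs(a.states.mean() - 10.0) < 0.5


@pytest.mark.parametrize("picker", [systematic_indices, multinomial_indices])
def test_resampling_unbiased(picker):
    weights = np.array([0.5, 0.3, 0.15, 0.05])
    rng = np.random.default_rng(0)
    R = 10_000
    counts = np.zeros((R, 4))
    for r in range(R):
        idx = picker(weights, rng)
        counts[r] = np.bincount(idx, minlength=4)
    mean = counts.mean(axis=0)
    se = counts.std(axis=0) / np.sqrt(R)
    assert np.all(np.abs(mean - 4 * weights) <= 3 * se + 1e-9)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    raw=st.lists(st.floats(min_value=0.01, max_value=10.0), min_size=2, max_size=30)
)
def test_systematic_counts_within_one_of_expectation(raw):
    """Systematic resampling never misallocates a particle by >= 1 copy."""
    w = np.array(raw)
    w /= w.sum()
    idx = systematic_indices(w, np.random.default_rng(5))
    counts = np.bincount(idx, minlength=len(w))
    assert np.all(np.abs(counts - len(w) * w) < 1.0 + 1e-9)


# ---------------------------------------------------------------------------
# filter runs
# ---------------------------------------------------------------------------

def test_weight_normalization_invariants(logistic_pipeline):
    hist = logistic_pipeline["est"].history_
    np.testing.assert_allclose(
        hist.inner_weights.sum(axis=2), 1.0, atol=1e-12
    )
    np.testing.assert_allclose(hist.outer_weights.sum(axis=1), 1.0, atol=1e-12)
    assert np.all(hist.inner_weights >= 0) and np.all(hist.outer_weights >= 0)
    se = logistic_pipeline["se"]
    np.testing.assert_allclose(
        se.smoothed_weights.sum(axis=(1, 2)), 1.0, atol=1e-10
    )


def test_jitter_containment_and_zero_jitter(logistic_system):
    noise = c.NoiseConfig(sigma_u=0.01, sigma_w=1.0)
    integ = logistic_system.default_integ
    real = c.simulate_ssm(
        logistic_system, logistic_system.theta_true, [10.0], 40, noise, integ,
        seed=0,
    )
    est = c.NestedParticleSmoother(
        system=logistic_system, M=8, N=10, jitter_scale=0.0,
        sigma_u=0.01, sigma_w=1.0, delta=integ.delta, substeps=integ.substeps,
        smooth=False, seed=1,
    ).fit(real.obs)
    hist = est.history_
    # without jitter, theta values never leave the initial multiset
    init = set(np.round(hist.theta[0].ravel(), 12))
    assert set(np.round(hist.theta.ravel(), 12)) <= init

    est2 = c.NestedParticleSmoother(
        system=logistic_system, M=8, N=10, jitter_scale=0.2,
        sigma_u=0.01, sigma_w=1.0, delta=integ.delta, substeps=integ.substeps,
        smooth=False, seed=1,
    ).fit(real.obs)
    low, high = logistic_system.prior_bounds.T
    assert np.all(est2.history_.theta >= low) and np.all(est2.history_.theta <= high)


def test_history_shapes(logistic_pipeline):
    hist = logistic_pipeline["est"].history_
    T, M, N = 300, 10, 30
    assert hist.theta.shape == (T + 1, M, 2)
    assert hist.states.shape == (T + 1, M, N, 1)
    assert hist.inner_weights.shape == (T + 1, M, N)
    assert hist.outer_weights.shape == (T + 1, M)
    assert hist.T == T


def test_fixed_theta_bootstrap_reduction(logistic_system):
    """M=1 with pinned parameters is a plain bootstrap particle filter."""
    noise = c.NoiseConfig(sigma_u=0.01, sigma_w=1.0)
    integ = logistic_system.default_integ
    real = c.simulate_ssm(
        logistic_system, logistic_system.theta_true, [10.0], 60, noise, integ,
        seed=2,
    )
    est = c.NestedParticleSmoother(
        system=logistic_system, M=1, N=200, fixed_theta=logistic_system.theta_true,
        sigma_u=0.01, sigma_w=1.0, delta=integ.delta, substeps=integ.substeps,
        smooth=False, seed=3,
    ).fit(real.obs)
    hist = est.history_
    assert np.all(hist.theta == logistic_system.theta_true)
    assert np.all(hist.outer_weights == 1.0)
    # the filter tracks the hidden state
    err = np.abs(est.state_mean_[:, 0] - real.hidden[:, 0])
    assert err.mean() < 3 * np.sqrt(noise.sigma_w)


def test_sigma_w_zero_rejected(logistic_system):
    with pytest.raises(c.DegenerateLikelihoodError):
        c.NestedParticleSmoother(
            system=logistic_system, sigma_u=0.01, sigma_w=0.0
        ).fit(np.ones((5, 1)))


def test_sklearn_params_roundtrip(logistic_system):
    est = c.NestedParticleSmoother(system="logistic", M=7, seed=3)
    params = est.get_params()
    assert params["M"] == 7 and params["seed"] == 3
    est.set_params(N=13)
    assert est.N == 13


# ---------------------------------------------------------------------------
# point estimates and smoothing boundary conditions
# ---------------------------------------------------------------------------

def _singleton_history(outer_weights, thetas):
    """T=0 history with N=1 state particles, for hand-checking moments."""
    M = len(outer_weights)
    return FilterHistory(
        theta=np.asarray(thetas, float)[None, :, None],
        states=np.zeros((1, M, 1, 1)),
        inner_weights=np.ones((1, M, 1)),
        outer_weights=np.asarray(outer_weights, float)[None, :],
        outer_anc=np.arange(M)[None, :],
        inner_anc=np.zeros((1, M, 1), dtype=int),
        config=FilterConfig(M=M, N=1),
        noise=c.NoiseConfig(1.0, 1.0),
        integ=c.IntegratorConfig(),
    )


def test_point_estimates_hand_weighted_moments(logistic_system):
    hist = _singleton_history([0.25, 0.75], [2.0, 4.0])
    se = backward_smooth(
        hist, make_ar1_system(0.9), c.NoiseConfig(1.0, 1.0), c.IntegratorConfig()
    )
    theta_hat, sigma_theta, state_mean = point_estimates(se)
    assert theta_hat[0] == pytest.approx(3.5)
    assert sigma_theta[0] == pytest.approx(np.sqrt(0.75))
    assert state_mean.shape == (1, 1)


def test_point_estimates_degenerate_cases():
    one = backward_smooth(
        _singleton_history([1.0], [2.5]),
        make_ar1_system(0.9), c.NoiseConfig(1.0, 1.0), c.IntegratorConfig(),
    )
    assert one.sigma_theta[0] == 0.0
    equal = backward_smooth(
        _singleton_history([0.5, 0.5], [2.0, 4.0]),
        make_ar1_system(0.9), c.NoiseConfig(1.0, 1.0), c.IntegratorConfig(),
    )
    assert equal.theta_hat[0] == pytest.approx(3.0)  # arithmetic mean


def test_smoothed_weights_at_T_equal_filtered(logistic_pipeline):
    se = logistic_pipeline["se"]
    hist = logistic_pipeline["est"].history_
    expected = hist.outer_weights[-1][:, None] * hist.inner_weights[-1]
    np.testing.assert_allclose(se.smoothed_weights[-1], expected, atol=1e-12)


# ---------------------------------------------------------------------------
# linear-Gaussian oracle (small version; the full-size one is an acceptance test)
# ---------------------------------------------------------------------------

def test_filter_smoother_match_kalman_rts_small():
    a, su, sw, T, N = 0.9, 1.0, 1.0, 25, 800
    system = make_ar1_system(a)
    x, y = simulate_ar1(a, su, sw, T, seed=0)
    mf, Pf, ms, Ps = kalman_rts(y, a, su, sw, m0=y[0], P0=sw)
    est = c.NestedParticleSmoother(
        system=system, M=1, N=N, sigma_u=su, sigma_w=sw,
        fixed_theta=[a], seed=100,
    ).fit(y[:, None])
    filt = filtered_means_from_history(est.history_)[:, 0]
    zf = np.abs(filt - mf) / np.sqrt(Pf / inner_ess(est.history_.inner_weights[:, 0, :]))
    assert zf.max() < 3.0
    sm = est.ensemble_.state_mean[:, 0]
    ess_s = inner_ess(est.ensemble_.smoothed_weights.reshape(T + 1, -1))
    zs = np.abs(sm - ms) / np.sqrt(Ps / ess_s)
    assert zs.max() < 3.0
    # smoothing on average improves on filtering
    assert np.mean(np.abs(sm - x)) <= np.mean(np.abs(filt - x))


def test_sigma_u_zero_ancestral_fallback():
    """With a degenerate transition the smoother falls back to lineage weights."""
    a, T, N = 0.9, 15, 50
    system = make_ar1_system(a)
    rng = np.random.default_rng(1)
    x = np.zeros(T + 1)
    for t in range(1, T + 1):
        x[t] = a * x[t - 1]
    y = x + rng.standard_normal(T + 1)
    est = c.NestedParticleSmoother(
        system=system, M=1, N=N, sigma_u=0.0, sigma_w=1.0,
        fixed_theta=[a], seed=4,
    ).fit(y[:, None])
    w = est.ensemble_.smoothed_weights
    np.testing.assert_allclose(w.sum(axis=(1, 2)), 1.0, atol=1e-10)
    assert np.all(w >= 0)
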