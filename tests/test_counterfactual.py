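"""Counterfactual SCM construction and trajectory sampling."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

import cfdyn as c
from cfdyn.npfs import SmoothedEnsemble


def _dummy_ensemble(theta_hat, sigma_theta):
    """Minimal smoothed ensemble carrying only the parameter posterior."""
    p = len(theta_hat)
    return SmoothedEnsemble(
        states=np.zeros((1, 1, 1, 1)),
        thetas=np.zeros((1, 1, p)),
        parents=np.zeros((1, 1, 1), dtype=int),
        smoothed_weights=np.ones((1, 1, 1)),
        outer_weights=np.ones(1),
        theta_hat=np.asarray(theta_hat, float),
        sigma_theta=np.asarray(sigma_theta, float),
        state_mean=np.zeros((1, 1)),
        history=None,
    )


def _flat_noise(T, d, mu=0.0, sigma2=0.0):
    return c.NoisePosterior(
        mu=np.full((T, d), mu), sigma2=np.full((T, d), sigma2)
    )


def test_theta_mode_true_uses_true_parameters(logistic_system):
    spec = c.CFSpec(delta=10.0, theta_mode="true", n_samples=8, T=20, seed=0)
    model = c.build_cf_model(
        _flat_noise(20, 1), None, logistic_system, spec, [10.0],
        theta_true=logistic_system.theta_true,
    )
    cf = c.sample_cf_trajectories(model, spec, logistic_system.default_integ)
    assert np.all(cf.thetas_used == logistic_system.theta_true)


def test_intervention_shifts_initial_state(logistic_system):
    spec = c.CFSpec(delta=10.0, j=0, theta_mode="true", n_samples=5, T=10, seed=1)
    model = c.build_cf_model(
        _flat_noise(10, 1), None, logistic_system, spec, [10.0],
        theta_true=logistic_system.theta_true,
    )
    cf = c.sample_cf_trajectories(model, spec, logistic_system.default_integ)
    assert np.all(cf.trajectories[:, 0, 0] == 20.0)
    # delta = 0 is the null intervention
    null = c.CFSpec(delta=0.0, theta_mode="true", n_samples=2, T=10, seed=1)
    with pytest.raises(ValueError):
        c.CFSpec(delta=1.0, j=-1)
    model0 = c.build_cf_model(
        _flat_noise(10, 1), None, logistic_system, null, [10.0],
        theta_true=logistic_system.theta_true,
    )
    assert model0.x0_cf[0] == 10.0


def test_null_intervention_with_null_noise_is_factual_bitwise(lorenz_system):
    """delta=0 and mu=sigma=0 reproduce the noise-free factual run exactly."""
    integ = lorenz_system.default_integ
    T = 100
    spec = c.CFSpec(delta=0.0, theta_mode="true", n_samples=3, T=T, seed=2)
    model = c.build_cf_model(
        _flat_noise(T, 3), None, lorenz_system, spec, [1.0, 1.0, 1.0],
        theta_true=lorenz_system.theta_true,
    )
    cf = c.sample_cf_trajectories(model, spec, integ)
    factual = c.propagate_deterministic(
        lorenz_system, lorenz_system.theta_true, [1.0, 1.0, 1.0], T, integ
    )
    for k in range(3):
        np.testing.assert_array_equal(cf.trajectories[k], factual)


def test_posterior_mode_with_zero_spread_equals_point(logistic_system):
    se = _dummy_ensemble([3.5, 1.05], [0.0, 0.0])
    T = 30
    out = {}
    for mode in ("point", "posterior"):
        spec = c.CFSpec(delta=10.0, theta_mode=mode, n_samples=6, T=T, seed=3)
        model = c.build_cf_model(
            _flat_noise(T, 1, sigma2=0.001), se, logistic_system, spec, [10.0]
        )
        out[mode] = c.sample_cf_trajectories(
            model, spec, logistic_system.default_integ
        )
    np.testing.assert_array_equal(
        out["point"].trajectories, out["posterior"].trajectories
    )


def test_mode_nesting_statistically_indistinguishable(logistic_system):
    """With sigma_theta -> 0 and theta_hat -> theta_true the three regimes agree.

    Kolmogorov-Smirnov on the final-state marginals at alpha = 0.01.
    """
    se = _dummy_ensemble(logistic_system.theta_true, [1e-9, 1e-9])
    T, K = 100, 200
    finals = {}
    for i, mode in enumerate(("true", "point", "posterior")):
        spec = c.CFSpec(delta=10.0, theta_mode=mode, n_samples=K, T=T, seed=40 + i)
        model = c.build_cf_model(
            _flat_noise(T, 1, sigma2=0.005), se, logistic_system, spec, [10.0],
            theta_true=logistic_system.theta_true,
        )
        cf = c.sample_cf_trajectories(model, spec, logistic_system.default_integ)
        finals[mode] = cf.trajectories[:, -1, 0]
    for a, b in (("true", "point"), ("true", "posterior"), ("point", "posterior")):
        assert ks_2samp(finals[a], finals[b]).pvalue > 0.01


def test_logistic_ensemble_converges_to_deterministic(logistic_system):
    """Non-chaotic contraction: the ensemble mean tracks the reference."""
    integ = logistic_system.default_integ
    T = 400
    spec = c.CFSpec(delta=10.0, theta_mode="true", n_samples=30, T=T, seed=5)
    model = c.build_cf_model(
        _flat_noise(T, 1, sigma2=0.01), None, logistic_system, spec, [10.0],
        theta_true=logistic_system.theta_true,
    )
    cf = c.sample_cf_trajectories(model, spec, integ)
    ref = c.deterministic_counterfactual(
        logistic_system, logistic_system.theta_true, [10.0], spec, integ
    )
    assert abs(np.nanmean(cf.trajectories[:, -1, 0]) - ref[-1, 0]) < 0.5


def test_lorenz_chaotic_amplification_across_seeds(lorenz_system):
    """Any nonzero abducted noise decorrelates chaotic counterfactuals."""
    integ = lorenz_system.default_integ
    T = 2000
    ref = None
    for seed in range(5):
        spec = c.CFSpec(
            delta=1e-4, j=0, theta_mode="true", n_samples=5, T=T, seed=seed
        )
        model = c.build_cf_model(
            _flat_noise(T, 3, sigma2=0.01), None, lorenz_system, spec,
            [1.0, 1.0, 1.0], theta_true=lorenz_system.theta_true,
        )
        cf = c.sample_cf_trajectories(model, spec, integ)
        if ref is None:
            ref = c.deterministic_counterfactual(
                lorenz_system, lorenz_system.theta_true, [1.0, 1.0, 1.0],
                spec, integ,
            )
        dist = np.linalg.norm(cf.trajectories - ref[None], axis=2)
        assert np.nanmax(dist) > 1.0


def test_deterministic_counterfactual_butterfly(lorenz_system):
    integ = lorenz_system.default_integ
    # on-attractor start: spin up past the weakly expanding transient
    x0 = c.propagate_deterministic(
        lorenz_system, lorenz_system.theta_true, [1.0, 1.0, 1.0], 5000, integ
    )[-1]
    spec = c.CFSpec(delta=1e-4, j=0, T=2000)
    cf = c.deterministic_counterfactual(
        lorenz_system, lorenz_system.theta_true, x0, spec, integ
    )
    factual = c.propagate_deterministic(
        lorenz_system, lorenz_system.theta_true, x0, 2000, integ
    )
    assert np.linalg.norm(cf - factual, axis=1).max() > 1.0
    # null intervention equals the factual trajectory
    null = c.CFSpec(delta=0.0, j=0, T=50)
    same = c.deterministic_counterfactual(
        lorenz_system, lorenz_system.theta_true, x0, null, integ
    )
    np.testing.assert_array_equal(same, factual[:51])


def test_diverged_trajectories_are_flagged(logistic_system):
    spec = c.CFSpec(delta=10.0, theta_mode="true", n_samples=4, T=60, seed=6)
    model = c.build_cf_model(
        _flat_noise(60, 1, mu=-5.0, sigma2=0.0), None, logistic_system, spec,
        [10.0], theta_true=logistic_system.theta_true,
    )
    cf = c.sample_cf_trajectories(model, spec, logistic_system.default_integ)
    assert cf.diverged.all()
    with pytest.raises(ValueError, match="diverged"):
        c.rmse_curve(cf, np.zeros((61, 1)), window=5)


def test_cf_ensemble_save(tmp_path, logistic_system):
    spec = c.CFSpec(delta=10.0, theta_mode="true", n_samples=3, T=15, seed=7)
    model = c.build_cf_model(
        _flat_noise(15, 1), None, logistic_system, spec, [10.0],
        theta_true=logistic_system.theta_true,
    )
    cf = c.sample_cf_trajectories(model, spec, logistic_system.default_integ)
    cf.save(tmp_path)
    assert (tmp_path / "counterfactuals.csv").exists()
    import json

    meta = json.loads((tmp_path / "counterfactuals.json").read_text())
    assert meta["theta_mode"] == "true" and meta["n_samples"] == 3
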