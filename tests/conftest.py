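"""Shared fixtures: a small end-to-end pipeline run reused across modules."""

import logging

import numpy as np
import pytest

import cfdyn as c

logging.getLogger("cfdyn").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def logistic_system():
    return c.get_system("logistic")


@pytest.fixture(scope="session")
def lorenz_system():
    return c.get_system("lorenz")


@pytest.fixture(scope="session")
def rossler_system():
    return c.get_system("rossler")


@pytest.fixture(scope="session")
def logistic_pipeline(logistic_system):
    """One small but complete run: simulate -> filter -> smooth -> abduct.

    Logistic growth with known-good noise levels; big enough to exercise
    every stage, small enough to share across the suite.
    """
    system = logistic_system
    integ = system.default_integ
    noise = c.NoiseConfig(sigma_u=0.01, sigma_w=1.0)
    real = c.simulate_ssm(
        system, system.theta_true, system.x0_default, 300, noise, integ, seed=7
    )
    est = c.NestedParticleSmoother(
        system=system,
        M=10,
        N=30,
        sigma_u=noise.sigma_u,
        sigma_w=noise.sigma_w,
        scheme=integ.scheme,
        delta=integ.delta,
        substeps=integ.substeps,
        seed=8,
    ).fit(real.obs)
    se = est.ensemble_
    residuals = c.particle_residuals(se, system, integ)
    post = c.noise_posterior(residuals, se)
    return {
        "system": system,
        "integ": integ,
        "noise": noise,
        "real": real,
        "est": est,
        "se": se,
        "residuals": residuals,
        "post": post,
    }
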