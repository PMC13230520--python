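"""Exogenous-noise abduction from the smoothed particle ensemble.

Each particle pair (x_t, x_{t-1}) along its ancestral lineage carries a
process-noise residual

    mu_t^(n,m) = x_t^(n,m) - F(x_{t-1}^(n,m), theta^(m)),

and the per-step abducted-noise posterior is the Gaussian N(mu_t, sigma_t)
with mu_t the smoothed-weight average of the residuals and sigma_t their
smoothed-weight variance, componentwise (a diagonal Gaussian, matching
the diagonal process-noise model). Counterfactual trajectories later
draw their process noise U_t^cf from this posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import logging

import numpy as np
import pandas as pd

from .npfs import SmoothedEnsemble
from .systems import IntegratorConfig, SystemSpec, forward_operator_batch

logger = logging.getLogger(__name__)

__all__ = ["NoisePosterior", "particle_residuals", "noise_posterior"]


@dataclass(frozen=True)
class NoisePosterior:
    """Per-step abducted-noise Gaussian N(mu_t, diag(sigma2_t)), t = 1..T."""

    mu: np.ndarray      # (T, d)
    sigma2: np.ndarray  # (T, d)
    source: dict | None = None

    def __post_init__(self):
        mu = np.asarray(self.mu, float)
        sigma2 = np.asarray(self.sigma2, float)
        if mu.shape != sigma2.shape or mu.ndim != 2:
            raise ValueError("mu and sigma2 must both have shape (T, d)")
        if not (np.all(np.isfinite(mu)) and np.all(np.isfinite(sigma2))):
            raise ValueError("noise posterior must be finite")
        if np.any(sigma2 < 0):
            raise ValueError("sigma2 must be non-negative")
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma2", sigma2)

    @property
    def T(self) -> int:
        return self.mu.shape[0]

    def to_frame(self) -> pd.DataFrame:
        d = self.mu.shape[1]
        data = {"step": np.arange(1, self.T + 1)}
        for i in range(d):
            data[f"mu_{i + 1}"] = self.mu[:, i]
        for i in range(d):
            data[f"sigma2_{i + 1}"] = self.sigma2[:, i]
        return pd.DataFrame(data)

    def save(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def particle_residuals(
    se: SmoothedEnsemble, system: SystemSpec, integ: IntegratorConfig
) -> np.ndarray:
    """Per-particle process-noise residuals along ancestral paths.

    Returns an array of shape (T, M, N, d); entry [t-1] holds the
    residuals for step t. By construction the reconstruction identity
    x_t = F(x_{t-1}, theta) + residual holds exactly on every particle.
    """
    T = se.T
    M, N, d = se.states.shape[1:]
    res = np.empty((T, M, N, d))
    rows = np.arange(M)[:, None]
    with np.errstate(invalid="ignore"):
        for t in range(1, T + 1):
            parents = se.states[t - 1][rows, se.parents[t]]      # (M, N, d)
            fx = forward_operator_batch(
                parents, se.thetas[t][:, None, :], system, integ
            )
            res[t - 1] = se.states[t] - fx
    # runaway particles (clamped at the divergence guard, smoothed weight
    # ~0) leave non-finite residuals; zero them so they cannot poison the
    # weighted moments through 0 * nan
    bad = ~np.isfinite(res)
    if bad.any():
        logger.warning(
            "zeroing %d non-finite residual entries from runaway particles",
            int(bad.sum()),
        )
        res[bad] = 0.0
    return res


def noise_posterior(residuals: np.ndarray, se: SmoothedEnsemble) -> NoisePosterior:
    """Aggregate particle residuals into the per-step noise posterior.

    Uses the jointly normalized smoothed weights: mu_t is the weighted
    residual mean and sigma2_t the weighted variance (as displayed — no
    Bessel-style correction), componentwise.
    """
    T = residuals.shape[0]
    w = se.smoothed_weights[1 : T + 1]                       # (T, M, N)
    mu = np.einsum("tmn,tmnd->td", w, residuals)
    dev = residuals - mu[:, None, None, :]
    sigma2 = np.einsum("tmn,tmnd->td", w, dev**2)
    source = {"theta_hat": se.theta_hat.tolist()}
    return NoisePosterior(mu=mu, sigma2=np.maximum(sigma2, 0.0), source=source)
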