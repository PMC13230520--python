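"""State-space simulation: hidden dynamics plus Gaussian observation noise.

The generative model is

    X_t = F(X_{t-1}, theta) + U_t,   U_t ~ N(0, sigma_u I)
    Y_t = H X_t + W_t,               W_t ~ N(0, sigma_w I)

with X_0 fixed and every step t = 0..T observed (Y_0 observes X_0). The
realized process noise is stored so tests can verify the reconstruction
identity exactly. This module is also the synthetic-data generator for
the whole test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DegenerateLikelihoodError, DivergedStateError
from .systems import (
    DIVERGENCE_NORM,
    IntegratorConfig,
    SystemSpec,
    forward_operator_batch,
    save_trajectory,
)

__all__ = [
    "NoiseConfig",
    "ObservationSeq",
    "SSMRealization",
    "simulate_ssm",
    "observation_logdensity",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class NoiseConfig:
    """Noise variances and observation matrix of the SSM.

    ``sigma_u`` and ``sigma_w`` are scalar variances (the covariance
    matrices are sigma_u I and sigma_w I). ``H`` is the d x d observation
    matrix; ``None`` means the identity.
    """

    sigma_u: float
    sigma_w: float
    H: np.ndarray | None = None

    def __post_init__(self):
        if self.sigma_u < 0 or self.sigma_w < 0:
            raise ValueError("noise variances must be non-negative")
        if self.H is not None:
            H = np.asarray(self.H, float)
            if H.ndim != 2 or H.shape[0] != H.shape[1]:
                raise ValueError("H must be a square d x d matrix")
            object.__setattr__(self, "H", H)

    def observe_matrix(self, dim: int) -> np.ndarray:
        if self.H is None:
            return np.eye(dim)
        if self.H.shape != (dim, dim):
            raise ValueError(f"H has shape {self.H.shape}, expected ({dim}, {dim})")
        return self.H

    @property
    def identity_H(self) -> bool:
        return self.H is None or np.array_equal(self.H, np.eye(self.H.shape[0]))


@dataclass(frozen=True)
class ObservationSeq:
    """Noisy observations Y_{0:T}; the sole input to inference."""

    y: np.ndarray          # (T+1, d)
    times: np.ndarray      # (T+1,) integer step index

    def __post_init__(self):
        y = np.asarray(self.y, float)
        if y.ndim != 2:
            raise ValueError("y must be a (T+1, d) matrix")
        if not np.all(np.isfinite(y)):
            raise ValueError("observations must be finite")
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "times", np.asarray(self.times, int))
        if len(self.times) != len(y):
            raise ValueError("times and y must have equal length")

    @property
    def T(self) -> int:
        return len(self.y) - 1

    @property
    def dim(self) -> int:
        return self.y.shape[1]


@dataclass(frozen=True)
class SSMRealization:
    """One simulated run: hidden states, observations, realized noise."""

    hidden: np.ndarray         # (T+1, d)
    obs: ObservationSeq
    process_noise: np.ndarray  # (T+1, d); row 0 is zero (X_0 is fixed)
    seed: int
    theta: np.ndarray
    noise: NoiseConfig
    integ: IntegratorConfig

    def save(self, directory) -> None:
        """Write hidden/observed CSVs plus a JSON sidecar of the settings."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        save_trajectory(directory / "hidden.csv", self.hidden, self.integ.delta)
        save_trajectory(directory / "observed.csv", self.obs.y, self.integ.delta)
        meta = {
            "theta": np.asarray(self.theta).tolist(),
            "sigma_u": self.noise.sigma_u,
            "sigma_w": self.noise.sigma_w,
            "seed": self.seed,
            "scheme": self.integ.scheme,
            "delta": self.integ.delta,
            "substeps": self.integ.substeps,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def simulate_ssm(
    system: SystemSpec,
    theta,
    x0,
    T: int,
    noise: NoiseConfig,
    integ: IntegratorConfig,
    seed: int,
) -> SSMRealization:
    """Simulate hidden states and observations for steps 0..T.

    X_0 equals ``x0`` exactly (no process noise at t=0); observations are
    produced for every step including t=0.
    """
    if T < 1:
        raise ValueError("T must be >= 1")
    if seed is None:
        raise ValueError("an explicit seed is required")
    rng = np.random.default_rng(seed)
    theta = np.asarray(theta, float)
    x0 = np.asarray(x0, float)
    d = system.dim
    H = noise.observe_matrix(d)

    hidden = np.empty((T + 1, d))
    u = np.zeros((T + 1, d))
    hidden[0] = x0
    sd_u = float(np.sqrt(noise.sigma_u))
    for t in range(1, T + 1):
        fx = forward_operator_batch(hidden[t - 1], theta, system, integ)
        u[t] = sd_u * rng.standard_normal(d)
        hidden[t] = fx + u[t]
        if not np.all(np.isfinite(hidden[t])) or np.linalg.norm(
            hidden[t]
        ) > DIVERGENCE_NORM:
            raise DivergedStateError(f"hidden state diverged at step {t}", step=t)

    w = float(np.sqrt(noise.sigma_w)) * rng.standard_normal((T + 1, d))
    y = hidden @ H.T + w
    obs = ObservationSeq(y=y, times=np.arange(T + 1))
    return SSMRealization(
        hidden=hidden,
        obs=obs,
        process_noise=u,
        seed=seed,
        theta=theta,
        noise=noise,
        integ=integ,
    )


def gaussian_logpdf_batch(
    y: np.ndarray, mean: np.ndarray, variance: float
) -> np.ndarray:
    """log N(y; mean, variance * I), summed over the last axis (batched)."""
    d = mean.shape[-1]
    sq = np.sum((y - mean) ** 2, axis=-1)
    return -0.5 * (d * (_LOG_2PI + np.log(variance)) + sq / variance)


def observation_logdensity(y, x, noise: NoiseConfig) -> float:
    """Log density of observation y given hidden state x.

    Raises
    ------
    DegenerateLikelihoodError
        If ``sigma_w`` is zero (point-mass likelihood cannot weight particles).
    """
    y = np.asarray(y, float)
    x = np.asarray(x, float)
    if y.shape != x.shape:
        raise ValueError("y and x must have matching shapes")
    if noise.sigma_w == 0:
        raise DegenerateLikelihoodError(
            "sigma_w = 0: observation likelihood is a point mass"
        )
    H = noise.observe_matrix(x.shape[-1])
    return float(gaussian_logpdf_batch(y, x @ H.T, noise.sigma_w))
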