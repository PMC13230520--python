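"""Counterfactual SCM construction and trajectory sampling.

Pearl's abduction-action-prediction recipe applied to the unrolled SSM:
the abducted noise posterior N(mu_t, sigma_t) replaces the process-noise
prior, the intervention shifts the initial state by delta along one
coordinate, and the structural equations are re-solved forward:

    X^cf_0 = X_0 + delta * e_j
    X^cf_t = F(X^cf_{t-1}, theta~) + U^cf_t,   U^cf_t ~ N(mu_t, diag(sigma_t))

The parameter node theta~ reflects three levels of knowledge: the true
parameters, the smoothed point estimate theta_hat, or a draw from the
Gaussian parameter posterior N(theta_hat, diag(sigma_theta^2)).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd

from .abduction import NoisePosterior
from .npfs import SmoothedEnsemble
from .systems import (
    DIVERGENCE_NORM,
    IntegratorConfig,
    SystemSpec,
    forward_operator_batch,
    propagate_deterministic,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CFSpec",
    "CFModel",
    "CFEnsemble",
    "build_cf_model",
    "sample_cf_trajectories",
    "deterministic_counterfactual",
]

THETA_MODES = ("true", "point", "posterior")


@dataclass(frozen=True)
class CFSpec:
    """Intervention and sampling settings for one counterfactual run.

    ``j`` is the 0-based index of the perturbed coordinate (the unit
    vector e_j); ``delta`` the perturbation magnitude in state units.
    """

    delta: float
    j: int = 0
    theta_mode: str = "true"
    n_samples: int = 50
    T: int = 2000
    seed: int | None = None

    def __post_init__(self):
        if self.theta_mode not in THETA_MODES:
            raise ValueError(f"theta_mode must be one of {THETA_MODES}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.j < 0:
            raise ValueError("j must be a valid 0-based coordinate index")


@dataclass
class CFModel:
    """Assembled counterfactual SCM: theta~ sampler, noise posterior, x0^cf."""

    theta_sampler: Callable[[np.random.Generator, int], np.ndarray]
    mu: np.ndarray      # (T, d)
    sigma2: np.ndarray  # (T, d)
    x0_cf: np.ndarray   # (d,)
    system: SystemSpec
    spec: CFSpec


@dataclass
class CFEnsemble:
    """Sampled counterfactual trajectories plus the theta~ draws used."""

    trajectories: np.ndarray  # (K, T+1, d); rows past divergence are NaN
    thetas_used: np.ndarray   # (K, p)
    diverged: np.ndarray      # (K,) bool
    spec: CFSpec

    @property
    def K(self) -> int:
        return self.trajectories.shape[0]

    def to_frame(self) -> pd.DataFrame:
        K, T1, d = self.trajectories.shape
        frames = []
        for k in range(K):
            df = pd.DataFrame(
                self.trajectories[k], columns=[f"x{i + 1}" for i in range(d)]
            )
            df.insert(0, "step", np.arange(T1))
            df.insert(0, "sample", k)
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def save(self, directory) -> None:
        """Long-form CSV plus a JSON sidecar with the run settings."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        self.to_frame().to_csv(directory / "counterfactuals.csv", index=False)
        meta = {
            "theta_mode": self.spec.theta_mode,
            "delta": self.spec.delta,
            "j": self.spec.j,
            "seed": self.spec.seed,
            "n_samples": self.spec.n_samples,
            "thetas_used": self.thetas_used.tolist(),
            "diverged": self.diverged.tolist(),
        }
        (directory / "counterfactuals.json").write_text(json.dumps(meta, indent=2))


def build_cf_model(
    noise_post: NoisePosterior,
    se: SmoothedEnsemble | None,
    system: SystemSpec,
    spec: CFSpec,
    x0,
    theta_true=None,
) -> CFModel:
    """Assemble the counterfactual SCM for one parameter regime.

    ``theta_mode="true"`` requires ``theta_true``; the other two modes
    read theta_hat / sigma_theta from the smoothed ensemble. A posterior
    mode whose sigma_theta is identically zero degenerates to point mode
    (logged notice).
    """
    if spec.j >= system.dim:
        raise ValueError(f"j={spec.j} out of range for dimension {system.dim}")
    if spec.T > noise_post.T:
        raise ValueError(
            f"noise posterior covers {noise_post.T} steps, spec asks for {spec.T}"
        )
    mode = spec.theta_mode
    if mode == "true":
        if theta_true is None:
            raise ValueError("theta_mode='true' requires theta_true")
        theta_true = np.asarray(theta_true, float)

        def theta_sampler(rng, k):
            return np.tile(theta_true, (k, 1))

    else:
        if se is None:
            raise ValueError(f"theta_mode={mode!r} requires a smoothed ensemble")
        theta_hat = np.asarray(se.theta_hat, float)
        sigma_theta = np.asarray(se.sigma_theta, float)
        if mode == "posterior" and np.all(sigma_theta == 0):
            logger.info("sigma_theta is zero; posterior mode degenerates to point")
            mode = "point"
        if mode == "point":

            def theta_sampler(rng, k):
                return np.tile(theta_hat, (k, 1))

        else:  # posterior: unconstrained Gaussian, one draw per trajectory

            def theta_sampler(rng, k):
                return theta_hat + sigma_theta * rng.standard_normal(
                    (k, len(theta_hat))
                )

    x0 = np.asarray(x0, float)
    x0_cf = x0.copy()
    x0_cf[spec.j] += spec.delta
    return CFModel(
        theta_sampler=theta_sampler,
        mu=noise_post.mu[: spec.T],
        sigma2=noise_post.sigma2[: spec.T],
        x0_cf=x0_cf,
        system=system,
        spec=spec,
    )


def sample_cf_trajectories(
    model: CFModel, spec: CFSpec, integ: IntegratorConfig
) -> CFEnsemble:
    """Sample K counterfactual trajectories from the assembled SCM.

    Every trajectory draws its own theta~ (one draw, parameters are
    static) and its own independent noise sequence U^cf_t ~ N(mu_t,
    diag(sigma_t)). Trajectories that numerically diverge (posterior
    theta~ draws can leave the stable regime) are flagged and NaN-filled
    past the divergence point rather than aborting the ensemble.
    """
    rng = np.random.default_rng(spec.seed)
    K, T = spec.n_samples, spec.T
    d = model.system.dim
    thetas = model.theta_sampler(rng, K)
    sd = np.sqrt(model.sigma2)

    traj = np.full((K, T + 1, d), np.nan)
    traj[:, 0, :] = model.x0_cf
    active = np.ones(K, dtype=bool)
    x = np.broadcast_to(model.x0_cf, (K, d)).copy()
    for t in range(1, T + 1):
        u = model.mu[t - 1] + sd[t - 1] * rng.standard_normal((K, d))
        x = forward_operator_batch(x, thetas, model.system, integ) + u
        with np.errstate(over="ignore", invalid="ignore"):
            bad = active & (
                ~np.all(np.isfinite(x), axis=-1)
                | (np.linalg.norm(np.nan_to_num(x), axis=-1) > DIVERGENCE_NORM)
            )
        if bad.any():
            active &= ~bad
            x = np.where(active[:, None], x, 0.0)
        traj[active, t, :] = x[active]
    diverged = ~active
    if diverged.any():
        logger.warning("%d/%d counterfactual trajectories diverged", diverged.sum(), K)
    return CFEnsemble(
        trajectories=traj, thetas_used=thetas, diverged=diverged, spec=spec
    )


def deterministic_counterfactual(
    system: SystemSpec,
    theta_true,
    x0,
    spec: CFSpec,
    integ: IntegratorConfig,
) -> np.ndarray:
    """Noise-free reference: propagate x0 + delta e_j under theta_true."""
    x0_cf = np.asarray(x0, float).copy()
    x0_cf[spec.j] += spec.delta
    return propagate_deterministic(system, theta_true, x0_cf, spec.T, integ)
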