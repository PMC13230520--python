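"""Dynamical-system definitions and deterministic propagation.

This module holds the continuous-time models used throughout the package
(Lorenz, Rössler, logistic growth), the discretized one-step forward
operator ``F`` obtained by numerical integration, and two chaos
diagnostics: the closed-form Lorenz subcritical-Hopf threshold and a
Benettin-style estimator of the largest Lyapunov exponent.

All drift functions broadcast over leading axes: ``state`` has shape
``(..., d)`` and ``theta`` shape ``(..., p)`` with compatible leading
dimensions, so the same code propagates a single state or a whole
particle ensemble.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .errors import DivergedStateError, UndefinedThresholdError

__all__ = [
    "SystemSpec",
    "IntegratorConfig",
    "get_system",
    "register_system",
    "available_systems",
    "drift",
    "forward_operator",
    "propagate_deterministic",
    "lorenz_critical_rho",
    "largest_lyapunov",
    "lyapunov_scan",
    "save_trajectory",
    "load_trajectory",
]

#: states with Euclidean norm above this are treated as numerically diverged
DIVERGENCE_NORM = 1e6


@dataclass(frozen=True)
class IntegratorConfig:
    """Fixed-step integrator settings for the forward operator.

    One SSM step advances model time by ``delta``; the integrator takes
    ``substeps`` internal steps of size ``delta / substeps``.
    """

    scheme: str = "rk4"
    delta: float = 0.01
    substeps: int = 1

    def __post_init__(self):
        if self.scheme not in ("rk4", "euler"):
            raise ValueError(f"unknown scheme {self.scheme!r}; use 'rk4' or 'euler'")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if self.substeps < 1:
            raise ValueError("substeps must be a positive integer")


@dataclass(frozen=True)
class SystemSpec:
    """An ODE family with ground-truth parameters and a uniform prior.

    Parameters
    ----------
    name : str
        Registry identifier.
    dim : int
        State dimension d.
    drift : callable
        ``drift(state, theta) -> dstate/dt``, broadcasting over leading axes.
    theta_true : ndarray, shape (p,)
        Ground-truth parameter vector used by the simulator.
    prior_bounds : ndarray, shape (p, 2)
        Per-parameter (low, high) of the uniform prior.
    x0_default : ndarray, shape (d,)
        Default initial state.
    forward_map : callable, optional
        Explicit discrete-time map ``(state, theta) -> next state``. When
        given, it replaces numerical integration entirely (one application
        per SSM step); used for exactly-specified discrete models such as
        linear-Gaussian test systems.
    default_integ : IntegratorConfig
        The SSM step this system is simulated with by default. The
        discrete step sets both the observation rate and the
        noise-injection interval; slow relaxing systems (logistic) use a
        coarser step with sub-stepping so the per-step process noise does
        not swamp the per-step deterministic contraction.
    """

    name: str
    dim: int
    drift: Callable[[np.ndarray, np.ndarray], np.ndarray]
    theta_true: np.ndarray
    prior_bounds: np.ndarray
    x0_default: np.ndarray
    forward_map: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    default_integ: IntegratorConfig = field(default_factory=IntegratorConfig)

    def __post_init__(self):
        object.__setattr__(self, "theta_true", np.asarray(self.theta_true, float))
        object.__setattr__(self, "prior_bounds", np.asarray(self.prior_bounds, float))
        object.__setattr__(self, "x0_default", np.asarray(self.x0_default, float))
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.prior_bounds.ndim != 2 or self.prior_bounds.shape[1] != 2:
            raise ValueError("prior_bounds must have shape (p, 2)")
        low, high = self.prior_bounds[:, 0], self.prior_bounds[:, 1]
        if not np.all(low < high):
            raise ValueError("each prior interval needs low < high")
        if not (np.all(self.theta_true >= low) and np.all(self.theta_true <= high)):
            raise ValueError("theta_true must lie inside prior_bounds")

    @property
    def n_params(self) -> int:
        return self.prior_bounds.shape[0]


# ---------------------------------------------------------------------------
# standard drifts
# ---------------------------------------------------------------------------

def lorenz_drift(state: np.ndarray, theta: np.ndarray) -> np.ndarray:
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    sigma, rho, beta = theta[..., 0], theta[..., 1], theta[..., 2]
    return np.stack(
        [sigma * (y - x), x * (rho - z) - y, x * y - beta * z], axis=-1
    )


def rossler_drift(state: np.ndarray, theta: np.ndarray) -> np.ndarray:
    x, y, z = state[..., 0], state[..., 1], state[..., 2]
    a, b, c = theta[..., 0], theta[..., 1], theta[..., 2]
    return np.stack([-y - z, x + a * y, b + z * (x - c)], axis=-1)


def logistic_drift(state: np.ndarray, theta: np.ndarray) -> np.ndarray:
    x = state[..., 0]
    r, k = theta[..., 0], theta[..., 1]
    return (r * x * (1.0 - x / k))[..., None]


_REGISTRY: dict[str, SystemSpec] = {}


def register_system(spec: SystemSpec) -> SystemSpec:
    """Add a system to the registry (overwrites an existing name)."""
    _REGISTRY[spec.name] = spec
    return spec


def get_system(name: str) -> SystemSpec:
    try:
        return _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown system {name!r}; available: {sorted(_REGISTRY)}"
        ) from None


def available_systems() -> list[str]:
    return sorted(_REGISTRY)


register_system(
    SystemSpec(
        name="lorenz",
        dim=3,
        drift=lorenz_drift,
        theta_true=(10.0, 28.0, 8.0 / 3.0),
        prior_bounds=[(5.0, 15.0), (20.0, 35.0), (2.0, 4.0)],
        x0_default=(1.0, 1.0, 1.0),
    )
)
register_system(
    SystemSpec(
        name="rossler",
        dim=3,
        drift=rossler_drift,
        theta_true=(0.2, 0.2, 5.7),
        prior_bounds=[(0.1, 0.3), (0.1, 0.3), (4.0, 7.0)],
        x0_default=(1.0, 1.0, 0.0),
    )
)
register_system(
    SystemSpec(
        name="logistic",
        dim=1,
        drift=logistic_drift,
        theta_true=(3.9, 1.0),
        prior_bounds=[(2.0, 4.0), (0.8, 1.2)],
        x0_default=(10.0,),
        # relaxation rate r*Delta per step must dominate the per-step noise:
        # coarser SSM step, same RK4 sub-step h = 0.01
        default_integ=IntegratorConfig(scheme="rk4", delta=0.1, substeps=10),
    )
)


# ---------------------------------------------------------------------------
# drift evaluation and integration
# ---------------------------------------------------------------------------

def drift(system: SystemSpec, state, theta) -> np.ndarray:
    """Evaluate the drift h_theta at a single state, with validation."""
    state = np.asarray(state, float)
    theta = np.asarray(theta, float)
    if state.shape[-1] != system.dim:
        raise ValueError(
            f"state has dimension {state.shape[-1]}, system {system.name!r} "
            f"expects {system.dim}"
        )
    if theta.shape[-1] != system.n_params:
        raise ValueError(
            f"theta has {theta.shape[-1]} entries, system {system.name!r} "
            f"expects {system.n_params}"
        )
    if not np.all(np.isfinite(state)):
        raise ValueError("non-finite state passed to drift")
    return system.drift(state, theta)


def _integrate_step(
    f: Callable, state: np.ndarray, theta: np.ndarray, integ: IntegratorConfig
) -> np.ndarray:
    """One SSM step of deterministic evolution (batched, no guards)."""
    h = integ.delta / integ.substeps
    x = state
    if integ.scheme == "euler":
        for _ in range(integ.substeps):
            x = x + h * f(x, theta)
    else:  # rk4
        for _ in range(integ.substeps):
            k1 = f(x, theta)
            k2 = f(x + 0.5 * h * k1, theta)
            k3 = f(x + 0.5 * h * k2, theta)
            k4 = f(x + h * k3, theta)
            x = x + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return x


def forward_operator_batch(
    state: np.ndarray, theta: np.ndarray, system: SystemSpec, integ: IntegratorConfig
) -> np.ndarray:
    """Batched forward operator without divergence guards.

    Non-finite outputs are returned as-is; callers (the particle filter,
    the counterfactual sampler) down-weight or flag them.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        if system.forward_map is not None:
            return system.forward_map(state, theta)
        return _integrate_step(system.drift, state, theta, integ)


def forward_operator(
    state, theta, system: SystemSpec, integ: IntegratorConfig
) -> np.ndarray:
    """Deterministic one-step map F(X_{t-1}, theta) for a single state.

    Raises
    ------
    DivergedStateError
        If the result is non-finite or its norm exceeds the guard.
    """
    state = np.asarray(state, float)
    theta = np.asarray(theta, float)
    if state.shape != (system.dim,):
        raise ValueError(f"state must have shape ({system.dim},)")
    out = forward_operator_batch(state, theta, system, integ)
    if not np.all(np.isfinite(out)) or np.linalg.norm(out) > DIVERGENCE_NORM:
        raise DivergedStateError("forward operator produced a diverged state", step=1)
    return out


def propagate_deterministic(
    system: SystemSpec,
    theta,
    x0,
    T: int,
    integ: IntegratorConfig,
) -> np.ndarray:
    """Noise-free trajectory of T+1 states starting at x0.

    ``out[t]`` is the state after t applications of the forward operator.
    """
    if T < 0:
        raise ValueError("T must be >= 0")
    x0 = np.asarray(x0, float)
    theta = np.asarray(theta, float)
    traj = np.empty((T + 1, system.dim))
    traj[0] = x0
    x = x0
    for t in range(1, T + 1):
        x = forward_operator_batch(x, theta, system, integ)
        if not np.all(np.isfinite(x)) or np.linalg.norm(x) > DIVERGENCE_NORM:
            raise DivergedStateError(
                f"trajectory diverged at step {t}", step=t
            )
        traj[t] = x
    return traj


# ---------------------------------------------------------------------------
# chaos diagnostics
# ---------------------------------------------------------------------------

def lorenz_critical_rho(sigma: float, beta: float) -> float:
    """Subcritical-Hopf threshold rho_H = sigma (sigma + beta + 3) / (sigma - beta - 1).

    For rho above this value the Lorenz fixed points lose stability and
    the system is chaotic (24.74 at the classical sigma=10, beta=8/3).
    """
    denom = sigma - beta - 1.0
    if denom == 0.0:
        raise UndefinedThresholdError(
            "critical rho undefined: sigma - beta - 1 = 0"
        )
    return sigma * (sigma + beta + 3.0) / denom


def lyapunov_scan(
    system: SystemSpec,
    thetas,
    integ: IntegratorConfig,
    horizon: float = 2000.0,
    transient: float = 50.0,
    x0=None,
    renorm_interval: float = 1.0,
    d0: float = 1e-8,
) -> np.ndarray:
    """Largest Lyapunov exponent for a batch of parameter vectors.

    Benettin's method: evolve a reference trajectory and a companion
    offset by ``d0`` along the first coordinate; every
    ``renorm_interval`` time units record log(d/d0) and rescale the
    companion back to separation ``d0``. The exponent is the mean log
    stretch per unit time over ``horizon``, after discarding
    ``transient`` time units.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    thetas = np.atleast_2d(np.asarray(thetas, float))
    B = thetas.shape[0]
    x0 = system.x0_default if x0 is None else np.asarray(x0, float)

    ref = np.broadcast_to(x0, (B, system.dim)).copy()
    n_transient = int(round(transient / integ.delta))
    for t in range(n_transient):
        ref = forward_operator_batch(ref, thetas, system, integ)
        if not np.all(np.isfinite(ref)):
            raise DivergedStateError("transient diverged", step=t)

    comp = ref.copy()
    comp[:, 0] += d0
    steps_per_interval = max(1, int(round(renorm_interval / integ.delta)))
    tau = steps_per_interval * integ.delta
    n_intervals = max(1, int(round(horizon / tau)))

    log_stretch = np.zeros(B)
    both = np.concatenate([ref, comp], axis=0)  # (2B, d), one integration batch
    for i in range(n_intervals):
        for _ in range(steps_per_interval):
            both = forward_operator_batch(
                both, np.concatenate([thetas, thetas], axis=0), system, integ
            )
        if not np.all(np.isfinite(both)) or np.any(
            np.abs(both) > DIVERGENCE_NORM
        ):
            raise DivergedStateError("lyapunov trajectory diverged", step=i)
        ref, comp = both[:B], both[B:]
        sep = comp - ref
        dist = np.linalg.norm(sep, axis=1)
        dist = np.maximum(dist, 1e-300)  # fully converged twins
        log_stretch += np.log(dist / d0)
        comp = ref + sep * (d0 / dist)[:, None]
        both = np.concatenate([ref, comp], axis=0)
    return log_stretch / (n_intervals * tau)


def largest_lyapunov(
    system: SystemSpec,
    theta,
    integ: IntegratorConfig,
    horizon: float = 2000.0,
    transient: float = 50.0,
    x0=None,
    renorm_interval: float = 1.0,
    d0: float = 1e-8,
) -> float:
    """Benettin estimate of the largest Lyapunov exponent for one theta."""
    return float(
        lyapunov_scan(
            system,
            np.asarray(theta, float)[None, :],
            integ,
            horizon=horizon,
            transient=transient,
            x0=x0,
            renorm_interval=renorm_interval,
            d0=d0,
        )[0]
    )


# ---------------------------------------------------------------------------
# trajectory serialization
# ---------------------------------------------------------------------------

def save_trajectory(path, traj: np.ndarray, delta: float) -> None:
    """Write a (T+1, d) trajectory as CSV with columns step, time, x1..xd."""
    traj = np.asarray(traj, float)
    d = traj.shape[1]
    df = pd.DataFrame(traj, columns=[f"x{i + 1}" for i in range(d)])
    df.insert(0, "time", np.arange(len(traj)) * delta)
    df.insert(0, "step", np.arange(len(traj)))
    df.to_csv(path, index=False)


def load_trajectory(path) -> np.ndarray:
    """Read a trajectory CSV written by :func:`save_trajectory`."""
    df = pd.read_csv(path)
    cols = [c for c in df.columns if c.startswith("x")]
    return df[cols].to_numpy(float)
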