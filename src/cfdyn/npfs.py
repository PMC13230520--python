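"""Nested particle filtering and backward smoothing.

Joint state-parameter inference for the additive-Gaussian SSM built on a
two-layer sequential Monte Carlo scheme: an outer population of M
parameter particles (jittered each step to avoid degeneracy of the
static parameter) and, attached to each, an inner bootstrap filter of N
state particles. After the forward pass, a backward smoothing recursion
reweights the state particles using the full observation sequence;
parameters are static, so their smoothed posterior is the final-time
outer posterior.

The public surface is the sklearn-style estimator
:class:`NestedParticleSmoother`; the module-level operations
(:func:`run_filter`, :func:`backward_smooth`, ...) are thin wrappers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp
from sklearn.base import BaseEstimator

from .errors import DegenerateLikelihoodError
from .ssm import NoiseConfig, ObservationSeq, gaussian_logpdf_batch
from .systems import (
    DIVERGENCE_NORM,
    IntegratorConfig,
    SystemSpec,
    forward_operator_batch,
    get_system,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FilterConfig",
    "ParticleState",
    "FilterHistory",
    "SmoothedEnsemble",
    "NestedParticleSmoother",
    "initialize_ensemble",
    "filter_step",
    "run_filter",
    "backward_smooth",
    "point_estimates",
    "systematic_indices",
    "multinomial_indices",
]


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def systematic_indices(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Systematic resampling: one uniform offset, stratified positions."""
    w = np.asarray(weights, float)
    n = len(w)
    positions = (rng.random() + np.arange(n)) / n
    cum = np.cumsum(w)
    cum[-1] = 1.0  # guard against rounding
    return np.searchsorted(cum, positions, side="right").clip(0, n - 1)


def multinomial_indices(weights: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    w = np.asarray(weights, float)
    return rng.choice(len(w), size=len(w), p=w / w.sum())


_RESAMPLERS = {"systematic": systematic_indices, "multinomial": multinomial_indices}


def _normalize_log(logw: np.ndarray, axis: int = -1):
    """Normalize log weights; degenerate slices fall back to uniform.

    Returns (normalized weights, log normalizer, degenerate mask).
    """
    lse = logsumexp(logw, axis=axis, keepdims=True)
    degenerate = ~np.isfinite(np.squeeze(lse, axis=axis))
    safe = np.where(np.isfinite(lse), lse, 0.0)
    w = np.exp(logw - safe)
    n = logw.shape[axis]
    uniform = np.full(logw.shape, 1.0 / n)
    mask = np.broadcast_to(np.expand_dims(degenerate, axis), logw.shape)
    w = np.where(mask, uniform, w)
    return w, np.squeeze(safe, axis=axis), degenerate


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterConfig:
    """Particle counts and Monte Carlo settings of the nested filter."""

    M: int = 50
    N: int = 100
    jitter_scale: float = 0.05
    resample_scheme: str = "systematic"
    seed: int | None = None

    def __post_init__(self):
        if self.M < 1 or self.N < 1:
            raise ValueError("particle counts must be >= 1")
        if self.jitter_scale < 0:
            raise ValueError("jitter_scale must be >= 0")
        if self.resample_scheme not in _RESAMPLERS:
            raise ValueError(f"unknown resample scheme {self.resample_scheme!r}")


@dataclass
class ParticleState:
    """Current particle populations (post-resampling), ready to propagate.

    ``anc_outer``/``anc_inner`` record which pre-resampling particles of
    the step just weighted were selected, i.e. the ancestry of the next
    propagation; they are copied into the next step's record so residual
    computation can pair each particle with its true parent.
    """

    theta: np.ndarray            # (M, p)
    states: np.ndarray           # (M, N, d)
    rng: np.random.Generator
    t: int = 0
    anc_outer: np.ndarray | None = None  # (M,)
    anc_inner: np.ndarray | None = None  # (M, N)


@dataclass
class StepRecord:
    """Pre-resampling snapshot stored for smoothing and abduction."""

    theta: np.ndarray          # (M, p) values used for propagation at t
    states: np.ndarray         # (M, N, d) post-propagation, pre-resampling
    inner_weights: np.ndarray  # (M, N), normalized within each m
    outer_weights: np.ndarray  # (M,), normalized
    outer_anc: np.ndarray      # (M,) parent block index at t-1
    inner_anc: np.ndarray      # (M, N) parent particle index within that block


@dataclass
class FilterHistory:
    """Full forward-pass history: one slice per step t = 0..T."""

    theta: np.ndarray          # (T+1, M, p)
    states: np.ndarray         # (T+1, M, N, d)
    inner_weights: np.ndarray  # (T+1, M, N)
    outer_weights: np.ndarray  # (T+1, M)
    outer_anc: np.ndarray      # (T+1, M); row 0 is arange
    inner_anc: np.ndarray      # (T+1, M, N); row 0 is arange
    config: FilterConfig
    noise: NoiseConfig
    integ: IntegratorConfig

    @property
    def T(self) -> int:
        return self.theta.shape[0] - 1

    def theta_posterior(self):
        """Final-time parameter posterior summary (weighted mean and SD)."""
        v = self.outer_weights[-1]
        th = self.theta[-1]
        mean = v @ th
        var = v @ (th - mean) ** 2
        return mean, np.sqrt(var)


@dataclass
class SmoothedEnsemble:
    """Backward-smoothing output, realigned to the final-time outer lineage.

    ``states[t, m]`` are the N state particles of the (final-time) m-th
    parameter block at step t, ``smoothed_weights[t]`` the jointly
    normalized weights (summing to one over n and m), and ``parents[t]``
    the ancestral index of each particle within block m at step t-1.
    """

    states: np.ndarray            # (T+1, M, N, d)
    thetas: np.ndarray            # (T+1, M, p)
    parents: np.ndarray           # (T+1, M, N); row 0 is arange
    smoothed_weights: np.ndarray  # (T+1, M, N)
    outer_weights: np.ndarray     # (M,) final-time outer posterior
    theta_hat: np.ndarray         # (p,)
    sigma_theta: np.ndarray       # (p,)
    state_mean: np.ndarray        # (T+1, d)
    history: FilterHistory

    @property
    def T(self) -> int:
        return self.states.shape[0] - 1


# ---------------------------------------------------------------------------
# filter mechanics
# ---------------------------------------------------------------------------

def _sanitize(states: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Clamp non-finite/huge particle states; return (states, invalid mask).

    Invalid particles keep finite placeholder values and get -inf
    likelihood, so they are eliminated at the next resampling step
    instead of aborting the run (jittered parameters can leave the
    stable regime).
    """
    with np.errstate(over="ignore", invalid="ignore"):
        invalid = ~np.all(np.isfinite(states), axis=-1)
        invalid |= (
            np.linalg.norm(np.nan_to_num(states), axis=-1) > DIVERGENCE_NORM
        )
    if invalid.any():
        states = np.nan_to_num(
            states, nan=0.0, posinf=DIVERGENCE_NORM, neginf=-DIVERGENCE_NORM
        )
    return states, invalid


def _inner_outer_weights(states, y_t, noise, M, N):
    states, invalid = _sanitize(states)
    H = noise.observe_matrix(states.shape[-1])
    loglik = gaussian_logpdf_batch(y_t, states @ H.T, noise.sigma_w)
    loglik = np.where(invalid, -np.inf, loglik)
    inner, log_norm, degen_inner = _normalize_log(loglik, axis=1)
    if degen_inner.any():
        logger.warning(
            "inner weights degenerate for %d/%d parameter blocks; uniform fallback",
            int(degen_inner.sum()), M,
        )
    # outer weight: mean unnormalized inner likelihood, in log space
    log_u = log_norm - np.log(N)
    log_u = np.where(degen_inner, -np.inf, log_u)
    outer, _, degen_outer = _normalize_log(log_u, axis=0)
    if degen_outer:
        logger.warning("all outer weights degenerate; uniform fallback")
    return states, inner, outer


def _resample(record: StepRecord, cfg: FilterConfig, rng) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Outer-then-inner resampling; returns new (theta, states, A, B)."""
    pick = _RESAMPLERS[cfg.resample_scheme]
    M, N, _ = record.states.shape
    A = pick(record.outer_weights, rng)
    B = np.empty((M, N), dtype=int)
    for m in range(M):
        B[m] = pick(record.inner_weights[A[m]], rng)
    theta = record.theta[A]
    states = record.states[A[:, None], B]
    return theta, states, A, B


def _jitter(theta, system: SystemSpec, cfg: FilterConfig, rng):
    """Gaussian parameter jitter, SD shrinking with M, reflected at the prior."""
    if cfg.jitter_scale == 0:
        return theta
    low = system.prior_bounds[:, 0]
    high = system.prior_bounds[:, 1]
    width = high - low
    sd = cfg.jitter_scale * width / np.sqrt(cfg.M)
    cand = theta + sd * rng.standard_normal(theta.shape)
    # reflect into [low, high]
    span = 2.0 * width
    y = np.mod(cand - low, span)
    y = np.where(y > width, span - y, y)
    return low + y


def initialize_ensemble(
    system: SystemSpec,
    cfg: FilterConfig,
    first_obs,
    noise: NoiseConfig,
    rng: np.random.Generator | None = None,
    fixed_theta=None,
) -> ParticleState:
    """Draw the initial particle populations.

    Parameters come from the uniform prior (or are pinned to
    ``fixed_theta``); states come from the state prior tau_0, which
    anchors on the first observation, N(Y_0, sigma_w I), when the
    observation matrix is the identity, and on N(x0_default, I)
    otherwise.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    first_obs = np.asarray(first_obs, float)
    p = system.n_params
    if fixed_theta is not None:
        theta = np.tile(np.asarray(fixed_theta, float), (cfg.M, 1))
    else:
        low = system.prior_bounds[:, 0]
        high = system.prior_bounds[:, 1]
        theta = rng.uniform(low, high, size=(cfg.M, p))
    if noise.identity_H and noise.sigma_w > 0:
        center, sd = first_obs, float(np.sqrt(noise.sigma_w))
    else:
        center, sd = system.x0_default, 1.0
    states = center + sd * rng.standard_normal((cfg.M, cfg.N, system.dim))
    return ParticleState(theta=theta, states=states, rng=rng, t=0)


def filter_step(
    particles: ParticleState,
    y_t,
    system: SystemSpec,
    noise: NoiseConfig,
    integ: IntegratorConfig,
    cfg: FilterConfig,
) -> tuple[ParticleState, StepRecord]:
    """One recursive update of the nested filter.

    Jitter the parameter particles, propagate every state particle
    through the forward operator plus process noise, weight inner
    particles by the observation likelihood, weight parameter particles
    by the mean inner likelihood, then resample the outer layer
    (carrying state blocks along) followed by the inner layer.
    """
    rng = particles.rng
    y_t = np.asarray(y_t, float)
    M, N = cfg.M, cfg.N
    theta = _jitter(particles.theta, system, cfg, rng)
    fx = forward_operator_batch(particles.states, theta[:, None, :], system, integ)
    u = np.sqrt(noise.sigma_u) * rng.standard_normal(fx.shape)
    states = fx + u
    states, inner, outer = _inner_outer_weights(states, y_t, noise, M, N)
    record = StepRecord(
        theta=theta,
        states=states,
        inner_weights=inner,
        outer_weights=outer,
        # ancestry of THIS propagation: the resampling that formed
        # ``particles`` at the end of the previous step
        outer_anc=particles.anc_outer,
        inner_anc=particles.anc_inner,
    )
    new_theta, new_states, A, B = _resample(record, cfg, rng)
    new = ParticleState(
        theta=new_theta,
        states=new_states,
        rng=rng,
        t=particles.t + 1,
        anc_outer=A,
        anc_inner=B,
    )
    return new, record


class NestedParticleSmoother(BaseEstimator):
    """Nested particle filter with backward smoothing, sklearn-style.

    ``fit(Y)`` consumes a full observation sequence and exposes the
    joint state-parameter posterior through fitted attributes.

    Parameters
    ----------
    system : SystemSpec or str
        The dynamical system (registry name or explicit spec).
    M, N : int
        Outer (parameter) and inner (state) particle counts.
    jitter_scale : float
        Relative width c of the parameter jitter kernel; the
        per-component SD is ``c * prior_width / sqrt(M)``, reflected at
        the prior bounds.
    sigma_u, sigma_w : float
        Process and observation noise variances assumed by the filter.
    H : ndarray or None
        Observation matrix (None = identity).
    scheme, delta, substeps :
        Integrator settings of the forward operator.
    fixed_theta : array-like or None
        Pin the parameters (no prior draws, no jitter); with M=1 this
        reduces exactly to a bootstrap particle filter with known
        parameters.
    resample_scheme : {"systematic", "multinomial"}
    smooth : bool
        Run the backward smoothing pass after filtering.
    seed : int or None
        Seed for all Monte Carlo draws.

    Attributes
    ----------
    history_ : FilterHistory
    ensemble_ : SmoothedEnsemble or None
        Present when ``smooth=True``.
    theta_hat_ : ndarray, shape (p,)
        Posterior-mean parameter estimate.
    sigma_theta_ : ndarray, shape (p,)
        Componentwise posterior SD of the parameters.
    state_mean_ : ndarray, shape (T+1, d)
        Smoothed (or, with ``smooth=False``, filtered) state means.
    """

    def __init__(
        self,
        system="lorenz",
        M=50,
        N=100,
        jitter_scale=0.05,
        sigma_u=1.0,
        sigma_w=1.0,
        H=None,
        scheme="rk4",
        delta=0.01,
        substeps=1,
        fixed_theta=None,
        resample_scheme="systematic",
        smooth=True,
        seed=None,
    ):
        self.system = system
        self.M = M
        self.N = N
        self.jitter_scale = jitter_scale
        self.sigma_u = sigma_u
        self.sigma_w = sigma_w
        self.H = H
        self.scheme = scheme
        self.delta = delta
        self.substeps = substeps
        self.fixed_theta = fixed_theta
        self.resample_scheme = resample_scheme
        self.smooth = smooth
        self.seed = seed

    # -- assembled configuration objects ---------------------------------
    def _resolve(self):
        system = get_system(self.system) if isinstance(self.system, str) else self.system
        cfg = FilterConfig(
            M=self.M,
            N=self.N,
            jitter_scale=0.0 if self.fixed_theta is not None else self.jitter_scale,
            resample_scheme=self.resample_scheme,
            seed=self.seed,
        )
        noise = NoiseConfig(sigma_u=self.sigma_u, sigma_w=self.sigma_w, H=self.H)
        integ = IntegratorConfig(
            scheme=self.scheme, delta=self.delta, substeps=self.substeps
        )
        return system, cfg, noise, integ

    def fit(self, Y, y=None):
        """Run the forward filter (and backward smoother) on Y_{0:T}."""
        system, cfg, noise, integ = self._resolve()
        if noise.sigma_w == 0:
            raise DegenerateLikelihoodError(
                "sigma_w = 0: particle weighting needs a non-degenerate likelihood"
            )
        obs = Y if isinstance(Y, ObservationSeq) else ObservationSeq(
            y=np.atleast_2d(np.asarray(Y, float)), times=np.arange(len(Y))
        )
        if obs.dim != system.dim:
            raise ValueError(
                f"observations have dimension {obs.dim}, system expects {system.dim}"
            )
        T = obs.T
        rng = np.random.default_rng(cfg.seed)

        particles = initialize_ensemble(
            system, cfg, obs.y[0], noise, rng=rng, fixed_theta=self.fixed_theta
        )
        # step 0: weight and resample against Y_0, no propagation
        states, inner, outer = _inner_outer_weights(
            particles.states, obs.y[0], noise, cfg.M, cfg.N
        )
        rec0 = StepRecord(
            theta=particles.theta,
            states=states,
            inner_weights=inner,
            outer_weights=outer,
            outer_anc=np.arange(cfg.M),
            inner_anc=np.tile(np.arange(cfg.N), (cfg.M, 1)),
        )
        theta_r, states_r, A0, B0 = _resample(rec0, cfg, rng)
        particles = ParticleState(
            theta=theta_r, states=states_r, rng=rng, t=0,
            anc_outer=A0, anc_inner=B0,
        )

        records = [rec0]
        for t in range(1, T + 1):
            particles, rec = filter_step(
                particles, obs.y[t], system, noise, integ, cfg
            )
            records.append(rec)

        self.history_ = FilterHistory(
            theta=np.stack([r.theta for r in records]),
            states=np.stack([r.states for r in records]),
            inner_weights=np.stack([r.inner_weights for r in records]),
            outer_weights=np.stack([r.outer_weights for r in records]),
            outer_anc=np.stack([r.outer_anc for r in records]),
            inner_anc=np.stack([r.inner_anc for r in records]),
            config=cfg,
            noise=noise,
            integ=integ,
        )
        self.n_steps_ = T
        if self.smooth:
            self.ensemble_ = backward_smooth(self.history_, system, noise, integ)
            self.theta_hat_ = self.ensemble_.theta_hat
            self.sigma_theta_ = self.ensemble_.sigma_theta
            self.state_mean_ = self.ensemble_.state_mean
        else:
            self.ensemble_ = None
            self.theta_hat_, self.sigma_theta_ = self.history_.theta_posterior()
            joint = (
                self.history_.outer_weights[:, :, None]
                * self.history_.inner_weights
            )
            self.state_mean_ = np.einsum("tmn,tmnd->td", joint, self.history_.states)
        return self


def run_filter(
    obs: ObservationSeq,
    system: SystemSpec,
    noise: NoiseConfig,
    integ: IntegratorConfig,
    cfg: FilterConfig,
    fixed_theta=None,
) -> FilterHistory:
    """Forward nested-filter pass; thin wrapper over the estimator."""
    est = NestedParticleSmoother(
        system=system,
        M=cfg.M,
        N=cfg.N,
        jitter_scale=cfg.jitter_scale,
        sigma_u=noise.sigma_u,
        sigma_w=noise.sigma_w,
        H=noise.H,
        scheme=integ.scheme,
        delta=integ.delta,
        substeps=integ.substeps,
        fixed_theta=fixed_theta,
        resample_scheme=cfg.resample_scheme,
        smooth=False,
        seed=cfg.seed,
    )
    est.fit(obs)
    return est.history_


# ---------------------------------------------------------------------------
# backward smoothing
# ---------------------------------------------------------------------------

def backward_smooth(
    hist: FilterHistory,
    system: SystemSpec,
    noise: NoiseConfig,
    integ: IntegratorConfig,
) -> SmoothedEnsemble:
    """Forward-filtering backward-smoothing pass over a filter history.

    State particles are realigned to the final-time outer lineage (each
    of the M parameter blocks traced back through the outer resampling
    ancestry), then within each block the standard backward recursion

        w~_T = w_T
        w~_t(n) ∝ w_t(n) * sum_k w~_{t+1}(k)
                  * f(x_{t+1}(k) | x_t(n)) / sum_l w_t(l) f(x_{t+1}(k) | x_t(l))

    runs with the Gaussian transition density f = N(F(x_t, theta),
    sigma_u I); the denominator is the particle predictive density that
    normalizes each forward transition.
    Parameters are static, so their smoothed posterior is the final-time
    outer posterior; the joint smoothed weight of particle (n, m) at
    step t is v_T(m) * w~_t(n|m).

    With ``sigma_u = 0`` the transition density is degenerate and the
    smoother falls back to ancestral-path weights (final-time weights
    propagated back along the resampling lineage), with a logged warning.
    """
    T = hist.T
    M, N = hist.config.M, hist.config.N

    # realign every slice to the final-time outer lineage
    L = np.empty((T + 1, M), dtype=int)
    L[T] = np.arange(M)
    for t in range(T, 0, -1):
        L[t - 1] = hist.outer_anc[t][L[t]]
    idx = L[:, :, None]
    xs = np.take_along_axis(hist.states, idx[..., None], axis=1)
    ws = np.take_along_axis(hist.inner_weights, idx, axis=1)
    th = np.take_along_axis(hist.theta, idx[:, :, 0][..., None], axis=1)
    parents = np.take_along_axis(hist.inner_anc, idx, axis=1)

    s = np.empty((T + 1, M, N))
    s[T] = ws[T]
    if noise.sigma_u == 0:
        logger.warning(
            "sigma_u = 0: transition density degenerate; "
            "falling back to ancestral-path smoothing"
        )
        for t in range(T - 1, -1, -1):
            acc = np.zeros((M, N))
            flat = np.ravel_multi_index(
                (np.repeat(np.arange(M), N), parents[t + 1].ravel()), (M, N)
            )
            np.add.at(acc.ravel(), flat, s[t + 1].ravel())
            s[t] = acc
    else:
        d = system.dim
        # the Gaussian normalizing constant cancels between the transition
        # density and the particle predictive density, so work with the
        # exponent -||x_{t+1} - F(x_t)||^2 / (2 sigma_u) only
        with np.errstate(divide="ignore"):
            log_ws = np.log(ws)
        log_s_next = np.log(np.maximum(s[T], 1e-300))
        for t in range(T - 1, -1, -1):
            mean = forward_operator_batch(
                xs[t], th[t + 1][:, None, :], system, integ
            )
            log_s_t = np.empty((M, N))
            with np.errstate(invalid="ignore", over="ignore"):
                for m in range(M):
                    # pairwise squared distances (n, k), per-dimension accumulation
                    sq = np.zeros((N, N))
                    for i in range(d):
                        diff = xs[t + 1][m, None, :, i] - mean[m, :, None, i]
                        sq += diff * diff
                    A = sq
                    A *= -0.5 / noise.sigma_u
                    np.nan_to_num(A, copy=False, nan=-np.inf)
                    # log particle predictive density of each x_{t+1}(k)
                    A += log_ws[t, m][:, None]
                    cmax = A.max(axis=0)
                    cmax_safe = np.where(np.isfinite(cmax), cmax, 0.0)
                    log_pred = cmax_safe + np.log(
                        np.exp(A - cmax_safe[None, :]).sum(axis=0) + 1e-300
                    )
                    # A rows already carry log w_t(n), which is constant in k,
                    # so the row log-sum-exp directly gives log w~_t(n)
                    A += (log_s_next[m] - log_pred)[None, :]
                    rmax = A.max(axis=1)
                    rmax_safe = np.where(np.isfinite(rmax), rmax, 0.0)
                    log_s_t[m] = rmax_safe + np.log(
                        np.exp(A - rmax_safe[:, None]).sum(axis=1) + 1e-300
                    )
                    np.nan_to_num(log_s_t[m], copy=False, nan=-np.inf)
            s_t, _, degen = _normalize_log(log_s_t, axis=1)
            if degen.any():
                logger.warning(
                    "smoother degenerate at step %d for %d blocks", t, int(degen.sum())
                )
            s[t] = s_t
            log_s_next = np.log(np.maximum(s_t, 1e-300))

    v_T = hist.outer_weights[T]
    smoothed = v_T[None, :, None] * s

    theta_hat = v_T @ th[T]
    sigma_theta = np.sqrt(v_T @ (th[T] - theta_hat) ** 2)
    state_mean = np.einsum("tmn,tmnd->td", smoothed, xs)

    return SmoothedEnsemble(
        states=xs,
        thetas=th,
        parents=parents,
        smoothed_weights=smoothed,
        outer_weights=v_T,
        theta_hat=theta_hat,
        sigma_theta=sigma_theta,
        state_mean=state_mean,
        history=hist,
    )


def point_estimates(se: SmoothedEnsemble):
    """(theta_hat, sigma_theta, per-step smoothed state means)."""
    return se.theta_hat, se.sigma_theta, se.state_mean
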