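"""Independent closed-form oracles used by the tests.

These deliberately avoid every cfdyn code path they are used to check.
"""

import numpy as np

import cfdyn as c


def make_ar1_system(a: float = 0.9) -> c.SystemSpec:
    """Scalar linear-Gaussian SSM with exact forward map F(x) = a x."""
    return c.SystemSpec(
        name="ar1",
        dim=1,
        drift=lambda s, th: np.zeros_like(s),
        theta_true=(a,),
        prior_bounds=[(0.5, 1.0)],
        x0_default=(0.0,),
        forward_map=lambda s, th: th[..., 0:1] * s,
    )


def simulate_ar1(a, su, sw, T, seed):
    """Direct simulation of the scalar linear-Gaussian SSM."""
    rng = np.random.default_rng(seed)
    x = np.zeros(T + 1)
    for t in range(1, T + 1):
        x[t] = a * x[t - 1] + np.sqrt(su) * rng.standard_normal()
    y = x + np.sqrt(sw) * rng.standard_normal(T + 1)
    return x, y


def kalman_rts(y, a, su, sw, m0, P0):
    """Exact scalar Kalman filter and Rauch-Tung-Striebel smoother.

    Returns (filtered means, filtered vars, smoothed means, smoothed vars)
    for the model x_t = a x_{t-1} + N(0, su), y_t = x_t + N(0, sw), with
    a N(m0, P0) prior on x_0 updated by y_0.
    """
    T = len(y) - 1
    mf = np.zeros(T + 1)
    Pf = np.zeros(T + 1)
    m_pred, P_pred = m0, P0
    for t in range(T + 1):
        K = P_pred / (P_pred + sw)
        mf[t] = m_pred + K * (y[t] - m_pred)
        Pf[t] = (1 - K) * P_pred
        m_pred, P_pred = a * mf[t], a * a * Pf[t] + su
    ms = mf.copy()
    Ps = Pf.copy()
    for t in range(T - 1, -1, -1):
        Pp = a * a * Pf[t] + su
        G = Pf[t] * a / Pp
        ms[t] = mf[t] + G * (ms[t + 1] - a * mf[t])
        Ps[t] = Pf[t] + G * G * (Ps[t + 1] - Pp)
    return mf, Pf, ms, Ps


def filtered_means_from_history(hist):
    """Posterior state means per step implied by a FilterHistory."""
    joint = hist.outer_weights[:, :, None] * hist.inner_weights
    return np.einsum("tmn,tmnd->td", joint, hist.states)


def inner_ess(weights):
    """Effective sample size of a normalized weight vector (last axis)."""
    return 1.0 / np.sum(weights**2, axis=-1)
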