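"""Numba-compiled inner loops for the neural and hemodynamic integrators.

These kernels carry the per-step arithmetic only; all validation, seeding
and shape handling lives in :mod:`pmfm.dynamics`. Noise is pre-drawn by the
caller so that the stochastic integrator is reproducible independently of
the JIT compilation path.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def euler_maruyama_mfm(
    s0: np.ndarray,
    noise: np.ndarray,
    C: np.ndarray,
    w: np.ndarray,
    I_ext: np.ndarray,
    sigma: np.ndarray,
    G: float,
    J: float,
    a: float,
    b: float,
    d: float,
    r_kin: float,
    tau_s: float,
    dt: float,
) -> np.ndarray:
    """Integrate dS_i = [-S_i/tau_s + r(1-S_i)H(x_i)]dt + sigma_i dW_i.

    x_i = w_i*J*S_i + G*J*sum_j C_ij S_j + I_i. Returns S with shape
    (N, n_steps+1) including the initial state; S clamped to [0, 1].
    """
    N = s0.shape[0]
    n_steps = noise.shape[1]
    S = np.empty((N, n_steps + 1))
    S[:, 0] = s0
    sqdt = np.sqrt(dt)
    s = s0.copy()
    for t in range(n_steps):
        coupling = C @ s
        for i in range(N):
            x = w[i] * J * s[i] + G * J * coupling[i] + I_ext[i]
            u = a * x - b
            # transfer function with removable singularity at u == 0
            if np.abs(u) < 1e-9:
                H = 1.0 / d
            else:
                H = u / (1.0 - np.exp(-d * u))
            drift = -s[i] / tau_s + r_kin * (1.0 - s[i]) * H
            si = s[i] + dt * drift + sigma[i] * sqdt * noise[i, t]
            if si < 0.0:
                si = 0.0
            elif si > 1.0:
                si = 1.0
            s[i] = si
        S[:, t + 1] = s
    return S


@njit(cache=True)
def euler_balloon(
    z: np.ndarray,
    dt: float,
    kappa: float,
    gamma: float,
    tau: float,
    alpha: float,
    rho: float,
    V0: float,
    k1: float,
    k2: float,
    k3: float,
) -> np.ndarray:
    """Balloon-Windkessel model driven by neural activity z (N x K).

    State per region: vasodilatory signal s, inflow f, volume v,
    deoxyhemoglobin q, initialized at rest (s=0, f=v=q=1). Returns BOLD
    (N x K); entry k is the BOLD of the state after integrating through
    z[:, :k] (entry 0 is the resting baseline). Emits NaN rows on
    non-positive v or q so the caller can raise a diagnostic error.
    """
    N, K = z.shape
    bold = np.empty((N, K))
    ia = 1.0 / alpha
    for i in range(N):
        s = 0.0
        f = 1.0
        v = 1.0
        q = 1.0
        bold[i, 0] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
        for k in range(1, K):
            zi = z[i, k - 1]
            ds = zi - kappa * s - gamma * (f - 1.0)
            df = s
            fv = v ** ia
            dv = (f - fv) / tau
            E = 1.0 - (1.0 - rho) ** (1.0 / f)
            dq = (f * E / rho - fv * q / v) / tau
            s = s + dt * ds
            f = f + dt * df
            v = v + dt * dv
            q = q + dt * dq
            if v <= 0.0 or q <= 0.0 or not (np.isfinite(v) and np.isfinite(q)):
                for kk in range(k, K):
                    bold[i, kk] = np.nan
                break
            bold[i, k] = V0 * (k1 * (1.0 - q) + k2 * (1.0 - q / v) + k3 * (1.0 - v))
    return bold
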