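"""Low-level numeric kernels.

The right-hand side and fixed-step integrator loops live here in a
numba-compatible form. When numba is importable the hot loops are jit-compiled
(cached on disk); otherwise the same pure-Python implementations run, just
slower. Nothing here knows about dataclasses — parameters arrive as the flat
float vector produced by ``ModelParameters.to_array()``:

    [r, b, c, beta0, e, a, alpha1, alpha2, sigma, d, c1, c2,
     mu, m, theta, CS, CP, x_dynamic_flag]
"""

from __future__ import annotations

import numpy as np

try:  # optional acceleration
    from numba import njit

    HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def deco(f):
            return f

        return deco


@njit(cache=True)
def rhs(y, p):
    """Time derivative of (S, I, P, x).

    dS/dt = [r − bS − cI − β(x)·I/(a+S) − α1·P/(σ+S)]·S
    dI/dt = [β(x)·S/(a+S) − α2·P/(d+I) − μ]·I
    dP/dt = [(c1·α1·S/(σ+S) + c2·α2·I/(d+I))·P/(θ+P) − m]·P
    dx/dt = x(1−x)·(−CS·S + I + CP·P)   (when the dynamic flag is set)

    β(x) = max(β0·(1−e·x), 0); the Allee factor P/(θ+P) is taken as 1 when
    θ=0 so that the Allee-free model is recovered exactly.
    """
    r, b, c, beta0, e, a = p[0], p[1], p[2], p[3], p[4], p[5]
    alpha1, alpha2, sigma, d, c1, c2 = p[6], p[7], p[8], p[9], p[10], p[11]
    mu, m, theta, CS, CP = p[12], p[13], p[14], p[15], p[16]
    x_dyn = p[17]

    S, I, P, x = y[0], y[1], y[2], y[3]

    beta = beta0 * (1.0 - e * x)
    if beta < 0.0:
        beta = 0.0

    if theta == 0.0:
        allee = 1.0
    else:
        allee = P / (theta + P)

    fS = S / (sigma + S)   # Holling-II saturation, susceptible prey
    fI = I / (d + I)       # Holling-II saturation, infected prey

    out = np.empty(4)
    out[0] = (r - b * S - c * I - beta * I / (a + S) - alpha1 * P / (sigma + S)) * S
    out[1] = (beta * S / (a + S) - alpha2 * P / (d + I) - mu) * I
    out[2] = ((c1 * alpha1 * fS + c2 * alpha2 * fI) * allee - m) * P
    if x_dyn != 0.0:
        out[3] = x * (1.0 - x) * (-CS * S + I + CP * P)
    else:
        out[3] = 0.0
    return out


@njit(cache=True)
def _rk4_step(y, p, dt):
    k1 = rhs(y, p)
    k2 = rhs(y + 0.5 * dt * k1, p)
    k3 = rhs(y + 0.5 * dt * k2, p)
    k4 = rhs(y + dt * k3, p)
    return y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


@njit(cache=True)
def rk4_integrate(y0, p, t_grid, dt):
    """Classical RK4 with a fixed internal step, sampled on ``t_grid``.

    The internal step is shortened on the final sub-interval so every report
    time is hit exactly. Returns an array of shape (len(t_grid), 4).
    """
    n = t_grid.shape[0]
    out = np.empty((n, 4))
    y = y0.copy()
    out[0] = y
    t = t_grid[0]
    for i in range(1, n):
        target = t_grid[i]
        while t < target - 1e-12:
            h = dt
            if t + h > target:
                h = target - t
            y = _rk4_step(y, p, h)
            t += h
        out[i] = y
    return out


@njit(cache=True)
def lyapunov_benettin(y0, p, dt, t_transient, t_window, renorm_dt, d0):
    """Largest Lyapunov exponent by two-trajectory Benettin renormalisation.

    A companion trajectory offset by ``d0`` is integrated alongside the
    reference; every ``renorm_dt`` time units the separation is measured,
    its log-growth accumulated, and the companion is rescaled back to d0
    along the current separation direction.

    Returns (exponent, ok_flag); ok_flag is False when the reference
    trajectory collapses (all populations below 1e-12), where the exponent
    is not meaningful.
    """
    y = y0.copy()
    t = 0.0
    while t < t_transient - 1e-12:
        h = dt
        if t + h > t_transient:
            h = t_transient - t
        y = _rk4_step(y, p, h)
        t += h

    z = y.copy()
    z[0] += d0  # perturb along S
    log_sum = 0.0
    n_renorm = int(round(t_window / renorm_dt))
    for _ in range(n_renorm):
        tau = 0.0
        while tau < renorm_dt - 1e-12:
            h = dt
            if tau + h > renorm_dt:
                h = renorm_dt - tau
            y = _rk4_step(y, p, h)
            z = _rk4_step(z, p, h)
            tau += h
        diff = z - y
        dist = np.sqrt(np.sum(diff * diff))
        if dist <= 0.0 or not np.isfinite(dist):
            return 0.0, False
        log_sum += np.log(dist / d0)
        z = y + diff * (d0 / dist)
    if y[0] < 1e-12 and y[1] < 1e-12 and y[2] < 1e-12:
        return 0.0, False
    return log_sum / (n_renorm * renorm_dt), True
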