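"""Exact convolution of a piecewise-linear input with exponential kernels.

The tissue response of a linear compartment chain is a sum of exponentials
h(t) = sum_j A_j exp(-a_j t).  Against a piecewise-linear input the
convolution integral has a closed form on every input segment, so the curve
can be propagated knot-to-knot exactly and evaluated anywhere in between.
All times here are in the caller's unit (minutes for PET, also minutes for
perfusion CT); rate constants a_j are in the reciprocal unit.
"""

import numba
import numpy as np

__all__ = ["expconv_eval", "cumulative_pl_integral"]


@numba.njit(cache=True)
def _phis(alpha, dt):
    """exp(-a*dt), int_0^dt e^{-a(dt-u)}du, int_0^dt u e^{-a(dt-u)}du."""
    x = alpha * dt
    if x < 1e-6:
        # series expansions; avoids cancellation for tiny exponents
        e = 1.0 - x + 0.5 * x * x
        p1 = dt * (1.0 - 0.5 * x + x * x / 6.0)
        p2 = dt * dt * (0.5 - x / 3.0 + x * x / 8.0)
    else:
        e = np.exp(-x)
        p1 = -np.expm1(-x) / alpha
        p2 = (dt - p1) / alpha
    return e, p1, p2


@numba.njit(cache=True)
def expconv_eval(t_knots, c_knots, alphas, t_eval):
    """y_j(t) = int_0^t c(s) exp(-alphas[j] (t-s)) ds at each t in t_eval.

    c is piecewise linear through (t_knots, c_knots); t_knots[0] must be 0
    and t_eval must lie within [t_knots[0], t_knots[-1]].  Returns an array
    of shape (len(t_eval), len(alphas)); entries for t <= 0 are 0.
    """
    nk = t_knots.shape[0]
    na = alphas.shape[0]
    nt = t_eval.shape[0]
    # cumulative convolution value at every knot, per kernel
    Y = np.zeros((nk, na))
    for k in range(nk - 1):
        dt = t_knots[k + 1] - t_knots[k]
        a0 = c_knots[k]
        b = (c_knots[k + 1] - c_knots[k]) / dt
        for j in range(na):
            e, p1, p2 = _phis(alphas[j], dt)
            Y[k + 1, j] = Y[k, j] * e + a0 * p1 + b * p2
    out = np.zeros((nt, na))
    for i in range(nt):
        t = t_eval[i]
        if t <= t_knots[0]:
            continue
        k = np.searchsorted(t_knots, t) - 1
        if k >= nk - 1:
            k = nk - 2
        dt = t - t_knots[k]
        a0 = c_knots[k]
        b = (c_knots[k + 1] - c_knots[k]) / (t_knots[k + 1] - t_knots[k])
        for j in range(na):
            e, p1, p2 = _phis(alphas[j], dt)
            out[i, j] = Y[k, j] * e + a0 * p1 + b * p2
    return out


@numba.njit(cache=True)
def cumulative_pl_integral(t_knots, c_knots, t_eval):
    """F(t) = int_{t_knots[0]}^{t} c(s) ds for piecewise-linear c.

    t below the first knot clamps to F = 0; t above the last knot
    extrapolates with the last knot value held constant.
    """
    nk = t_knots.shape[0]
    F = np.zeros(nk)
    for k in range(nk - 1):
        F[k + 1] = F[k] + 0.5 * (c_knots[k] + c_knots[k + 1]) * (t_knots[k + 1] - t_knots[k])
    out = np.zeros(t_eval.shape[0])
    for i in range(t_eval.shape[0]):
        t = t_eval[i]
        if t <= t_knots[0]:
            continue
        if t >= t_knots[-1]:
            out[i] = F[-1] + c_knots[-1] * (t - t_knots[-1])
            continue
        k = np.searchsorted(t_knots, t) - 1
        dt = t - t_knots[k]
        b = (c_knots[k + 1] - c_knots[k]) / (t_knots[k + 1] - t_knots[k])
        out[i] = F[k] + c_knots[k] * dt + 0.5 * b * dt * dt
    return out
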