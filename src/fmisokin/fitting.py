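"""Weighted least-squares fitting of compartment models to tumor TACs.

The objective is the weighted sum of squares over frames,

    WSS = sum_i w_i (C_PET(t_i) - C_model(t_i))^2,
    w_i = dt_i * exp(-lambda * t_i) / C_PET(t_i),

with dt_i the frame duration (seconds), t_i the frame mid-time
post-injection and lambda the F-18 decay constant: the weight is the usual
count-statistics form for decay-corrected data.  Minimization runs from many
random starting points (100 by default) to reach a global rather than local
optimum; each start is refined with a trust-region Levenberg-Marquardt
variant honoring box bounds, and the best converged start is polished at
tight tolerance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import least_squares

from . import models as M
from .tac import FrameSchedule, InputFunction, TimeActivityCurve

__all__ = [
    "compute_weights",
    "default_bounds",
    "fit_model",
    "loo_refit",
    "FitResult",
    "FitFailureError",
    "WEIGHT_FLOOR_EPS",
]

#: Relative floor applied to C_PET in the weight denominator: early frames can
#: be zero or negative from reconstruction noise, where the raw weight formula
#: is undefined.
WEIGHT_FLOOR_EPS = 1e-3

#: Box bounds for the free parameters ("suitably constrained" starting values):
#: physiological ranges for thoracic tumors.
VB_BOUNDS = (0.0, 0.5)
K1_BOUNDS = (1e-4, 2.0)
K_BOUNDS = (1e-5, 2.0)


class FitFailureError(RuntimeError):
    """No start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics


def compute_weights(
    tac: TimeActivityCurve,
    lambda_f18: float = M.LAMBDA_F18_PER_MIN,
    floor_eps: float = WEIGHT_FLOOR_EPS,
) -> np.ndarray:
    """Per-frame fit weights w_i = dt_i exp(-lambda t_i) / C_PET(t_i).

    Durations in seconds, mid-times in minutes against ``lambda_f18`` (min^-1).
    Non-positive activities are floored at ``floor_eps * max(C)``;
    pre-injection frames get weight 0 (they carry no model signal but keep
    frame indices aligned with files).
    """
    c = tac.activity
    c_max = c.max(initial=0.0)
    if c_max <= 0:
        raise ValueError("all-zero or negative TAC: no weightable signal")
    mid_min = tac.schedule.mid_s / 60.0
    denom = np.maximum(c, floor_eps * c_max)
    w = tac.schedule.duration_s * np.exp(-lambda_f18 * mid_min) / denom
    w[mid_min <= 0] = 0.0
    return w


def default_bounds(model: M.ModelSpec):
    """(lower, upper) arrays over the free parameter vector (vB, K1, k...)."""
    lo = np.array([VB_BOUNDS[0], K1_BOUNDS[0]] + [K_BOUNDS[0]] * (model.n_rates - 1))
    hi = np.array([VB_BOUNDS[1], K1_BOUNDS[1]] + [K_BOUNDS[1]] * (model.n_rates - 1))
    return lo, hi


def draw_starts(model: M.ModelSpec, n: int, rng: np.random.Generator, bounds=None) -> np.ndarray:
    """Random starting vectors: v_B uniform, rate constants log-uniform."""
    lo, hi = bounds if bounds is not None else default_bounds(model)
    out = np.empty((n, model.n_free))
    out[:, 0] = rng.uniform(lo[0], hi[0], size=n)
    log_lo, log_hi = np.log(lo[1:]), np.log(hi[1:])
    out[:, 1:] = np.exp(rng.uniform(log_lo, log_hi, size=(n, model.n_free - 1)))
    return out


@dataclasses.dataclass
class FitResult:
    """Best fit over all starts, with multi-start provenance."""

    model: M.ModelSpec
    params: M.KineticParameters
    wss: float
    residuals: np.ndarray  # measured - modeled, per frame
    weights: np.ndarray
    n_starts: int
    n_converged: int
    best_start_index: int
    seed: int
    bounds: tuple
    modeled: np.ndarray

    def as_dict(self) -> dict:
        d = {
            "model": self.model.name,
            "wss": self.wss,
            "n_starts": self.n_starts,
            "n_converged": self.n_converged,
            "best_start_index": self.best_start_index,
            "seed": self.seed,
            "params": self.params.as_dict(),
        }
        if not self.model.reversible:
            d["k_flux"] = self.params.k_flux
        return d


def make_predictor(
    model: M.ModelSpec,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    vb_mixing: str = "scaled",
):
    """Closure mapping a free-parameter vector to frame-averaged model values.

    Precomputes input knots and quadrature nodes once; the fitter calls this
    thousands of times.
    """
    knots_min = input_fn.knots_s / 60.0
    values = input_fn.knot_values
    tq = M._frame_quad_times(schedule)
    flat = np.ascontiguousarray(tq.ravel())
    cb = np.interp(flat, knots_min, values)
    cb[flat <= 0] = 0.0
    shape = tq.shape
    glw = M._GL_W

    def predict(free_vec: np.ndarray) -> np.ndarray:
        params = M.KineticParameters.from_free(model, free_vec)
        h = M.impulse_response(model, params)
        if h.degenerate:
            A, b = M._rate_matrix(model.n_tissue, params.rates)
            tissue = M._tissue_curve_expm(A, b, knots_min, values, flat)
        else:
            conv = M.expconv_eval(knots_min, values, np.ascontiguousarray(h.alphas), flat)
            tissue = conv @ h.amps
        scale = (1.0 - params.v_b) if vb_mixing == "scaled" else 1.0
        total = scale * tissue + params.v_b * cb
        return total.reshape(shape) @ glw

    return predict


def fit_model(
    model,
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    n_starts: int = 100,
    bounds=None,
    seed: int = 0,
    extra_starts=None,
    weights=None,
    vb_mixing: str = "scaled",
    max_nfev_per_start: int = 400,
    polish: bool = True,
) -> FitResult:
    """Multi-start weighted least-squares fit of one model to one TAC.

    ``extra_starts`` prepends user-supplied starting vectors (e.g. a nested
    model's solution, or a warm start) to the ``n_starts`` random draws.
    Deterministic for a fixed seed.
    """
    if isinstance(model, str):
        model = M.model_spec(model)
    lo, hi = bounds if bounds is not None else default_bounds(model)
    w = compute_weights(tac) if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w)
    predict = make_predictor(model, input_fn, tac.schedule, vb_mixing)
    meas = tac.activity

    def resid(x):
        return sw * (meas - predict(x))

    rng = np.random.default_rng(seed)
    starts = draw_starts(model, n_starts, rng, (lo, hi))
    if extra_starts is not None:
        extra = np.atleast_2d(np.asarray(extra_starts, float))
        starts = np.vstack([extra, starts])
    # keep starts strictly inside the box so TRF does not stall on the boundary
    span = hi - lo
    starts = np.clip(starts, lo + 1e-12 * span, hi - 1e-12 * span)

    results = []
    statuses = []
    for i, x0 in enumerate(starts):
        sol = least_squares(
            resid,
            x0,
            bounds=(lo, hi),
            method="trf",
            ftol=1e-10,
            xtol=1e-10,
            gtol=1e-8,
            max_nfev=max_nfev_per_start,
        )
        statuses.append(sol.status)
        if sol.status > 0:
            results.append((2.0 * sol.cost, i, sol.x))
    if not results:
        raise FitFailureError(
            f"no converged start among {len(starts)} for {model.name}",
            diagnostics={"statuses": statuses},
        )
    best_wss = min(r[0] for r in results)
    # ties broken by the smaller parameter-vector norm, for reproducibility
    tied = [r for r in results if r[0] <= best_wss * (1.0 + 1e-10) + 1e-300]
    wss, idx, x_best = min(tied, key=lambda r: (np.linalg.norm(r[2]), r[1]))
    if polish:
        sol = least_squares(
            resid,
            x_best,
            bounds=(lo, hi),
            method="trf",
            ftol=1e-15,
            xtol=1e-15,
            gtol=1e-12,
            max_nfev=5000,
        )
        if sol.status > 0 and 2.0 * sol.cost <= wss:
            wss, x_best = 2.0 * sol.cost, sol.x
    modeled = predict(x_best)
    residuals = meas - modeled
    return FitResult(
        model=model,
        params=M.KineticParameters.from_free(model, x_best),
        wss=float(np.sum(w * residuals**2)),
        residuals=residuals,
        weights=w,
        n_starts=len(starts),
        n_converged=sum(1 for s in statuses if s > 0),
        best_start_index=int(idx),
        seed=seed,
        bounds=(lo.copy(), hi.copy()),
        modeled=modeled,
    )


def loo_refit(
    model,
    tac: TimeActivityCurve,
    input_fn: InputFunction,
    leave_out_index: int,
    warm_start: FitResult,
    n_restarts: int = 9,
    seed: int = 0,
):
    """Refit on all frames but one; predict the model value at the omitted frame.

    Warm-started from the full-data best fit plus ``n_restarts`` random
    restarts.  Returns ``(prediction, fold_fit)`` where the prediction is the
    frame-averaged model value at the omitted frame.
    """
    if isinstance(model, str):
        model = M.model_spec(model)
    T = tac.schedule.n_frames
    if T - 1 < model.n_free + 1:
        raise ValueError(f"{T - 1} frames cannot determine {model.n_free} parameters")
    reduced = tac.drop_frame(leave_out_index)
    fold = fit_model(
        model,
        reduced,
        input_fn,
        n_starts=n_restarts,
        seed=seed,
        extra_starts=[warm_start.params.free_values],
    )
    predict_full = make_predictor(model, input_fn, tac.schedule)
    pred = predict_full(fold.params.free_values)[leave_out_index]
    return float(pred), fold
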