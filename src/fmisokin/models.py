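"""Linear-chain compartment models for dynamic FMISO PET.

A model ``xCyK`` is a linear chain of ``x`` tissue compartments (excluding
blood-borne tracer) with ``y`` rate constants: K1 carries tracer from blood
into the first compartment, k2 returns it, k3/k4 exchange with the second
compartment, and so on.  Irreversible variants (odd ``y``) fix the terminal
"bound -> unbound" return rate at zero, so tracer reaching the last
compartment is trapped — the usual description of FMISO binding in hypoxic
cells.  Rate-constant names carry an ``-xC`` suffix except for the
three-tissue models (K1, k2 ... k6), matching common usage.

Units: K1 in mL·min⁻¹·mL⁻¹, all k's in min⁻¹, v_B dimensionless.  The
model curve mixes tissue and blood signal as (1 − v_B)·C_tissue + v_B·C_B
("scaled" convention; an additive convention is switchable).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import scipy.linalg

from ._expconv import expconv_eval
from .tac import FrameSchedule, InputFunction, TimeActivityCurve

__all__ = [
    "ModelSpec",
    "KineticParameters",
    "MODELS",
    "MODEL_NAMES",
    "model_spec",
    "ImpulseResponse",
    "impulse_response",
    "model_tac",
    "k_flux_2c",
    "k_flux_3c",
    "steady_flux_equivalence",
    "LAMBDA_F18_PER_MIN",
    "F18_HALF_LIFE_MIN",
]

#: Half-life of ¹⁸F in minutes and the derived decay constant λ = ln2 / T½.
F18_HALF_LIFE_MIN = 109.77
LAMBDA_F18_PER_MIN = math.log(2.0) / F18_HALF_LIFE_MIN


class FluxUndefinedError(ZeroDivisionError):
    """Flux constant requested where its denominator vanishes."""


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """One member of the xCyK family."""

    name: str
    n_tissue: int  # x
    n_rates: int  # y = 2x (reversible) or 2x - 1 (irreversible)

    def __post_init__(self):
        x, y = self.n_tissue, self.n_rates
        if x not in (2, 3, 4) or y not in (2 * x, 2 * x - 1):
            raise ValueError(f"invalid model {self.name}: x={x}, y={y}")

    @property
    def reversible(self) -> bool:
        return self.n_rates == 2 * self.n_tissue

    @property
    def rate_names(self) -> tuple:
        suffix = "" if self.n_tissue == 3 else f"-{self.n_tissue}C"
        names = [f"K1{suffix}"] + [f"k{i}{suffix}" for i in range(2, 2 * self.n_tissue + 1)]
        return tuple(names)

    @property
    def free_param_names(self) -> tuple:
        """v_B plus the y free rate constants, in fit order."""
        return ("vB",) + self.rate_names[: self.n_rates]

    @property
    def n_free(self) -> int:
        return 1 + self.n_rates


MODELS = {
    s.name: s
    for s in (
        ModelSpec("2C3K", 2, 3),
        ModelSpec("2C4K", 2, 4),
        ModelSpec("3C5K", 3, 5),
        ModelSpec("3C6K", 3, 6),
        ModelSpec("4C7K", 4, 7),
        ModelSpec("4C8K", 4, 8),
    )
}
MODEL_NAMES = tuple(MODELS)


def model_spec(name: str) -> ModelSpec:
    try:
        return MODELS[name]
    except KeyError:
        raise KeyError(f"unknown model {name!r}; choose from {MODEL_NAMES}") from None


@dataclasses.dataclass
class KineticParameters:
    """v_B plus the full rate-constant chain of one model.

    ``rates`` always has length 2x (K1, k2, ..., k_{2x}); for irreversible
    models the terminal return rate is exactly 0.
    """

    model: ModelSpec
    v_b: float
    rates: np.ndarray

    def __post_init__(self):
        self.rates = np.asarray(self.rates, dtype=float)
        x = self.model.n_tissue
        if self.rates.shape != (2 * x,):
            raise ValueError(f"expected {2 * x} rates for {self.model.name}")
        if not 0.0 <= self.v_b <= 1.0:
            raise ValueError(f"v_B must be in [0, 1], got {self.v_b}")
        if np.any(self.rates < 0):
            raise ValueError("rate constants must be non-negative")
        if not self.model.reversible and self.rates[-1] != 0.0:
            raise ValueError(f"{self.model.name} requires the terminal return rate fixed at 0")

    @classmethod
    def from_free(cls, model: ModelSpec, free_values) -> "KineticParameters":
        """Build from the fit vector (vB, K1, k2, ..., k_y)."""
        free_values = np.asarray(free_values, dtype=float)
        if free_values.shape != (model.n_free,):
            raise ValueError(f"expected {model.n_free} values for {model.name}")
        rates = np.zeros(2 * model.n_tissue)
        rates[: model.n_rates] = free_values[1:]
        return cls(model, float(free_values[0]), rates)

    @property
    def free_values(self) -> np.ndarray:
        return np.concatenate([[self.v_b], self.rates[: self.model.n_rates]])

    def as_dict(self) -> dict:
        return dict(zip(self.model.free_param_names, self.free_values))

    @property
    def k_flux(self) -> float:
        """Net trapping constant; only defined for irreversible models."""
        if self.model.reversible:
            raise ValueError(f"{self.model.name} is reversible; no flux constant")
        r = self.rates
        if self.model.n_tissue == 2:
            return k_flux_2c(r[0], r[1], r[2])
        if self.model.n_tissue == 3:
            return k_flux_3c(r[0], r[1], r[2], r[3], r[4])
        return steady_flux_equivalence(self.model, self)


def k_flux_2c(K1: float, k2: float, k3: float) -> float:
    """Flux constant of the irreversible two-tissue model: K1·k3/(k2+k3)."""
    if K1 == 0:
        return 0.0
    if k2 + k3 == 0:
        raise FluxUndefinedError("k2 + k3 = 0: flux constant undefined")
    return K1 * k3 / (k2 + k3)


def k_flux_3c(K1: float, k2: float, k3: float, k4: float, k5: float) -> float:
    """Flux constant of the irreversible three-tissue model.

    k_flux = K1·k3·k5 / (k2·k4 + k2·k5 + k3·k5)
    """
    if K1 == 0:
        return 0.0
    denom = k2 * k4 + k2 * k5 + k3 * k5
    if denom == 0:
        raise FluxUndefinedError("k2k4 + k2k5 + k3k5 = 0: flux constant undefined")
    return K1 * k3 * k5 / denom


def _rate_matrix(x: int, rates: np.ndarray):
    """Chain rate matrix A and input vector b: dC/dt = A C + b C_B(t)."""
    A = np.zeros((x, x))
    # exit rates: compartment i loses via backward rate k_{2i} and forward k_{2i+1}
    for i in range(x):
        back = rates[2 * i + 1]  # k2, k4, k6, k8
        fwd = rates[2 * i + 2] if i < x - 1 else 0.0  # k3, k5, k7
        A[i, i] = -(back + fwd)
        if i < x - 1:
            A[i + 1, i] = fwd  # forward transfer
            A[i, i + 1] = rates[2 * i + 3]  # return from the next compartment
    b = np.zeros(x)
    b[0] = rates[0]  # K1
    return A, b


@dataclasses.dataclass
class ImpulseResponse:
    """Sum-of-exponentials tissue kernel h(t) = Σ amps·exp(−alphas·t)."""

    amps: np.ndarray
    alphas: np.ndarray
    degenerate: bool = False  # eigenbasis ill-conditioned; use the expm path

    def __call__(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, float))
        out = np.einsum("j,tj->t", self.amps, np.exp(-np.outer(t, self.alphas)))
        return out

    @property
    def trapping_coefficient(self) -> float:
        """Coefficient of the non-decaying (α = 0) term."""
        scale = max(self.alphas.max(initial=0.0), 1.0)
        mask = np.abs(self.alphas) < 1e-12 * scale
        return float(self.amps[mask].sum())


def impulse_response(model: ModelSpec, params: KineticParameters) -> ImpulseResponse:
    """Tissue response to a unit-impulse blood input, as exponential pairs.

    Derived from the eigen-decomposition of the chain's rate matrix.  If the
    eigenbasis is ill-conditioned (near-degenerate eigenvalues) the result is
    flagged ``degenerate`` and curve evaluation falls back to exact
    matrix-exponential stepping.
    """
    x = model.n_tissue
    rates = params.rates
    if rates[0] == 0.0 or np.all(rates == 0):
        return ImpulseResponse(np.zeros(1), np.zeros(1))
    A, b = _rate_matrix(x, rates)
    lam, V = np.linalg.eig(A)
    if np.iscomplexobj(lam) and np.abs(lam.imag).max() > 1e-12 * max(np.abs(lam.real).max(), 1.0):
        return ImpulseResponse(np.zeros(x), np.zeros(x), degenerate=True)
    lam, V = lam.real, V.real
    cond = np.linalg.cond(V)
    if not np.isfinite(cond) or cond > 1e8:
        return ImpulseResponse(np.zeros(x), np.zeros(x), degenerate=True)
    W = np.linalg.inv(V)
    amps = (V.sum(axis=0)) * (W @ b)
    alphas = -lam
    alphas[np.abs(alphas) < 1e-14] = 0.0
    return ImpulseResponse(amps, alphas)


# 5-point Gauss–Legendre rule on [0, 1]; sub-frame accuracy matters for the
# 5-s frames spanning the bolus peak.
_GL_X, _GL_W = np.polynomial.legendre.leggauss(5)
_GL_X = 0.5 * (_GL_X + 1.0)
_GL_W = 0.5 * _GL_W


def _frame_quad_times(schedule: FrameSchedule):
    """Gauss–Legendre node times (minutes) per frame, shape (T, 5)."""
    start = schedule.start_s / 60.0
    dur = schedule.duration_s / 60.0
    return start[:, None] + np.outer(dur, _GL_X)


def _tissue_curve_expm(A, b, knots_min, values, t_eval_min):
    """Exact total tissue concentration via segment-wise matrix exponentials.

    Fallback for ill-conditioned eigenbases: the piecewise-linear input is
    integrated exactly with the augmented-matrix discretization.
    """
    x = A.shape[0]
    M = np.zeros((x + 2, x + 2))
    M[:x, :x] = A
    M[:x, x] = b
    M[x, x + 1] = 1.0
    t_eval = np.asarray(t_eval_min, float)
    order = np.argsort(t_eval)
    out = np.zeros_like(t_eval)
    state = np.zeros(x)
    seg = 0
    t_cur = knots_min[0]
    for idx in order:
        t = t_eval[idx]
        if t <= knots_min[0]:
            continue
        while seg < len(knots_min) - 2 and knots_min[seg + 1] <= t:
            state = _expm_step(M, state, knots_min, values, seg, knots_min[seg + 1] - knots_min[seg])
            seg += 1
            t_cur = knots_min[seg]
        state_t = _expm_step(M, state, knots_min, values, seg, t - t_cur)
        # keep `state` anchored at the segment start; only advance at knots
        out[idx] = state_t.sum()
    return out


def _expm_step(M, state, knots_min, values, seg, dt):
    x = M.shape[0] - 2
    slope = (values[seg + 1] - values[seg]) / (knots_min[seg + 1] - knots_min[seg])
    z = np.concatenate([state, [values[seg], slope]])
    z = scipy.linalg.expm(M * dt) @ z
    return z[:x]


def model_tac(
    model: ModelSpec,
    params: KineticParameters,
    input_fn: InputFunction,
    schedule: FrameSchedule,
    vb_mixing: str = "scaled",
) -> TimeActivityCurve:
    """Frame-averaged model TAC for the given blood input and schedule.

    Each frame value is the Gauss–Legendre average over the frame of
    (1 − v_B)·(C_B ⊗ h)(t) + v_B·C_B(t) (``vb_mixing="scaled"``) or
    C_tissue + v_B·C_B with ``vb_mixing="additive"``.  Frames entirely
    pre-injection are exactly 0.
    """
    if vb_mixing not in ("scaled", "additive"):
        raise ValueError(f"unknown vb_mixing {vb_mixing!r}")
    knots_min = input_fn.knots_s / 60.0
    values = input_fn.knot_values
    tq = _frame_quad_times(schedule)  # (T, 5) minutes
    flat = np.ascontiguousarray(tq.ravel())
    h = impulse_response(model, params)
    if h.degenerate:
        A, b = _rate_matrix(model.n_tissue, params.rates)
        tissue = _tissue_curve_expm(A, b, knots_min, values, flat)
    else:
        conv = expconv_eval(knots_min, values, np.ascontiguousarray(h.alphas), flat)
        tissue = conv @ h.amps
    cb = np.interp(flat, knots_min, values)
    cb[flat <= 0] = 0.0
    tissue_scale = (1.0 - params.v_b) if vb_mixing == "scaled" else 1.0
    total = tissue_scale * tissue + params.v_b * cb
    frame_vals = total.reshape(tq.shape) @ _GL_W
    return TimeActivityCurve(schedule, frame_vals, label=f"model:{model.name}")


def steady_flux_equivalence(model: ModelSpec, params: KineticParameters) -> float:
    """Trapping coefficient of the impulse response of an irreversible model.

    Equals the closed-form flux constant; useful as an internal consistency
    check and as the flux definition for the four-tissue chain.
    """
    if model.reversible:
        raise ValueError(f"{model.name} is reversible; trapping flux not applicable")
    h = impulse_response(model, params)
    if h.degenerate:
        raise ValueError("degenerate eigenbasis; trapping coefficient unavailable")
    return h.trapping_coefficient
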