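"""AATH perfusion-CT model, extraction-fraction relations, and correlations.

The adiabatic approximation to the tissue homogeneity (AATH) model treats
the capillary as a plug-flow tube: blood traverses the tumor with a finite
transit time Tc = v_P/BF, and contrast exchanges with the extravascular
extracellular space only at the venous outlet.  The tissue enhancement is

    C(t) = BF * (AIF x R)(t - t0)

with the residue function R(tau) = 1 for 0 <= tau < Tc and
R(tau) = E * exp(-(E*BF/v_e) * (tau - Tc)) afterwards, where the extraction
fraction for a cylindrical capillary is E = 1 - exp(-PS/BF).  The delivery
constant of a PET kinetic model is linked to blood flow by K1 = BF * E, so
for a freely extracted tracer (PS >> BF) K1 approaches BF.

CT attenuation enhancement (HU above baseline) is taken proportional to
iodine concentration; the proportionality constant cancels between the
tissue curve and the arterial input, so BF keeps absolute units.
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
from scipy import stats
from scipy.optimize import least_squares

from ._expconv import cumulative_pl_integral, expconv_eval

__all__ = [
    "AATHParameters",
    "AttenuationCurve",
    "extraction_fraction",
    "predicted_k1",
    "aath_tac",
    "fit_aath",
    "correlate",
    "CorrelationResult",
    "correlation_sweep",
]


def extraction_fraction(ps: float, bf: float) -> float:
    """E = 1 - exp(-PS/BF) for a cylindrical capillary.

    BF = 0 returns the limiting value 1.0 (any extractable tracer leaving
    infinitely slowly is fully extracted).
    """
    if ps < 0:
        raise ValueError(f"PS must be >= 0, got {ps}")
    if bf < 0:
        raise ValueError(f"BF must be >= 0, got {bf}")
    if bf == 0:
        return 1.0
    return -math.expm1(-ps / bf)


def predicted_k1(bf: float, ps: float) -> float:
    """K1 = BF * E: the delivery constant implied by flow and permeability."""
    if bf == 0:
        return 0.0
    return bf * extraction_fraction(ps, bf)


@dataclasses.dataclass
class AATHParameters:
    """AATH fit parameters, flow units mL·min⁻¹·mL⁻¹, delay seconds."""

    bf: float
    v_p: float
    v_e: float
    ps: float
    t0_s: float = 0.0

    def __post_init__(self):
        if min(self.bf, self.v_p, self.v_e, self.ps, self.t0_s) < 0:
            raise ValueError("AATH parameters must be non-negative")
        if self.v_p + self.v_e > 1.0 + 1e-12:
            raise ValueError("v_P + v_e must not exceed 1")

    @property
    def extraction(self) -> float:
        return extraction_fraction(self.ps, self.bf)

    @property
    def transit_time_min(self) -> float:
        """Capillary transit time Tc = v_P / BF, minutes."""
        if self.bf == 0:
            raise ZeroDivisionError("transit time undefined for BF = 0")
        return self.v_p / self.bf

    def as_dict(self) -> dict:
        return {
            "BF": self.bf,
            "vP": self.v_p,
            "ve": self.v_e,
            "PS": self.ps,
            "t0_s": self.t0_s,
            "E": self.extraction,
        }


@dataclasses.dataclass
class AttenuationCurve:
    """CT attenuation-vs-time samples (native 1 Hz cine sampling)."""

    times_s: np.ndarray
    values_hu: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, float)
        self.values_hu = np.asarray(self.values_hu, float)
        if self.times_s.shape != self.values_hu.shape or self.times_s.ndim != 1:
            raise ValueError("times and values must be equal-length 1-D arrays")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")

    def enhancement(self, baseline_window_s: float = 3.0):
        """Baseline-subtracted curve; baseline = mean of pre-enhancement samples."""
        mask = self.times_s <= self.times_s[0] + baseline_window_s
        base = float(self.values_hu[mask].mean())
        return self.values_hu - base, base


def aath_tac(params: AATHParameters, aif_times_s, aif_values, t_eval_s) -> np.ndarray:
    """AATH tissue enhancement at ``t_eval_s`` for a piecewise-linear AIF.

    Exact segment-wise evaluation: the plateau part of the residue integrates
    the AIF over a sliding transit-time window and the exponential tail uses
    the closed-form exponential convolution.
    """
    aif_t = np.asarray(aif_times_s, float) / 60.0  # minutes internally
    aif_c = np.asarray(aif_values, float)
    t = (np.asarray(t_eval_s, float) - params.t0_s) / 60.0
    if aif_t[0] > 0:
        aif_t = np.concatenate([[0.0], aif_t])
        aif_c = np.concatenate([[aif_c[0]], aif_c])
    # constant extension so evaluation never leaves the knot support
    tmax = max(float(t.max(initial=0.0)), aif_t[-1]) + 1.0
    aif_t = np.concatenate([aif_t, [tmax]])
    aif_c = np.concatenate([aif_c, [aif_c[-1]]])
    E = params.extraction
    if params.bf == 0:
        return np.zeros_like(t)
    tc = params.transit_time_min
    # intravascular plateau: integral of AIF over [t - Tc, t]
    F_t = cumulative_pl_integral(aif_t, aif_c, np.ascontiguousarray(t))
    F_tc = cumulative_pl_integral(aif_t, aif_c, np.ascontiguousarray(t - tc))
    intravasc = F_t - F_tc
    if E > 0:
        if params.v_e == 0:
            raise ValueError("v_e = 0 with nonzero extraction: degenerate washout")
        ke = E * params.bf / params.v_e
        # tail: E * int_0^{t-Tc} AIF(u) exp(-ke (t-Tc-u)) du
        shifted = np.ascontiguousarray(t - tc)
        conv = expconv_eval(aif_t, aif_c, np.array([ke]), shifted)[:, 0]
        tail = E * conv
    else:
        tail = 0.0
    out = params.bf * (intravasc + tail)
    out[t <= 0] = 0.0
    return out


#: Fit bounds: BF and PS in (0, 3] mL/min/mL, volumes in (0, 1], delay 0-15 s.
AATH_BOUNDS_LO = np.array([1e-3, 1e-3, 1e-3, 1e-3, 0.0])
AATH_BOUNDS_HI = np.array([3.0, 1.0, 1.0, 3.0, 15.0])


def fit_aath(
    tissue: AttenuationCurve,
    aif: AttenuationCurve,
    seed: int = 0,
    n_starts: int = 30,
    fit_delay: bool = True,
    baseline_window_s: float = 3.0,
):
    """Multi-start least-squares AATH fit of a tissue curve against an AIF.

    Uniform weights (CT noise has no count-statistics structure).  Both
    curves are baseline-subtracted before fitting.  Deterministic per seed.
    Returns (AATHParameters, info dict).
    """
    tis, _ = tissue.enhancement(baseline_window_s)
    art, _ = aif.enhancement(baseline_window_s)
    if np.ptp(tis) < 1e-9:
        raise ValueError("flat tissue curve: no enhancement to fit")
    t = tissue.times_s

    lo, hi = AATH_BOUNDS_LO.copy(), AATH_BOUNDS_HI.copy()
    if not fit_delay:
        hi[4] = 1e-9

    def _params(x):
        v_p = min(x[1], 1.0 - 1e-6)
        v_e = max(min(x[2], 1.0 - v_p), 1e-6)
        return AATHParameters(bf=x[0], v_p=v_p, v_e=v_e, ps=x[3], t0_s=x[4])

    def resid(x):
        return aath_tac(_params(x), aif.times_s, art, t) - tis

    rng = np.random.default_rng(seed)
    starts = np.empty((n_starts, 5))
    starts[:, 0] = np.exp(rng.uniform(np.log(0.05), np.log(2.0), n_starts))  # BF
    starts[:, 1] = rng.uniform(0.01, 0.3, n_starts)  # vP
    starts[:, 2] = rng.uniform(0.05, 0.6, n_starts)  # ve
    starts[:, 3] = np.exp(rng.uniform(np.log(0.05), np.log(2.0), n_starts))  # PS
    starts[:, 4] = rng.uniform(0.0, 10.0, n_starts) if fit_delay else 0.0
    best = None
    n_conv = 0
    for x0 in starts:
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12 * (hi - lo))
        sol = least_squares(
            resid, x0, bounds=(lo, hi), method="trf", ftol=1e-12, xtol=1e-12, gtol=1e-10,
            max_nfev=600,
        )
        if sol.status > 0:
            n_conv += 1
            if best is None or sol.cost < best.cost:
                best = sol
    if best is None:
        raise RuntimeError("no AATH start converged")
    sol = least_squares(
        resid, best.x, bounds=(lo, hi), method="trf", ftol=1e-15, xtol=1e-15, gtol=1e-12,
        max_nfev=3000,
    )
    if sol.status > 0 and sol.cost < best.cost:
        best = sol
    params = _params(best.x)
    info = {"ss": float(2 * best.cost), "n_starts": n_starts, "n_converged": n_conv, "seed": seed}
    return params, info


@dataclasses.dataclass
class CorrelationResult:
    r: float
    n: int
    p_value: float
    ci_low: float
    ci_high: float


def correlate(x, y, ci_level: float = 0.95) -> CorrelationResult:
    """Pearson correlation with two-sided p-value and Fisher-z CI."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("values must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / math.sqrt(n - 3)
    zc = stats.norm.ppf(0.5 + ci_level / 2.0)
    lo, hi = np.tanh(z - zc * se), np.tanh(z + zc * se)
    return CorrelationResult(r, n, float(res.pvalue), float(lo), float(hi))


def correlation_sweep(bf_values, tacs, first_minutes: float = 2.0):
    """Pearson r between BF and static uptake at every frame time-point.

    ``tacs`` share one schedule; returns (frame mid-times s, r per frame,
    r for the mean uptake over the first ``first_minutes`` post-injection).
    Mirrors the comparison of flow against static tracer uptake across the
    dynamic series and against the early-uptake average.
    """
    bf_values = np.asarray(bf_values, float)
    sched = tacs[0].schedule
    acts = np.array([t.activity for t in tacs])
    if acts.shape[0] != bf_values.size:
        raise ValueError("one TAC per BF value required")
    r_per_frame = np.full(sched.n_frames, np.nan)
    for i in range(sched.n_frames):
        if np.ptp(acts[:, i]) == 0:
            continue
        r_per_frame[i] = correlate(bf_values, acts[:, i]).r
    mid = sched.mid_s
    early = (mid > 0) & (mid <= first_minutes * 60.0)
    r_early = correlate(bf_values, acts[:, early].mean(axis=1)).r if np.any(early) else np.nan
    return mid, r_per_frame, r_early
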