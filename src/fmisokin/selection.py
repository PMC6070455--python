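"""Adequacy and relative-quality scoring of compartment-model fits.

Four complementary criteria: the Wald-Wolfowitz runs test on residual signs
(absolute adequacy), AIC corrected for small samples and BIC (parsimony),
and leave-one-out cross-validated mean squared error of prediction (MSEP).
"""

from __future__ import annotations

import dataclasses
import math

import numpy as np
import pandas as pd
from scipy.special import comb
from scipy.stats import norm

from . import models as M
from .fitting import FitResult, fit_model, loo_refit

__all__ = [
    "runs_test",
    "RunsTestResult",
    "aicc",
    "aic",
    "bic",
    "information_criteria",
    "loo_msep",
    "SelectionScores",
    "score_fit",
    "rank_models",
]


@dataclasses.dataclass
class RunsTestResult:
    n_runs: int
    n_pos: int
    n_neg: int
    p_value: float
    passed: bool
    method: str  # "exact" or "normal"


def _residual_signs(residuals: np.ndarray) -> np.ndarray:
    """Signs of residuals; exact zeros inherit the previous sign.

    Zero residuals have measure zero for continuous data; a leading zero
    inherits the first nonzero sign that follows.
    """
    signs = np.sign(residuals)
    nz = np.nonzero(signs)[0]
    if nz.size == 0:
        return signs
    first = signs[nz[0]]
    out = np.empty_like(signs)
    prev = first
    for i, s in enumerate(signs):
        if s == 0:
            s = prev
        out[i] = s
        prev = s
    return out


def _exact_runs_cdf(n1: int, n2: int):
    """P(R = r) for r = 2..n1+n2 under random arrangement of n1 +, n2 -."""
    n = n1 + n2
    total = comb(n, n1, exact=True)
    pmf = {}
    for r in range(2, n + 1):
        if r % 2 == 0:
            k = r // 2
            ways = 2 * comb(n1 - 1, k - 1, exact=True) * comb(n2 - 1, k - 1, exact=True)
        else:
            k = (r - 1) // 2
            ways = comb(n1 - 1, k - 1, exact=True) * comb(n2 - 1, k, exact=True) + comb(
                n1 - 1, k, exact=True
            ) * comb(n2 - 1, k - 1, exact=True)
        if ways:
            pmf[r] = ways / total
    return pmf


#: Sample size at or below which the exact run-count distribution is used.
EXACT_RUNS_MAX_N = 20


def runs_test(residuals, alpha: float = 0.05) -> RunsTestResult:
    """Wald-Wolfowitz runs test on the signs of fit residuals.

    Tests whether positive and negative residuals are randomly interleaved;
    systematic model misfit produces too few runs.  For n <= 20 the run-count
    distribution is enumerated exactly and reported as a two-sided mid-p
    (half the observed count's probability in each tail), which removes the
    conservatism of the discrete statistic; for larger n the plain normal
    approximation is used, which tracks the mid-p closely.  "passed" means
    the fit is not rejected at level ``alpha``.
    """
    residuals = np.asarray(residuals, float)
    signs = _residual_signs(residuals)
    if np.count_nonzero(signs) < 2:
        raise ValueError("need at least two signed residuals")
    n1 = int(np.sum(signs > 0))
    n2 = int(np.sum(signs < 0))
    runs = int(1 + np.sum(signs[1:] != signs[:-1]))
    if n1 == 0 or n2 == 0:
        # all one sign: a single run; randomness cannot be rejected the usual
        # way, but the case is defined (p from the degenerate distribution)
        return RunsTestResult(runs, n1, n2, 1.0, True, "degenerate")
    n = n1 + n2
    if n <= EXACT_RUNS_MAX_N:
        pmf = _exact_runs_cdf(n1, n2)
        pr = pmf.get(runs, 0.0)
        lo = sum(p for r, p in pmf.items() if r <= runs)
        hi = sum(p for r, p in pmf.items() if r >= runs)
        p = min(1.0, max(0.0, 2.0 * min(lo - pr / 2.0, hi - pr / 2.0)))
        method = "exact"
    else:
        mu = 2.0 * n1 * n2 / n + 1.0
        var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
        z = (runs - mu) / math.sqrt(var)
        p = min(1.0, float(2.0 * norm.sf(abs(z))))
        method = "normal"
    return RunsTestResult(runs, n1, n2, p, p >= alpha, method)


# ---------------------------------------------------------------------------
# Information criteria (Gaussian weighted-least-squares forms)
# ---------------------------------------------------------------------------


def aic(wss: float, T: int, k: int) -> float:
    """AIC = T ln(WSS/T) + 2k for a Gaussian WLS fit."""
    if wss <= 0:
        raise ValueError("WSS must be positive for the log-likelihood form")
    return T * math.log(wss / T) + 2.0 * k


def aicc(wss: float, T: int, k: int) -> float:
    """AIC with the small-sample correction 2k(k+1)/(T-k-1)."""
    if T <= k + 1:
        raise ValueError(f"AICc undefined for T={T}, k={k} (needs T > k+1)")
    return aic(wss, T, k) + 2.0 * k * (k + 1.0) / (T - k - 1.0)


def bic(wss: float, T: int, k: int) -> float:
    """BIC = T ln(WSS/T) + k ln T."""
    if wss <= 0:
        raise ValueError("WSS must be positive for the log-likelihood form")
    return T * math.log(wss / T) + k * math.log(T)


def information_criteria(fit: FitResult) -> dict:
    """AIC/AICc/BIC from a fit, with weights normalized to mean 1.

    Normalizing the (shared) weights to unit mean over the contributing
    frames adds the same constant to every model's score on a given TAC, so
    rankings are comparable across models.  T counts frames with nonzero
    weight; k counts v_B plus the free rate constants.
    """
    mask = fit.weights > 0
    T = int(mask.sum())
    k = fit.model.n_free
    w = fit.weights[mask] / fit.weights[mask].mean()
    wss = float(np.sum(w * fit.residuals[mask] ** 2))
    return {
        "aic": aic(wss, T, k),
        "aicc": aicc(wss, T, k),
        "bic": bic(wss, T, k),
        "T": T,
        "k": k,
        "wss_norm": wss,
    }


def loo_msep(
    model,
    tac,
    input_fn,
    full_fit: FitResult | None = None,
    n_restarts: int = 9,
    seed: int = 0,
    n_starts_full: int = 100,
):
    """Leave-one-out mean squared error of prediction, (kBq/mL)^2.

    Each frame is omitted in turn, the model refit (warm-started from the
    full-data fit), and the squared difference between the omitted value and
    the model prediction averaged.  Unweighted, as "squared error of
    prediction" implies.  Returns (msep, n_folds, per-frame predictions).
    """
    if isinstance(model, str):
        model = M.model_spec(model)
    if full_fit is None:
        full_fit = fit_model(model, tac, input_fn, n_starts=n_starts_full, seed=seed)
    T = tac.schedule.n_frames
    preds = np.full(T, np.nan)
    for i in range(T):
        try:
            preds[i], _ = loo_refit(
                model, tac, input_fn, i, full_fit, n_restarts=n_restarts, seed=seed + i + 1
            )
        except Exception:
            continue
    ok = np.isfinite(preds)
    if not np.any(ok):
        raise RuntimeError("every leave-one-out fold failed")
    msep = float(np.mean((tac.activity[ok] - preds[ok]) ** 2))
    return msep, int(ok.sum()), preds


@dataclasses.dataclass
class SelectionScores:
    """All adequacy/quality scores for one model on one TAC."""

    model: str
    runs: RunsTestResult
    aic: float
    aicc: float
    bic: float
    msep: float
    msep_folds: int
    T: int
    k: int


def score_fit(fit: FitResult, tac, input_fn, msep_restarts: int = 9, seed: int = 0) -> SelectionScores:
    """Compute the full score set for one fitted model/TAC pair."""
    mask = fit.weights > 0
    runs = runs_test(fit.residuals[mask])
    ic = information_criteria(fit)
    msep, folds, _ = loo_msep(
        fit.model, tac, input_fn, full_fit=fit, n_restarts=msep_restarts, seed=seed
    )
    return SelectionScores(
        model=fit.model.name,
        runs=runs,
        aic=ic["aic"],
        aicc=ic["aicc"],
        bic=ic["bic"],
        msep=msep,
        msep_folds=folds,
        T=ic["T"],
        k=ic["k"],
    )


def rank_models(scores: dict) -> pd.DataFrame:
    """Summarize scores of several models over a common TAC set.

    ``scores`` maps model name -> list of SelectionScores (one per TAC, same
    TAC order for every model).  Returns a table with one row per model:
    runs-test pass counts, totaled AIC/AICc/BIC/MSEP, and the number of TACs
    for which the model attains each lowest score.
    """
    names = list(scores)
    lengths = {len(v) for v in scores.values()}
    if len(lengths) != 1:
        raise ValueError("all models must be scored on the same TAC set")
    (n_tacs,) = lengths
    rows = []
    mats = {
        key: np.array([[getattr(s, key) for s in scores[m]] for m in names])
        for key in ("aic", "aicc", "bic", "msep")
    }
    winners = {key: np.argmin(mats[key], axis=0) for key in mats}
    for j, m in enumerate(names):
        row = {"model": m, "n_tacs": n_tacs}
        row["runs_passes"] = int(sum(s.runs.passed for s in scores[m]))
        for key in mats:
            row[f"total_{key}"] = float(mats[key][j].sum())
            row[f"wins_{key}"] = int(np.sum(winners[key] == j))
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")
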