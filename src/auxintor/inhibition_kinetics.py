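"""Steady-state inhibition kinetics and dose-response fitting.

Rate laws (v as a function of substrate S and inhibitor I):

    MM              v = Vmax*S / (Km + S)
    competitive     v = Vmax*S / (Km*(1 + I/Ki) + S)
    noncompetitive  v = Vmax*S / ((1 + I/Ki) * (Km + S))
    uncompetitive   v = Vmax*S / (Km + S*(1 + I/Ki))
    mixed           v = Vmax*S / (Km*(1 + I/Ki) + S*(1 + I/(alpha*Ki)))

All mechanisms reduce to Michaelis-Menten at I = 0.  Fits are global (one
Vmax, Km, Ki shared across inhibitor levels), performed in log-parameter
space to enforce positivity, with multi-start initialization.  Mechanism
discrimination uses the small-sample Akaike criterion

    AICc = n*ln(SSE/n) + 2k + 2k(k+1)/(n - k - 1).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .errors import FitFailureError, SimulationSpecError

MECHANISMS = ("MM", "competitive", "noncompetitive", "uncompetitive", "mixed")

KINETICS_COLUMNS = ["substrate_uM", "inhibitor_uM", "velocity", "replicate"]


@dataclass
class KineticParams:
    """Rate-law parameters; Ki applies to inhibited mechanisms, alpha to mixed."""

    mechanism: str
    vmax: float
    km: float
    ki: float | None = None
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.mechanism not in MECHANISMS:
            raise SimulationSpecError(f"unknown mechanism {self.mechanism!r}")
        if not (self.vmax > 0 and self.km > 0):
            raise SimulationSpecError("Vmax and Km must be positive")
        if self.mechanism != "MM":
            if self.ki is None or not self.ki > 0:
                raise SimulationSpecError("Ki must be positive for inhibited mechanisms")
        if self.mechanism == "mixed":
            if self.alpha is None or not self.alpha > 0:
                raise SimulationSpecError("alpha must be positive for the mixed mechanism")

    @property
    def n_params(self) -> int:
        return {"MM": 2, "mixed": 4}.get(self.mechanism, 3)

    def to_dict(self) -> dict:
        return {
            "mechanism": self.mechanism,
            "vmax": self.vmax,
            "km": self.km,
            "ki": self.ki,
            "alpha": self.alpha,
        }


def n_params_for(mechanism: str) -> int:
    if mechanism not in MECHANISMS:
        raise ValueError(f"unknown mechanism {mechanism!r}")
    return {"MM": 2, "mixed": 4}.get(mechanism, 3)


def velocity(params: KineticParams, S, I=0.0):
    """Evaluate the rate law; accepts scalars or numpy arrays for S and I."""
    S = np.asarray(S, dtype=float)
    I = np.asarray(I, dtype=float)
    if np.any(S <= 0):
        raise ValueError("substrate concentrations must be positive")
    if np.any(I < 0):
        raise ValueError("inhibitor concentrations must be non-negative")
    m, vmax, km = params.mechanism, params.vmax, params.km
    if m == "MM":
        denom = km + S
    elif m == "competitive":
        denom = km * (1 + I / params.ki) + S
    elif m == "noncompetitive":
        denom = (1 + I / params.ki) * (km + S)
    elif m == "uncompetitive":
        denom = km + S * (1 + I / params.ki)
    else:  # mixed
        denom = km * (1 + I / params.ki) + S * (1 + I / (params.alpha * params.ki))
    v = vmax * S / denom
    return float(v) if v.ndim == 0 else v


def _params_from_theta(mechanism: str, theta: np.ndarray) -> KineticParams:
    vals = np.exp(theta)
    if mechanism == "MM":
        return KineticParams(mechanism, vals[0], vals[1])
    if mechanism == "mixed":
        return KineticParams(mechanism, vals[0], vals[1], vals[2], vals[3])
    return KineticParams(mechanism, vals[0], vals[1], vals[2])


@dataclass
class ModelFit:
    """Result of a global rate-law fit."""

    params: KineticParams | None
    sse: float
    n_obs: int
    n_params: int
    aicc: float
    converged: bool
    message: str = ""
    ci: dict[str, tuple[float, float]] | None = None

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict() if self.params else None,
            "sse": self.sse,
            "n_obs": self.n_obs,
            "n_params": self.n_params,
            "aicc": self.aicc,
            "converged": self.converged,
            "message": self.message,
            "ci": self.ci,
        }


def aicc(sse: float, n: int, k: int) -> float:
    """Small-sample Akaike information criterion for a least-squares fit."""
    if n <= k + 1:
        return np.inf
    sse = max(float(sse), 1e-300)  # guard log(0) for exact fits
    return n * np.log(sse / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def _check_dataset(data: pd.DataFrame, k: int) -> pd.DataFrame:
    missing = [c for c in ("substrate_uM", "inhibitor_uM", "velocity") if c not in data.columns]
    if missing:
        raise ValueError(f"kinetics data missing columns {missing}")
    n = len(data)
    if n < k + 2:
        raise ValueError(f"need at least {k + 2} observations for a {k}-parameter fit, got {n}")
    if data["substrate_uM"].nunique() < 2:
        raise ValueError("need at least 2 distinct substrate levels")
    return data


def _initial_thetas(mechanism: str, S: np.ndarray, I: np.ndarray, v: np.ndarray):
    """Multi-start grid: Km at substrate extremes/median, Ki at 0.1/1/10 x median I."""
    vmax0 = 1.1 * float(np.max(v)) if np.max(v) > 0 else 1.0
    km_starts = [float(np.min(S)), float(np.median(S)), float(np.max(S))]
    pos_I = I[I > 0]
    ki_scale = float(np.median(pos_I)) if pos_I.size else float(np.median(S))
    ki_starts = [0.1 * ki_scale, ki_scale, 10 * ki_scale]
    thetas = []
    if mechanism == "MM":
        for km0 in km_starts:
            thetas.append(np.log([vmax0, km0]))
    elif mechanism == "mixed":
        for km0, ki0 in itertools.product(km_starts, ki_starts):
            thetas.append(np.log([vmax0, km0, ki0, 1.0]))
    else:
        for km0, ki0 in itertools.product(km_starts, ki_starts):
            thetas.append(np.log([vmax0, km0, ki0]))
    return thetas


def fit_model(
    data: pd.DataFrame,
    mechanism: str,
    weighting: str = "none",
    theta0: np.ndarray | None = None,
) -> ModelFit:
    """Global weighted least-squares fit of one rate law across inhibitor levels.

    Parameters are fit in log space (positivity without constraints).
    ``weighting`` is ``none`` (default) or ``1/v2`` (relative residuals).
    ``theta0`` bypasses the multi-start grid with a single log-parameter start
    (used for bootstrap refits).
    """
    k = n_params_for(mechanism)
    data = _check_dataset(data, k)
    S = data["substrate_uM"].to_numpy(float)
    I = data["inhibitor_uM"].to_numpy(float)
    v = data["velocity"].to_numpy(float)
    n = len(v)
    if weighting not in ("none", "1/v2"):
        raise ValueError(f"unknown weighting {weighting!r}")
    w = 1.0 / np.maximum(v, np.max(v) * 1e-6) if weighting == "1/v2" else 1.0

    def residuals(theta: np.ndarray) -> np.ndarray:
        p = _params_from_theta(mechanism, theta)
        return (velocity(p, S, I) - v) * w

    starts = [theta0] if theta0 is not None else _initial_thetas(mechanism, S, I, v)
    best = None
    for th0 in starts:
        try:
            res = least_squares(residuals, th0, method="lm", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        return ModelFit(None, np.inf, n, k, np.inf, False, "all starts failed")
    sse, res = best
    params = _params_from_theta(mechanism, res.x)
    return ModelFit(params, sse, n, k, aicc(sse, n, k), bool(res.success),
                    message=res.message)


def select_mechanism(
    data: pd.DataFrame, candidates: tuple[str, ...] = MECHANISMS
) -> list[ModelFit]:
    """Fit every candidate mechanism and rank by AICc (ascending).

    Ties (within 1e-9) break toward fewer parameters.
    """
    fits = []
    for mech in candidates:
        try:
            fits.append(fit_model(data, mech))
        except ValueError:
            continue
    fits = [f for f in fits if f.converged]
    if not fits:
        raise FitFailureError("no candidate mechanism could be fit")
    fits.sort(key=lambda f: (round(f.aicc, 9), f.n_params))
    return fits


def bootstrap_ci(
    data: pd.DataFrame,
    mechanism: str,
    n_boot: int = 1000,
    seed: int = 0,
    level: float = 0.95,
) -> ModelFit:
    """Case-resampling bootstrap percentile intervals for the fit parameters.

    Resampled fits start at the point estimate.  Degenerate resamples (fewer
    than two substrate levels, or failed refits) are skipped; the count of
    skips is recorded in the returned fit's message.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    point = fit_model(data, mechanism)
    if not point.converged or point.params is None:
        raise FitFailureError("point fit failed; cannot bootstrap")
    rng = np.random.default_rng(seed)
    theta_hat = np.log([x for x in (
        point.params.vmax, point.params.km, point.params.ki, point.params.alpha
    ) if x is not None])
    names = ["vmax", "km", "ki", "alpha"][: len(theta_hat)]
    draws: list[np.ndarray] = []
    skipped = 0
    n = len(data)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        sample = data.iloc[idx]
        if sample["substrate_uM"].nunique() < 2:
            skipped += 1
            continue
        try:
            fit = fit_model(sample, mechanism, theta0=theta_hat)
        except (ValueError, FitFailureError):
            skipped += 1
            continue
        if not fit.converged or fit.params is None:
            skipped += 1
            continue
        draws.append(np.log([x for x in (
            fit.params.vmax, fit.params.km, fit.params.ki, fit.params.alpha
        ) if x is not None]))
        if not np.all(np.isfinite(draws[-1])):
            draws.pop()
            skipped += 1
    if not draws:
        raise FitFailureError("all bootstrap resamples were degenerate")
    arr = np.exp(np.array(draws))
    alpha = (1 - level) / 2
    ci = {}
    for j, name in enumerate(names):
        lo, hi = np.quantile(arr[:, j], [alpha, 1 - alpha])
        est = float(np.exp(theta_hat[j]))
        ci[name] = (min(float(lo), est), max(float(hi), est))
    point.ci = ci
    point.message = f"bootstrap n={len(draws)}, skipped={skipped}"
    return point


# ---------------------------------------------------------------------------
# dose-response (4-parameter logistic)


@dataclass
class DoseResponseFit:
    """Fitted 4PL curve: response = bottom + (top-bottom)/(1 + (d/IC50)^hill)."""

    ic50: float
    hill: float
    top: float
    bottom: float
    sse: float
    converged: bool = True
    message: str = ""

    def to_dict(self) -> dict:
        return {
            "ic50": self.ic50, "hill": self.hill, "top": self.top,
            "bottom": self.bottom, "sse": self.sse, "converged": self.converged,
            "message": self.message,
        }


def four_pl(dose, ic50: float, hill: float, top: float, bottom: float):
    """4PL response; dose 0 maps exactly to ``top`` for hill > 0."""
    dose = np.asarray(dose, dtype=float)
    with np.errstate(divide="ignore"):
        frac = np.where(dose > 0, (dose / ic50) ** hill, 0.0)
    out = bottom + (top - bottom) / (1.0 + frac)
    return float(out) if out.ndim == 0 else out


def fit_ic50(doses, responses) -> DoseResponseFit:
    """Fit a 4PL inhibition curve; bottom constrained >= 0.

    Requires >= 5 dose levels including dose 0; the top is initialized at the
    zero-dose mean.  A curve showing no response decrease from dose 0 to the
    highest dose returns a non-converged fit-failure result.
    """
    doses = np.asarray(doses, dtype=float)
    responses = np.asarray(responses, dtype=float)
    if doses.shape != responses.shape:
        raise ValueError("doses and responses must have the same length")
    if np.any(responses < 0) or np.any(doses < 0):
        raise ValueError("doses and responses must be non-negative")
    levels = np.unique(doses)
    if levels.size < 5:
        raise ValueError(f"need >= 5 distinct dose levels, got {levels.size}")
    if 0.0 not in levels:
        raise ValueError("dose 0 must be included to anchor the top plateau")

    means = {d: responses[doses == d].mean() for d in levels}
    top0 = means[0.0]
    bottom0 = min(means.values())
    if means[levels[-1]] >= top0 or top0 <= 0:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                               "no response decrease across doses")

    pos = levels[levels > 0]

    def residuals(theta):
        ic50, hill, top, bottom = np.exp(theta[0]), np.exp(theta[1]), theta[2], np.exp(theta[3])
        return four_pl(doses, ic50, hill, top, bottom) - responses

    # start IC50 near the dose whose mean is closest to half-way down
    half = (top0 + bottom0) / 2
    d_half = pos[np.argmin([abs(means[d] - half) for d in pos])]
    best = None
    for ic0 in {d_half, float(np.exp(np.mean(np.log(pos))))}:
        theta0 = np.array([np.log(ic0), 0.0, top0, np.log(max(bottom0, top0 * 1e-3))])
        try:
            res = least_squares(residuals, theta0, method="lm", xtol=1e-12, ftol=1e-12)
        except Exception:
            continue
        sse = float(np.sum(res.fun**2))
        if best is None or sse < best[0]:
            best = (sse, res)
    if best is None:
        return DoseResponseFit(np.nan, np.nan, np.nan, np.nan, np.nan, False,
                               "optimization failed")
    sse, res = best
    ic50, hill = float(np.exp(res.x[0])), float(np.exp(res.x[1]))
    top, bottom = float(res.x[2]), float(np.exp(res.x[3]))
    if bottom > top:
        return DoseResponseFit(ic50, hill, top, bottom, sse, False,
                               "inverted plateaus; curve is not inhibitory")
    return DoseResponseFit(ic50, hill, top, bottom, sse, bool(res.success), res.message)


def relative_activity(
    table: pd.DataFrame,
    target_col: str = "target_signal",
    loading_col: str = "loading_signal",
    condition_col: str = "condition",
    reference_condition=None,
) -> pd.DataFrame:
    """Densitometry normalization: target/loading, scaled so the reference is 100%."""
    for col in (target_col, loading_col, condition_col):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    if (table[loading_col] <= 0).any():
        raise ValueError("loading signal must be positive in every lane")
    out = table.copy()
    out["ratio"] = out[target_col] / out[loading_col]
    if reference_condition is None:
        reference_condition = out[condition_col].iloc[0]
    ref = out.loc[out[condition_col] == reference_condition, "ratio"]
    if ref.empty:
        raise ValueError(f"reference condition {reference_condition!r} not found")
    out["activity_pct"] = 100.0 * out["ratio"] / ref.mean()
    return out
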