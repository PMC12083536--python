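"""Wave-model and linear fits to distance curves, with restart/selection protocol.

The wave model is

    mu(L_G) = A0 + A * L_G + B * sin(k * L_G),   k = 2*pi*f

with intercept A0, linear coefficient A, amplitude B >= 0 and spatial frequency
f (oscillations per gene unit) constrained to (0, 0.5] — the Nyquist limit at
unit gene spacing, without which sine fits alias.  Fits are nonlinear least
squares on the binned means, repeated from random initial conditions (100
restarts by default) to remove starting-point bias; the best restart by
residual sum of squares wins.  Model selection follows the highest-R² /
lowest-BIC / lowest-AIC cascade, with R² values within ``r2_tol`` treated as
tied so that the 4-parameter wave (which nests the line at B = 0) does not win
on R² alone.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .pair_stats import DistanceCurve

F_MAX = 0.5  # Nyquist frequency at unit gene spacing


@dataclass
class WaveFitResult:
    A0: float
    A: float
    B: float
    f: float
    r2: float
    bic: float
    aic: float
    rss: float
    n_points: int
    n_restarts_converged: int
    degenerate: bool = False  # B ~ 0: f unidentifiable

    @property
    def k(self) -> float:
        return 2.0 * np.pi * self.f

    def predict(self, x: np.ndarray) -> np.ndarray:
        return wave_model(np.asarray(x, float), self.A0, self.A, self.B, self.f)

    def to_dict(self) -> dict:
        return dict(model="wave", A0=self.A0, A=self.A, B=self.B, f=self.f, k=self.k,
                    r2=self.r2, bic=self.bic, aic=self.aic,
                    n_restarts_converged=self.n_restarts_converged)


@dataclass
class LinearFitResult:
    intercept: float
    slope: float
    r2: float
    bic: float
    aic: float
    slope_p_value: float
    rss: float
    n_points: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, float)

    def to_dict(self) -> dict:
        return dict(model="linear", intercept=self.intercept, slope=self.slope,
                    r2=self.r2, bic=self.bic, aic=self.aic, slope_p=self.slope_p_value)


def wave_model(x: np.ndarray, A0: float, A: float, B: float, f: float) -> np.ndarray:
    return A0 + A * x + B * np.sin(2.0 * np.pi * f * x)


def _information_criteria(rss: float, n: int, n_params: int) -> tuple[float, float]:
    """Gaussian-likelihood BIC/AIC with the residual variance as one extra parameter."""
    rss = max(rss, 1e-300)
    k = n_params + 1
    ll = -0.5 * n * (np.log(2 * np.pi * rss / n) + 1)
    return float(k * np.log(n) - 2 * ll), float(2 * k - 2 * ll)


def _curve_criteria(curve, resid: np.ndarray, n_params: int) -> tuple[float, float]:
    """BIC/AIC for a fit to binned means.

    When the curve carries per-bin pair counts and SEMs, the criteria are
    evaluated on the pair-level Gaussian likelihood: N = total pairs, RSS =
    within-bin sum of squares + n-weighted between-bin misfit.  A binned-means
    likelihood (n = number of bins) lets the sine's tunable frequency overfit
    bin-level noise and can never favour the nested line, so the pair data the
    bins summarize are the honest evaluation set.  Bare (x, y) input falls back
    to the binned-points formula.
    """
    if isinstance(curve, DistanceCurve) and np.any(curve.n > 1):
        n_b = curve.n.astype(float)
        sd2 = (curve.sem**2) * n_b  # per-bin variance of the pair values
        within = float(np.sum((n_b - 1) * sd2))
        rss = within + float(np.sum(n_b * resid**2))
        return _information_criteria(rss, int(n_b.sum()), n_params)
    return _information_criteria(float(np.sum(resid**2)), len(resid), n_params)


def _r2(y: np.ndarray, resid: np.ndarray) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    rss = float(np.sum(resid**2))
    return 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)


def _curve_xyw(curve, weights: bool):
    if isinstance(curve, DistanceCurve):
        x, y = curve.x.astype(float), curve.mean.astype(float)
        w = curve.sem.astype(float) if weights else None
    else:
        x, y = np.asarray(curve[0], float), np.asarray(curve[1], float)
        w = None
    return x, y, w


def fit_wave(
    curve: DistanceCurve | tuple,
    n_restarts: int = 100,
    seed: int = 0,
    bounds: dict | None = None,
    weights: bool = False,
    b_degenerate_tol: float = 1e-6,
    tol: float = 1e-14,
) -> WaveFitResult:
    """Best-of-restarts nonlinear least squares of the wave model on binned means.

    Restarts draw f uniformly in (0, f_max] and B uniformly in [0, data range];
    A0 and A start from the OLS line.  ``weights=True`` uses 1/SEM² weights
    (zero-SEM bins fall back to unweighted).  Requires >= 5 bins (the model has
    4 shape parameters plus a variance).  An essentially zero fitted amplitude
    is flagged ``degenerate`` (f unidentifiable).
    """
    x, y, sem = _curve_xyw(curve, weights)
    if len(x) < 5:
        raise ValueError(f"wave fit needs >= 5 bins, got {len(x)}")
    rng = np.random.default_rng(seed)
    b = bounds or {}
    # identifiability guards: below ~a quarter oscillation over the fitted range
    # B*sin(2*pi*f*x) degenerates into a polynomial-mimic with arbitrarily large
    # B and compensating slope, so f is floored and B capped at the data range
    # (an oscillation larger than the curve's total span is unsupportable)
    f_floor = 1.0 / (4.0 * max(np.ptp(x), 1.0))
    f_lo, f_hi = b.get("f", (f_floor, F_MAX))
    b_lo, b_hi = b.get("B", (0.0, max(float(np.ptp(y)), 1e-12)))
    w = None
    if weights and sem is not None and np.all(sem > 0):
        w = 1.0 / sem

    slope, intercept = np.polyfit(x, y, 1)
    yr = float(np.ptp(y)) or 1.0

    def resid(theta):
        r = wave_model(x, *theta) - y
        return r * w if w is not None else r

    lower = [-np.inf, -np.inf, b_lo, f_lo]
    upper = [np.inf, np.inf, b_hi, f_hi]
    best, best_rss, n_ok = None, np.inf, 0
    for i in range(n_restarts):
        p0 = [
            intercept + rng.normal(0, 0.1 * yr),
            slope + rng.normal(0, 0.1 * yr / max(np.ptp(x), 1)),
            rng.uniform(b_lo, b_hi),
            rng.uniform(f_lo, f_hi),
        ]
        try:
            sol = optimize.least_squares(resid, p0, bounds=(lower, upper), method="trf", xtol=tol, ftol=tol, gtol=tol)
        except Exception:
            continue
        if not sol.success and not np.isfinite(sol.cost):
            continue
        n_ok += 1
        # restarts compete on the optimizer's own (possibly weighted) objective
        obj = float(np.sum(resid(sol.x) ** 2))
        if obj < best_rss:
            best, best_rss = sol.x, obj
    if best is None:
        raise RuntimeError("all wave-fit restarts diverged")
    A0, A, B, f = (float(v) for v in best)
    best_rss = float(np.sum((wave_model(x, A0, A, B, f) - y) ** 2))  # reported unweighted
    resid = wave_model(x, A0, A, B, f) - y
    r2 = _r2(y, resid)
    bic, aic = _curve_criteria(curve, resid, 4)
    return WaveFitResult(
        A0=A0, A=A, B=B, f=f, r2=r2, bic=bic, aic=aic, rss=best_rss,
        n_points=len(x), n_restarts_converged=n_ok,
        degenerate=B < b_degenerate_tol * max(yr, 1.0),
    )


def fit_linear_points(x: np.ndarray, y: np.ndarray) -> LinearFitResult:
    """OLS line with a t-test of the slope against zero (horizontal line)."""
    if len(x) < 3:
        raise ValueError(f"linear fit needs >= 3 points, got {len(x)}")
    if np.allclose(y, y[0]):
        # degenerate flat data: slope 0, no evidence against horizontality
        rss = 0.0
        bic, aic = _information_criteria(rss, len(x), 2)
        return LinearFitResult(float(y[0]), 0.0, 1.0, bic, aic, 1.0, rss, len(x))
    res = stats.linregress(x, y)
    pred = res.intercept + res.slope * x
    rss = float(np.sum((y - pred) ** 2))
    bic, aic = _information_criteria(rss, len(x), 2)
    return LinearFitResult(
        intercept=float(res.intercept), slope=float(res.slope),
        r2=float(res.rvalue**2), bic=bic, aic=aic,
        slope_p_value=float(res.pvalue), rss=rss, n_points=len(x),
    )


def fit_linear(curve: DistanceCurve | tuple) -> LinearFitResult:
    """OLS line on the binned means; BIC/AIC on the same likelihood as fit_wave."""
    x, y, _ = _curve_xyw(curve, False)
    res = fit_linear_points(x, y)
    bic, aic = _curve_criteria(curve, y - res.predict(x), 2)
    res.bic, res.aic = bic, aic
    return res


@dataclass
class ModelSelection:
    selected: str            # "wave" or "linear"
    by: str                  # "r2", "bic", "aic" or "parsimony"
    bic_aic_agree: bool
    wave: WaveFitResult = None
    linear: LinearFitResult = None


def select_model(
    wave: WaveFitResult, linear: LinearFitResult, r2_tol: float = 0.01
) -> ModelSelection:
    """Select between the wave and linear fits of the same binned points.

    Highest R² wins outright when the margin exceeds ``r2_tol`` (the reporting
    precision of R²); otherwise the lower BIC decides, then the lower AIC, and
    a full tie goes to the model with fewer parameters.  Records whether BIC
    and AIC agree.
    """
    if wave.n_points != linear.n_points:
        raise ValueError("fits must be computed on identical points")
    bic_agree = (wave.bic < linear.bic) == (wave.aic < linear.aic)
    if abs(wave.r2 - linear.r2) > r2_tol:
        sel = "wave" if wave.r2 > linear.r2 else "linear"
        return ModelSelection(sel, "r2", bic_agree, wave, linear)
    if wave.bic != linear.bic:
        sel = "wave" if wave.bic < linear.bic else "linear"
        return ModelSelection(sel, "bic", bic_agree, wave, linear)
    if wave.aic != linear.aic:
        sel = "wave" if wave.aic < linear.aic else "linear"
        return ModelSelection(sel, "aic", bic_agree, wave, linear)
    return ModelSelection("linear", "parsimony", bic_agree, wave, linear)


@dataclass
class FlatnessResult:
    p_amplitude: float
    p_slope: float
    observed_amplitude: float
    observed_abs_slope: float
    null_amplitudes: np.ndarray
    null_abs_slopes: np.ndarray


def flatness_test(
    curve: DistanceCurve,
    null_curves,
    *, n_restarts: int = 15, seed: int = 0, min_null: int = 200,
    null_stats: tuple[np.ndarray, np.ndarray] | None = None,
    tol: float = 1e-10,
) -> FlatnessResult:
    """Empirical p of the observed wave amplitude (and |slope|) against a shuffle null.

    p = (1 + #{null >= observed}) / (n_null + 1).  ``null_curves`` is an
    iterable of DistanceCurve (or a NullEnsemble with ``.curves``); pass
    ``null_stats`` to reuse amplitudes/slopes already computed for the same
    ensemble.  The observed fit uses the same restart count and tolerance as
    the null fits so the two statistics are exchangeable under the null.
    """
    curves = getattr(null_curves, "curves", null_curves)
    if null_stats is not None:
        null_b, null_s = (np.asarray(a, float) for a in null_stats)
    else:
        null_b, null_s = null_curve_stats(curves, n_restarts=n_restarts, seed=seed, tol=tol)
    if len(null_b) < min_null:
        raise ValueError(f"null ensemble too small ({len(null_b)} < {min_null})")
    obs_w = fit_wave(curve, n_restarts=n_restarts, seed=seed + 1, tol=tol)
    obs_l = fit_linear(curve)
    p_amp = (1.0 + np.sum(null_b >= obs_w.B)) / (len(null_b) + 1.0)
    p_slope = (1.0 + np.sum(null_s >= abs(obs_l.slope))) / (len(null_s) + 1.0)
    return FlatnessResult(float(p_amp), float(p_slope), obs_w.B, abs(obs_l.slope), null_b, null_s)


def null_curve_stats(
    curves, n_restarts: int = 15, seed: int = 0, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray]:
    """Wave amplitude and |OLS slope| for every curve of a null ensemble."""
    amps, slopes = [], []
    for i, c in enumerate(curves):
        amps.append(fit_wave(c, n_restarts=n_restarts, seed=seed + 7919 * i, tol=tol).B)
        slopes.append(abs(fit_linear(c).slope))
    return np.asarray(amps), np.asarray(slopes)
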