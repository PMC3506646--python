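"""Quantification-cycle (Cq) estimation and repeat-set summaries.

Two Cq estimators are provided:

* **threshold Cq** — the fractional cycle at which a cubic spline through the
  baseline-subtracted curve first crosses a fixed fluorescence threshold
  from below (Forsythe–Malcolm–Moler style interpolation);
* **SDM Cq** — the first positive maximum of the analytic second derivative
  of a five-parameter logistic model (5PLM, a Richards curve) fitted to the
  curve by nonlinear least squares (Levenberg–Marquardt).

The default threshold policy for a set of repeats places the threshold at
the fluorescence of the SDM with the lowest curve position in the set, which
makes the threshold user-independent while avoiding the upward displacement
of individual SDMs at low template input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.optimize import least_squares, minimize_scalar

__all__ = [
    "FivePLMParams", "CqResult", "five_plm", "five_plm_second_derivative",
    "threshold_cq", "fit_5plm", "sdm_cq", "sdm_threshold", "repeat_summary",
]


@dataclass(frozen=True)
class FivePLMParams:
    """Parameters of the five-parameter logistic (Richards) curve.

    F(x) = fb + (fmax - fb) / (1 + exp(-(x - c_infl)/b_growth))**g_asym

    ``fb`` is the base fluorescence, ``fmax`` the plateau, ``c_infl`` the
    position parameter (the inflection of the symmetric g = 1 curve),
    ``b_growth`` the growth-rate scale in cycles and ``g_asym`` (> 0) the
    asymmetry, which moves the point of maximum growth along the curve.
    """

    fb: float
    fmax: float
    c_infl: float
    b_growth: float
    g_asym: float

    def __post_init__(self) -> None:
        if not self.fmax > 0:
            raise ValueError("fmax must be > 0")
        if not self.g_asym > 0:
            raise ValueError("g_asym must be > 0")
        if not self.b_growth > 0:
            raise ValueError("b_growth must be > 0")


@dataclass(frozen=True)
class CqResult:
    """A Cq value with its estimator and threshold provenance.

    ``value`` is NaN when the estimator is undefined for the curve (e.g. the
    threshold is never crossed); ``ok`` makes the missingness explicit.
    """

    method: str                 # "threshold" | "sdm"
    value: float
    threshold_used: float | None = None
    flag: str | None = None

    @property
    def ok(self) -> bool:
        return math.isfinite(self.value)


def five_plm(x, p: FivePLMParams) -> np.ndarray:
    """Evaluate the 5PLM at cycle positions ``x``."""
    x = np.asarray(x, dtype=float)
    z = (x - p.c_infl) / p.b_growth
    # stable logistic
    s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
    return p.fb + (p.fmax - p.fb) * s**p.g_asym


def five_plm_second_derivative(x, p: FivePLMParams) -> np.ndarray:
    """Analytic second derivative of the 5PLM with respect to cycle.

    With s(x) the logistic of z = (x - c)/b, F = fb + A s**g and

        F'' = A g / b**2 * s**g (1 - s) [g (1 - s) - s].
    """
    x = np.asarray(x, dtype=float)
    z = (x - p.c_infl) / p.b_growth
    s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
    a = p.fmax - p.fb
    g = p.g_asym
    return a * g / p.b_growth**2 * s**g * (1.0 - s) * (g * (1.0 - s) - s)


def estimate_baseline(observed, camera_sd: float = 1.75) -> np.ndarray:
    """Estimate the linear base fluorescence of a raw curve.

    A first trend is fitted to the early cycles; the ground phase is taken
    to end three cycles before the first cycle whose residual against that
    trend exceeds ten camera standard deviations, and the baseline is
    re-fitted to cycles 3..(end of ground phase).  Returns the per-cycle
    baseline values (same length as ``observed``).
    """
    obs = np.asarray(observed, dtype=float)
    n = len(obs)
    if n < 12:
        raise ValueError("curve too short to estimate a baseline")
    x = np.arange(1, n + 1, dtype=float)
    first = np.polyfit(x[2:10], obs[2:10], 1)
    resid = obs - np.polyval(first, x)
    above = np.where(resid > 10.0 * camera_sd)[0]
    end = int(above[0]) - 3 if len(above) else n
    end = min(max(end, 8), n)
    coef = np.polyfit(x[2:end], obs[2:end], 1)
    return np.polyval(coef, x)


def threshold_cq(curve, threshold: float, cycles=None) -> CqResult:
    """Fractional cycle where the spline through the curve first reaches
    ``threshold`` from below.

    ``curve`` is baseline-subtracted fluorescence for cycles 1..C (or the
    positions given in ``cycles``).  A curve that never crosses yields a
    missing result; a crossing at the very first cycle is flagged because
    the threshold then sits inside the baseline region.
    """
    curve = np.asarray(curve, dtype=float)
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve must be finite")
    if not threshold > 0:
        raise ValueError("threshold must be > 0")
    x = np.arange(1, len(curve) + 1, dtype=float) if cycles is None \
        else np.asarray(cycles, dtype=float)
    spl = CubicSpline(x, curve)               # not-a-knot end conditions (FMM style)
    roots = spl.solve(threshold, extrapolate=False)
    # keep upward crossings only
    up = [float(r) for r in np.sort(roots) if spl(r, 1) > 0 or (
        # tangential/exact hits: accept if the curve is locally non-decreasing
        spl(min(r + 1e-6, x[-1])) >= spl(max(r - 1e-6, x[0])))]
    if not up:
        return CqResult("threshold", math.nan, threshold_used=threshold,
                        flag="threshold never crossed")
    cq = up[0]
    flag = "threshold inside baseline" if cq <= x[0] + 1e-9 else None
    return CqResult("threshold", cq, threshold_used=threshold, flag=flag)


def _5plm_residuals(theta, x, y):
    fb, fmax, c, log_b, log_g = theta
    b = math.exp(log_b)
    g = math.exp(log_g)
    z = (x - c) / b
    s = np.where(z >= 0, 1.0 / (1.0 + np.exp(-z)), np.exp(z) / (1.0 + np.exp(z)))
    return fb + (fmax - fb) * s**g - y


def fit_5plm(curve, cycles=None, fix_g: float | None = None) -> FivePLMParams:
    """Fit the 5PLM to a raw fluorescence curve by least squares.

    Multi-start initialization: the base level from the early cycles, the
    plateau from the late cycles, the position parameter from the maximum
    first difference, and a small grid of growth-rate/asymmetry starts;
    the best (lowest-residual) converged fit wins.  Raises ``RuntimeError``
    if no start converges.  ``fix_g`` pins the asymmetry (g = 1 gives the
    ordinary 4-parameter logistic).

    The asymmetry and growth-rate scale are restricted to [0.05, 20]:
    beyond that the Richards curve is numerically indistinguishable from its
    degenerate Gompertz limit (g -> inf with c_infl -> -inf along a flat
    residual ridge), which destabilizes the derived SDM.
    """
    y = np.asarray(curve, dtype=float)
    x = np.arange(1, len(y) + 1, dtype=float) if cycles is None \
        else np.asarray(cycles, dtype=float)
    if len(y) < 6:
        raise ValueError("need at least 6 points for a 5PLM fit")
    fb0 = float(np.mean(y[: max(3, len(y) // 10)]))
    fmax0 = float(np.mean(y[-3:]))
    if not fmax0 > fb0:
        raise RuntimeError("curve shows no rise; 5PLM fit not meaningful")
    c0 = float(x[np.argmax(np.diff(y))])
    scale = max(abs(fmax0), 1.0)

    log_lim = math.log(20.0)
    span = float(x[-1] - x[0])
    best = None
    for b0 in (0.8, 1.5, 3.0):
        for g0 in ((1.0,) if fix_g is not None else (0.3, 1.0, 3.0)):
            theta0 = np.array([fb0, fmax0, c0, math.log(b0),
                               math.log(fix_g if fix_g is not None else g0)])
            try:
                if fix_g is not None:
                    def resid(t, lg=math.log(fix_g)):
                        return _5plm_residuals(np.append(t, lg), x, y)
                    sol = least_squares(
                        resid, theta0[:4], method="trf", xtol=1e-14, ftol=1e-14,
                        max_nfev=4000,
                        bounds=([-np.inf, 0.0, x[0] - span, -log_lim],
                                [np.inf, np.inf, x[-1] + span, log_lim]))
                else:
                    sol = least_squares(
                        _5plm_residuals, theta0, args=(x, y), method="trf",
                        xtol=1e-14, ftol=1e-14, max_nfev=4000,
                        bounds=([-np.inf, 0.0, x[0] - span, -log_lim, -log_lim],
                                [np.inf, np.inf, x[-1] + span, log_lim, log_lim]))
            except Exception:
                continue
            cost = float(np.sqrt(2 * sol.cost / len(y)))
            if sol.success and (best is None or cost < best[0]):
                best = (cost, sol.x if fix_g is None
                        else np.append(sol.x, math.log(fix_g)))
    if best is None:
        raise RuntimeError("5PLM fit failed to converge from all starts")
    rms, theta = best
    fb, fmax, c, log_b, log_g = theta
    if rms > 0.05 * scale:
        raise RuntimeError(
            f"5PLM fit did not reach an acceptable residual (rms {rms:.3g} "
            f"vs plateau {scale:.3g})")
    return FivePLMParams(fb=fb, fmax=fmax, c_infl=c,
                         b_growth=math.exp(log_b), g_asym=math.exp(log_g))


def sdm_cq(p: FivePLMParams, search_span: float = 60.0) -> CqResult:
    """Position of the first positive maximum of the analytic 5PLM second
    derivative — the SDM Cq.

    Always precedes the curve's inflection point (at ``c_infl +
    b_growth * ln(g_asym)``); for the symmetric logistic (g = 1) the closed
    form is c_infl - b_growth * ln(2 + sqrt(3)).
    """
    # coarse scan of the analytic second derivative, then golden refinement
    lo = p.c_infl - max(20.0 * p.b_growth, 5.0)
    hi = p.c_infl + max(20.0 * p.b_growth, 5.0)
    xs = np.linspace(lo, hi, 4001)
    d2 = five_plm_second_derivative(xs, p)
    pos = np.where(d2 > 0)[0]
    if len(pos) == 0:
        return CqResult("sdm", math.nan, flag="no positive second-derivative maximum")
    k = pos[np.argmax(d2[pos])]
    a, b = xs[max(k - 1, 0)], xs[min(k + 1, len(xs) - 1)]
    res = minimize_scalar(lambda t: -five_plm_second_derivative(t, p),
                          bounds=(a, b), method="bounded",
                          options={"xatol": 1e-10})
    return CqResult("sdm", float(res.x))


def sdm_threshold(curves, fits=None) -> float:
    """Threshold at the lowest SDM fluorescence position in a repeat set.

    For every repeat the fitted 5PLM is evaluated at its own SDM; the
    minimum of these fluorescence positions over the set is returned.
    """
    if fits is None:
        fits = [fit_5plm(c) for c in curves]
    levels = []
    for c, p in zip(curves, fits):
        r = sdm_cq(p)
        if r.ok:
            levels.append(float(five_plm(r.value, p)) - p.fb)
    if not levels:
        raise RuntimeError("no repeat produced a valid SDM; cannot set threshold")
    return min(levels)


def repeat_summary(curves, threshold: float | None = None) -> dict:
    """Variability summary of a set of baseline-subtracted repeats.

    Returns the standard deviations of the threshold-based and SDM-based Cq
    estimates, and the coefficient of variation of the plateau (mean of each
    repeat's final three cycles).  ``threshold`` defaults to the
    lowest-SDM-position policy of :func:`sdm_threshold`.  Missing Cq values
    are excluded and counted.
    """
    curves = [np.asarray(c, dtype=float) for c in curves]
    if len(curves) < 2:
        raise ValueError("need at least 2 repeats")
    fits, fit_fail = [], 0
    for c in curves:
        try:
            fits.append(fit_5plm(c))
        except RuntimeError:
            fits.append(None)
            fit_fail += 1
    ok_pairs = [(c, p) for c, p in zip(curves, fits) if p is not None]
    if threshold is None:
        threshold = sdm_threshold(*zip(*ok_pairs))

    cq_thr = [threshold_cq(c, threshold) for c in curves]
    cq_sdm = [sdm_cq(p) if p is not None else CqResult("sdm", math.nan, flag="fit failed")
              for p in fits]
    thr_vals = np.array([r.value for r in cq_thr if r.ok])
    sdm_vals = np.array([r.value for r in cq_sdm if r.ok])
    plateaus = np.array([float(np.mean(c[-3:])) for c in curves])

    return {
        "n": len(curves),
        "threshold": threshold,
        "sd_cq_threshold": float(np.std(thr_vals, ddof=1)) if len(thr_vals) > 1 else math.nan,
        "sd_cq_sdm": float(np.std(sdm_vals, ddof=1)) if len(sdm_vals) > 1 else math.nan,
        "mean_cq_threshold": float(np.mean(thr_vals)) if len(thr_vals) else math.nan,
        "mean_cq_sdm": float(np.mean(sdm_vals)) if len(sdm_vals) else math.nan,
        "plateau_mean": float(np.mean(plateaus)),
        "cv_plateau": float(np.std(plateaus, ddof=1) / np.mean(plateaus)),
        "n_missing_threshold": int(sum(not r.ok for r in cq_thr)),
        "n_missing_sdm": int(sum(not r.ok for r in cq_sdm)),
        "n_fit_failures": fit_fail,
    }
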