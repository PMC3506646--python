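"""Full-process-kinetics (FPK) recovery of reaction parameters from curves.

The recovery mirrors the analysis the simulator is evaluated against:
per-cycle efficiencies are read off the baseline-subtracted curve as
consecutive fluorescence ratios, their double logs are regressed on the
previous cycle's fluorescence with the bilinear efficiency model, and the
fitted intercept yields the initial-efficiency estimate
``emax_hat = exp(exp(intercept))``.  Back-propagating each early-cycle
fluorescence through the fitted efficiency chain estimates the initial
amplicon fluorescence ``i0f_hat = f * N0``.

The regression is weighted by the delta-method precision of ln ln E under
additive camera noise, sd(y) ~ 1 / (F * E * ln E): the efficiency ratio of
two noisy readings is far noisier at low fluorescence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .efficiency_model import BilinearParams, efficiency_at, ln2_efficiency, single_phase_ln2
from .parameter_engine import DEFAULT_LINKS, EfficiencyLinkCoefficients

__all__ = ["FPKEstimate", "observed_efficiencies", "fit_bilinear_to_curve",
           "estimate_initial_signal", "DEFAULT_NOISE_FLOOR"]

#: default noise floor for the efficiency window, three camera standard
#: deviations (1.75 FU each) — a simple proxy for the end of the ground
#: phase; the fluorescence-proportional regression weights keep the noisier
#: low-fluorescence ratios from dominating the fit
DEFAULT_NOISE_FLOOR = 5.25


@dataclass(frozen=True)
class FPKEstimate:
    """Result of a full-process-kinetics fit of one curve."""

    emax_hat: float
    params_hat: BilinearParams
    i0f_hat: float | None          # filled by estimate_initial_signal
    rms_residual: float            # on the double-log scale
    model: str                     # "bilinear" | "single_phase"
    n_points: int
    flag: str | None = None


def observed_efficiencies(curve, noise_floor: float = DEFAULT_NOISE_FLOOR):
    """Per-cycle efficiency series E_n = F_n / F_{n-1} above the noise floor.

    ``curve`` holds baseline-subtracted fluorescence for cycles 1..C.
    Returns ``(f_prev, eff, cycle_index)`` restricted to cycles whose
    *previous* fluorescence exceeds ``noise_floor`` (so the ratio is
    meaningful), paired for regression of ln ln E on F_prev.
    """
    f = np.asarray(curve, dtype=float)
    if len(f) < 2:
        raise ValueError("curve too short")
    f_prev = f[:-1]
    f_next = f[1:]
    idx = np.arange(2, len(f) + 1)
    keep = (f_prev > noise_floor) & (f_next > 0)
    if not np.any(keep):
        raise RuntimeError(
            f"no cycles above the noise floor ({noise_floor} FU); "
            "cannot form an efficiency series")
    return f_prev[keep], f_next[keep] / f_prev[keep], idx[keep]


def _make_params(c: float, log_b1: float, b2: float,
                 links: EfficiencyLinkCoefficients, fc: float = math.inf) -> BilinearParams:
    b1 = -math.exp(log_b1)
    return BilinearParams(beta1=b1, beta2=b2,
                          beta3=min(links.beta3_const, 2.0 * b1), c=c,
                          eta=links.eta_const, fc=fc)


def fit_bilinear_to_curve(curve, noise_floor: float = DEFAULT_NOISE_FLOOR,
                          links: EfficiencyLinkCoefficients = DEFAULT_LINKS,
                          max_eff: float = 2.5, min_points: int = 6) -> FPKEstimate:
    """Fit the double-log efficiency model to one baseline-subtracted curve.

    Points with an efficiency ratio outside (1, ``max_eff``] carry no
    double-log information (plateau noise) and are dropped.  A full
    two-phase fit (free intercept, first-phase slope/curvature and
    phase-change fluorescence; the second-phase slope and transition
    abruptness held at their systematic constants) competes against the
    single-phase model; the two-phase branch is kept only when it clearly
    improves the residual, so excess-primer curves fall back to the
    single-phase model.  The first-phase slope is fitted on a log scale
    (it spans orders of magnitude across reaction conditions).
    """
    f_prev, eff, idx = observed_efficiencies(curve, noise_floor)
    # Restrict the regression to the rising portion: once the curve has
    # reached its plateau the ratio E_n is 1 plus camera noise, and keeping
    # only the (censored) ratios above 1 there would bias the fit with the
    # highest-weight points.
    arr = np.asarray(curve, dtype=float)
    # strict inequality also drops the arrival cycle itself: under primer
    # depletion its realized efficiency is capped by the remaining primers
    # and does not lie on the efficiency-vs-fluorescence curve
    cutoff_cycle = int(np.argmax(arr >= 0.995 * arr.max())) + 1
    good = (eff > 1.0 + 1e-4) & (eff <= max_eff) & (idx < cutoff_cycle)
    f_prev, eff = f_prev[good], eff[good]
    if len(f_prev) < min_points:
        raise RuntimeError(
            f"only {len(f_prev)} usable efficiency points (< {min_points})")
    y = np.log(np.log(eff))
    # delta-method precision of ln ln E under additive camera noise:
    # sd(y) ~ sqrt(2) * camera_sd / (F_prev * E * ln E)
    w = (f_prev * eff * np.log(eff)) ** 2
    w /= w.max()
    sw = np.sqrt(w)

    def sp_resid(theta):
        p = _make_params(theta[0], theta[1], theta[2], links)
        return sw * (single_phase_ln2(f_prev, p) - y)

    # For a fixed curvature the single-phase model is linear in (c, beta1):
    # profile out beta2 on a sign-symmetric grid by weighted least squares,
    # then polish the best candidate with Levenberg-Marquardt.
    fmax = float(f_prev.max())
    grid = np.concatenate([[0.0], 10.0 ** np.linspace(-6, 0, 25) / fmax * 3.0])
    starts = []
    for b2 in np.concatenate([grid, -grid[1:]]):
        u = np.minimum(f_prev, -1.0 / b2) if b2 < 0 else f_prev
        reg = u * np.exp(np.minimum(b2 * u, 500.0))
        A = np.column_stack([np.ones_like(reg), reg]) * sw[:, None]
        (c_h, b1_h), *_ = np.linalg.lstsq(A, y * sw, rcond=None)
        if b1_h >= 0:
            continue
        r = float(np.sqrt(np.mean((A @ (c_h, b1_h) - y * sw) ** 2)))
        starts.append((r, c_h, math.log(-b1_h), b2))
    if not starts:
        raise RuntimeError("single-phase efficiency fit found no declining trend")
    starts.sort(key=lambda t: t[0])

    sol_sp, rms_sp = None, math.inf
    for _, c0, log_b10, b20 in starts[:3]:
        try:
            s = least_squares(sp_resid, [c0, log_b10, b20], method="lm",
                              xtol=1e-14, ftol=1e-14, max_nfev=4000)
        except Exception:
            continue
        r = math.sqrt(2 * s.cost / len(y))
        if s.success and r < rms_sp:
            sol_sp, rms_sp = s, r
    if sol_sp is None:
        raise RuntimeError("single-phase efficiency fit failed to converge")

    def bl_resid(theta):
        p = _make_params(theta[0], theta[1], theta[2], links, math.exp(theta[3]))
        return sw * (ln2_efficiency(f_prev, p) - y)

    sol_bl, rms_bl = None, math.inf
    for fc0 in (0.9 * fmax, 1.1 * fmax):
        try:
            s = least_squares(bl_resid, [*sol_sp.x, math.log(fc0)],
                              method="lm", xtol=1e-14, ftol=1e-14, max_nfev=4000)
        except Exception:
            continue
        r = math.sqrt(2 * s.cost / len(y))
        if s.success and r < rms_bl:
            sol_bl, rms_bl = s, r

    # Keep the two-phase fit only when it is a clear improvement and its
    # phase change lies inside the observed fluorescence range.
    use_bl = (sol_bl is not None and rms_bl < 0.8 * rms_sp
              and math.exp(sol_bl.x[3]) < fmax)
    if use_bl:
        params = _make_params(sol_bl.x[0], sol_bl.x[1], sol_bl.x[2], links,
                              math.exp(sol_bl.x[3]))
        rms, model = rms_bl, "bilinear"
    else:
        params = _make_params(sol_sp.x[0], sol_sp.x[1], sol_sp.x[2], links)
        rms, model = rms_sp, "single_phase"

    emax_hat = math.exp(math.exp(params.c))
    flag = None
    if not (1.0 < emax_hat <= 2.2):
        flag = f"emax_hat {emax_hat:.3f} outside plausible (1, 2.2]"
    elif emax_hat > 2.05:
        flag = f"emax_hat {emax_hat:.3f} above 2.05"
    return FPKEstimate(emax_hat=emax_hat, params_hat=params, i0f_hat=None,
                       rms_residual=rms, model=model, n_points=len(y), flag=flag)


def estimate_initial_signal(curve, fit: FPKEstimate,
                            noise_floor: float = DEFAULT_NOISE_FLOOR,
                            window: int = 5) -> float:
    """Back-propagated initial amplicon fluorescence estimate i0f_hat.

    For the first ``window`` cycles whose fluorescence exceeds the noise
    floor, each F_n is divided by the product of fitted efficiencies along
    the curve up to cycle n (the model evaluated at the previous observed
    fluorescence, clipped at zero); the mean of these back-propagated values
    estimates f * N0.  Assumes every fluorescence change is amplification,
    so plateau-level variability inflates its dispersion.
    """
    f = np.asarray(curve, dtype=float)
    p = fit.params_hat
    f_prev = np.concatenate([[0.0], f[:-1]])
    eff_chain = efficiency_at(np.clip(f_prev, 0.0, None), p)
    cum = np.cumprod(eff_chain)
    # anchor the window on the amplification rise itself: the contiguous
    # above-floor run that ends in the curve maximum (isolated early
    # crossings are baseline-subtraction residue, not signal)
    above = f > noise_floor
    if not np.any(above):
        raise RuntimeError("no cycles above the noise floor")
    start = int(np.argmax(f))
    while start > 0 and above[start - 1]:
        start -= 1
    sel = np.arange(start, len(f))[:window]
    vals = f[sel] / cum[sel]
    i0f = float(np.mean(vals))
    if not i0f > 0:
        raise RuntimeError("non-positive initial-signal estimate")
    return i0f
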