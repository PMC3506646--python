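"""Double-log bilinear model of qPCR cycle efficiency.

The cycle efficiency E (fold increase in amplicons per cycle, 1 < E <= 2)
declines as the reaction consumes reagents.  Empirically the decline happens
in two phases: a gentle, curved first phase while primers are plentiful
("self-limiting" kinetics) and a steep second phase once primers run out.
Both phases are modelled on the double-log scale

    y = ln(ln E)

as a function of the previous cycle's baseline-subtracted amplicon
fluorescence F.  The first phase is a curved decline

    y = c + beta1 * F * exp(beta2 * F)

whose initial slope is ``beta1`` and whose curvature parameter ``beta2``
sets how the decline accelerates (beta2 > 0, efficient reactions that
self-limit) or decelerates (beta2 < 0, inhibited reactions that never reach
a plateau) over the course of the reaction.  The second phase is a straight
line of slope ``beta3``.  The two segments are joined smoothly at the
phase-change fluorescence ``fc`` by a log-logistic (softplus) transition
whose abruptness is set by ``eta``, in the style of Buchwald's bilinear
growth/decline profiles.

Because y(F = 0) equals the vertical offset ``c``, the model's intercept is
the double log of the initial (maximal) efficiency: c = ln(ln Emax).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "BilinearParams",
    "ln2_efficiency",
    "single_phase_ln2",
    "efficiency_at",
    "EFFICIENCY_FLOOR",
    "EFFICIENCY_CEILING",
]

#: efficiency is clipped to this open interval after evaluation; E <= 1 is
#: physically meaningless (no amplification) and E > 2 is impossible since a
#: template can at most double each cycle.
EFFICIENCY_FLOOR = 1.0 + 1e-12
EFFICIENCY_CEILING = 2.0


@dataclass(frozen=True)
class BilinearParams:
    """Parameter set of the two-phase double-log efficiency model.

    Attributes
    ----------
    beta1 : float
        First-phase slope (double-log units per FU), <= 0 in practice.
    beta2 : float
        First-phase curvature (per FU), the acceleration of the decline.
        Positive values give a convex decline (slow, then fast, ending in a
        sharp knee); negative values a concave one (fast, then stalling) as
        seen for heavily inhibited reactions.
    beta3 : float
        Second-phase slope (double-log units per FU); steeper than the first
        phase, i.e. ``beta3 < min(0, beta1)``.
    c : float
        Vertical offset; equals ln(ln Emax) of the reaction.
    eta : float
        Transition abruptness (per FU).  Stored with the conventional
        negative sign; only its magnitude enters the transition width.
    fc : float
        Phase-change fluorescence (FU, > 0).  ``math.inf`` disables the
        second phase (excess-primer / self-limiting conditions).
    """

    beta1: float
    beta2: float
    beta3: float
    c: float
    eta: float
    fc: float = math.inf

    def __post_init__(self) -> None:
        for name in ("beta1", "beta2", "beta3", "c", "eta"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if not self.fc > 0:
            raise ValueError(f"fc must be > 0, got {self.fc!r}")
        if not self.beta3 < min(0.0, self.beta1):
            raise ValueError(
                "beta3 must be below min(0, beta1): second phase declines "
                f"faster than the first (beta3={self.beta3}, beta1={self.beta1})"
            )
        if self.eta == 0:
            raise ValueError("eta must be nonzero")

    @property
    def emax(self) -> float:
        """Initial efficiency implied by the intercept, exp(exp(c))."""
        return math.exp(math.exp(self.c))

    def with_fc(self, fc: float) -> "BilinearParams":
        """Return a copy with the phase-change fluorescence set."""
        return replace(self, fc=fc)


def _check_fluorescence(f_prev) -> np.ndarray:
    f = np.asarray(f_prev, dtype=float)
    if not np.all(np.isfinite(f)):
        raise ValueError("f_prev must be finite")
    if np.any(f < 0):
        raise ValueError("f_prev must be >= 0 (baseline-subtracted fluorescence)")
    return f


def _first_phase(f: np.ndarray, p: BilinearParams) -> np.ndarray:
    # For decelerating profiles (beta2 < 0) the raw expression would turn
    # upward beyond its stationary point at F = -1/beta2; efficiency cannot
    # recover, so the curve is extended monotonically from there.
    if p.beta2 < 0:
        f = np.minimum(f, -1.0 / p.beta2)
    # the exponent is capped: beyond it the double-log is so negative that
    # the efficiency is exactly 1.0 in double precision anyway (the product
    # may still overflow to -inf, which downstream exponentials handle)
    with np.errstate(over="ignore"):
        return p.c + p.beta1 * f * np.exp(np.minimum(p.beta2 * f, 500.0))


def _softplus(x: np.ndarray) -> np.ndarray:
    # numerically stable log(1 + exp(x))
    return np.logaddexp(0.0, x)


def single_phase_ln2(f_prev, p: BilinearParams) -> np.ndarray | float:
    """First-phase (self-limiting) double-log efficiency, c + beta1 F e^(beta2 F).

    Equals :func:`ln2_efficiency` whenever the transition is pushed beyond
    the reaction's fluorescence range (``fc = inf``).
    """
    f = _check_fluorescence(f_prev)
    y = _first_phase(f, p)
    return float(y) if np.isscalar(f_prev) else y


def ln2_efficiency(f_prev, p: BilinearParams) -> np.ndarray | float:
    """Two-phase double-log efficiency y = ln(ln E) at fluorescence ``f_prev``.

    The first-phase curve is evaluated at a softly clamped abscissa
    ``u(F)`` that saturates at ``fc``; beyond the transition the model
    continues with slope ``beta3``:

        u(F) = F - [softplus(s (F - fc)) - softplus(-s fc)] / s,  s = |eta|
        y(F) = c + beta1 u exp(beta2 u) + beta3 (F - u)

    so that u ~ F well below ``fc``, u ~ fc well above it, and y(0) = c
    exactly (intercept identity).
    """
    f = _check_fluorescence(f_prev)
    if math.isinf(p.fc):
        y = _first_phase(f, p)
        return float(y) if np.isscalar(f_prev) else y
    s = abs(p.eta)
    u = f - (_softplus(s * (f - p.fc)) - _softplus(-s * p.fc)) / s
    y = _first_phase(u, p) + p.beta3 * (f - u)
    return float(y) if np.isscalar(f_prev) else y


def efficiency_at(f_prev, p: BilinearParams) -> np.ndarray | float:
    """Cycle efficiency E = exp(exp(y)), clipped to (1, 2].

    At F = 0 this returns the initial efficiency Emax; for large F it tends
    to 1 from above (the reaction dies out).
    """
    y = ln2_efficiency(f_prev, p)
    e = np.exp(np.exp(np.asarray(y)))
    e = np.clip(e, EFFICIENCY_FLOOR, EFFICIENCY_CEILING)
    return float(e) if np.isscalar(f_prev) else e
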