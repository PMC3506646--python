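"""Systematic parameters and per-repeat random draws for simulated reactions.

The systematic backbone maps a reaction's starting conditions (initial
template copies N0, initial efficiency Emax) to the parameters of the
double-log bilinear efficiency model:

* the first-phase slope ``beta1`` is a calibrated power-law function of Emax,
* the curvature ``beta2`` is a saturating function of ``beta1`` (and
  therefore independent of N0),
* the second-phase slope ``beta3`` and the transition abruptness ``eta`` are
  fixed constants (-8.5 and -0.04 per FU),
* the intercept ``c`` is derived each draw as ln(ln Emax),
* the phase-change fluorescence ``fc`` is not a free parameter: the reaction
  engine determines it on the fly from primer consumption.

On top of the systematic values, :func:`draw_repeat_parameters` realizes the
stochastic inputs of one technical repeat: Poisson-sampled template copies,
normally varying true Emax, per-repeat side-reaction greediness (percentage
of remaining primers lost per cycle), pipetted primer count, a linear
baseline, and small "kinetic" jitter on the bilinear coefficients.  When the
Emax and side-reaction sources are both active their latent normals are
coupled through a Gaussian copula so that repeats with a higher true
efficiency lose fewer primers to side reactions — reproducing the empirical
pattern that the curve emerging first reaches the highest plateau.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import constants

from .efficiency_model import BilinearParams

__all__ = [
    "ReactionConditions",
    "VariationConfig",
    "EfficiencyLinkCoefficients",
    "RepeatDraw",
    "DEFAULT_LINKS",
    "VARIATION_CODES",
    "derive_first_phase_slope",
    "derive_curvature",
    "make_bilinear",
    "draw_repeat_parameters",
]


@dataclass(frozen=True)
class ReactionConditions:
    """User-facing reaction setup.

    Parameters
    ----------
    n0_mean : float
        Expected initial template copies per reaction.
    emax : float
        Initial reaction efficiency (fold change per cycle), 1 < emax <= 2.
    cycles : int
        Number of PCR cycles (default 60).
    primer_conc : float
        Primer concentration in nM (default 260, the standard 1x mix).
    volume : float
        Reaction volume in microlitres (default 25).
    f_amp : float
        Fluorescence emitted by a single amplicon (FU).  The default 1e-9
        puts the primer-depletion plateau near 3.9e3 FU, the magnitude of a
        typical SYBR-green readout; it is a per-assay knob, not a constant.
    """

    n0_mean: float
    emax: float = 1.95
    cycles: int = 60
    primer_conc: float = 260.0
    volume: float = 25.0
    f_amp: float = 1e-9

    def __post_init__(self) -> None:
        if not (1.0 < self.emax <= 2.0):
            raise ValueError(f"emax must be in (1, 2], got {self.emax}")
        if self.n0_mean <= 0 or self.primer_conc <= 0 or self.volume <= 0 or self.f_amp <= 0:
            raise ValueError("n0_mean, primer_conc, volume and f_amp must be > 0")
        if not (isinstance(self.cycles, (int, np.integer)) and self.cycles >= 1):
            raise ValueError(f"cycles must be an integer >= 1, got {self.cycles!r}")

    @property
    def primer_count(self) -> float:
        """Initial number of primer molecules, conc * volume * Avogadro."""
        return self.primer_conc * 1e-9 * self.volume * 1e-6 * constants.Avogadro


#: Algorithm codes for the individual variation sources:
#: "En" per-cycle efficiency error, "E" between-repeat Emax variation,
#: "i" Poisson template sampling (pipetting), "p" primer-amount variation,
#: "s" side reactions, "a" kinetic (bilinear-coefficient) variation.
VARIATION_CODES = ("En", "E", "i", "p", "s", "a")


@dataclass(frozen=True)
class VariationConfig:
    """Variance components of the simulation and their on/off switches.

    Magnitudes are separate from switches so a source can be toggled without
    losing its configured size.  Defaults are the empirically grounded
    values: camera noise sd 1.75 FU, baseline slope ~ N(0.7, 0.2) FU/cycle
    and intercept ~ N(200, 70) FU, side-reaction loss ~ N(2.27, 0.47) %% of
    remaining primers per cycle, Emax-side coupling (rank) correlation 0.46,
    and a between-repeat Emax sd of 0.01 (about the largest value compatible
    with observed repeat dispersion).
    """

    emax_variation: bool = True        # code "E"
    e_cycle_error: bool = True         # code "En"
    poisson_n0: bool = True            # code "i"
    primer_variation: bool = True      # code "p"
    side_reactions: bool = True        # code "s"
    kinetic_variation: bool = True     # code "a"
    baseline: bool = False
    camera: bool = False

    sigma_emax: float = 0.01
    sigma_e_rel: float = 0.002
    sigma_primer_rel: float = 0.01
    sigma_kinetic_rel: float = 0.02
    baseline_intercept_mean: float = 200.0
    baseline_intercept_sd: float = 70.0
    baseline_slope_mean: float = 0.7
    baseline_slope_sd: float = 0.2
    camera_sd: float = 1.75
    side_g_mean: float = 2.27
    side_g_sd: float = 0.47
    rho_couple: float = 0.46
    #: whether the per-cycle efficiency error is re-drawn in phase II as well
    e_error_in_phase2: bool = True

    def __post_init__(self) -> None:
        for name in (
            "sigma_emax", "sigma_e_rel", "sigma_primer_rel", "sigma_kinetic_rel",
            "baseline_intercept_sd", "baseline_slope_sd", "camera_sd", "side_g_sd",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if abs(self.rho_couple) > 1:
            raise ValueError("rho_couple must satisfy |rho| <= 1")

    @classmethod
    def none(cls, **overrides) -> "VariationConfig":
        """All sources off (noise-free systematic simulation)."""
        off = dict(
            emax_variation=False, e_cycle_error=False, poisson_n0=False,
            primer_variation=False, side_reactions=False, kinetic_variation=False,
            baseline=False, camera=False,
        )
        off.update(overrides)
        return cls(**off)

    @classmethod
    def only(cls, *codes: str, **overrides) -> "VariationConfig":
        """Only the named source codes active (baseline/camera stay off)."""
        return cls.from_codes(codes, **overrides)

    @classmethod
    def from_codes(cls, codes, *, baseline: bool = False, camera: bool = False,
                   **overrides) -> "VariationConfig":
        codes = tuple(codes)
        unknown = [c for c in codes if c not in VARIATION_CODES]
        if unknown:
            raise ValueError(
                f"unknown variation code(s) {unknown}; valid codes are {VARIATION_CODES}"
            )
        kw = dict(
            e_cycle_error="En" in codes,
            emax_variation="E" in codes,
            poisson_n0="i" in codes,
            primer_variation="p" in codes,
            side_reactions="s" in codes,
            kinetic_variation="a" in codes,
            baseline=baseline,
            camera=camera,
        )
        kw.update(overrides)
        return cls(**kw)

    @property
    def codes(self) -> tuple[str, ...]:
        on = {
            "En": self.e_cycle_error, "E": self.emax_variation, "i": self.poisson_n0,
            "p": self.primer_variation, "s": self.side_reactions,
            "a": self.kinetic_variation,
        }
        return tuple(c for c in VARIATION_CODES if on[c])


#: pivot of the slope link, slightly above the physical efficiency maximum;
#: keeps the power law defined and monotone over the whole (1, 2] domain
EMAX_PIVOT = 2.02

#: scale (double-log units per FU) on which the curvature link saturates;
#: set to the beta1 magnitude of a mildly inhibited reaction
BETA1_SCALE = 1e-3


@dataclass(frozen=True)
class EfficiencyLinkCoefficients:
    """Coefficients linking (Emax, beta1, beta2) plus the phase-II constants.

    ``eq6_coeffs = (a, b)`` give the power-law slope link
    ``beta1 = -exp(a + b * ln(EMAX_PIVOT - emax))``; ``eq7_coeffs = (p, q)``
    give the saturating curvature link
    ``beta2 = p + q * tanh(beta1 / BETA1_SCALE)``, bounded so that strongly
    inhibited reactions keep a physically sensible concave decline instead
    of an ever-steeper one.  The defaults are
    calibrated so that the systematic model reproduces its kinetic anchors
    (see docs/methods.md): the constant-efficiency endpoint at fractional
    cycle 20.3 with efficiencies 1.88 / 1.86 at fractional cycles 21.3 /
    22.3 (N0 = 50,000, Emax = 1.90), and second-derivative-maximum positions
    25.6 / 26.7 under excess-primer vs. primer-limiting conditions
    (N0 = 50,000, Emax = 1.95).
    """

    eq6_coeffs: tuple[float, float]
    eq7_coeffs: tuple[float, float]
    beta3_const: float = -8.5
    eta_const: float = -0.04


# Calibrated against the kinetic anchors above; frozen after calibration.
DEFAULT_LINKS = EfficiencyLinkCoefficients(
    eq6_coeffs=(8.473362671626848, 7.444814490812778),
    eq7_coeffs=(8.611267513969871e-04, 1.4080788704789375e-03),
)


def derive_first_phase_slope(emax: float,
                             links: EfficiencyLinkCoefficients = DEFAULT_LINKS) -> float:
    """Systematic first-phase slope beta1 for a given initial efficiency.

    Deterministic and strictly increasing in Emax over the plausible range:
    the overall attenuation of efficiency proceeds faster (more negative
    slope) when the initial efficiency is lower.
    """
    if not (1.0 < emax <= 2.0):
        raise ValueError(f"emax must be in (1, 2], got {emax}")
    a, b = links.eq6_coeffs
    return -math.exp(a + b * math.log(EMAX_PIVOT - emax))


def derive_curvature(beta1: float,
                     links: EfficiencyLinkCoefficients = DEFAULT_LINKS) -> float:
    """Systematic first-phase curvature beta2 from the slope beta1.

    beta2 depends on Emax only through beta1 and is independent of N0.  Over
    the inhibition-spanning Emax range it changes sign, shifting the decline
    profile from convex (high Emax, accelerating decline ending in a knee)
    over straight to concave (low Emax, a decline that stalls).
    """
    p, q = links.eq7_coeffs
    return p + q * math.tanh(beta1 / BETA1_SCALE)


def make_bilinear(emax: float,
                  links: EfficiencyLinkCoefficients = DEFAULT_LINKS,
                  fc: float = math.inf) -> BilinearParams:
    """Systematic bilinear parameter set for a reaction starting at ``emax``."""
    beta1 = derive_first_phase_slope(emax, links)
    beta2 = derive_curvature(beta1, links)
    # the second phase must decline faster than the first; for strongly
    # inhibited reactions (very steep beta1) the constant is steepened
    beta3 = min(links.beta3_const, 2.0 * beta1)
    return BilinearParams(
        beta1=beta1,
        beta2=beta2,
        beta3=beta3,
        c=math.log(math.log(emax)),
        eta=links.eta_const,
        fc=fc,
    )


@dataclass(frozen=True)
class RepeatDraw:
    """Realized random inputs of one technical repeat."""

    n0: int
    emax_i: float
    g_i: float                      # side-reaction loss, % of primers per cycle
    primer_count: float
    baseline_intercept: float
    baseline_slope: float
    bilinear: BilinearParams
    truncated: bool = False         # any truncation event during the draw


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float, max_tries: int = 1000) -> tuple[float, bool]:
    """Rejection-sampled normal restricted to (lo, hi]; flags truncation."""
    if sd == 0:
        return mean, False
    truncated = False
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo < x <= hi:
            return x, truncated
        truncated = True
    return min(max(mean, lo + sd * 1e-6), hi), True


def draw_repeat_parameters(cond: ReactionConditions, var: VariationConfig,
                           rng: np.random.Generator,
                           links: EfficiencyLinkCoefficients = DEFAULT_LINKS) -> RepeatDraw:
    """Draw one repeat's random inputs from the configured variance components.

    With every source switched off the result equals the systematic values
    exactly.  All randomness flows through the injected ``rng``.
    """
    truncated = False

    couple = var.emax_variation and var.side_reactions and var.rho_couple != 0
    if couple:
        # Gaussian copula on the latent normals of (Emax, g).  The latent
        # correlation is chosen so the *rank* correlation between emax_i and
        # retained-primer propensity (-g) equals rho_couple; the sign makes
        # early-emerging, high-efficiency repeats lose fewer primers.
        rho_rank = var.rho_couple
        rho_lat = 2.0 * math.sin(math.pi * rho_rank / 6.0)
        z_e = rng.standard_normal()
        z_g = rho_lat * z_e + math.sqrt(1.0 - rho_lat**2) * rng.standard_normal()
        z_g = -z_g  # higher efficiency -> lower side loss
        emax_i = cond.emax + var.sigma_emax * z_e
        if not (1.0 < emax_i <= 2.0):
            truncated = True
            emax_i = min(max(emax_i, 1.0 + 1e-6), 2.0)
        g_i = var.side_g_mean + var.side_g_sd * z_g
        if g_i < 0:
            truncated = True
            g_i = 0.0
    else:
        if var.emax_variation and var.sigma_emax > 0:
            emax_i, t = _truncated_normal(rng, cond.emax, var.sigma_emax, 1.0, 2.0)
            truncated |= t
        else:
            emax_i = cond.emax
        if var.side_reactions:
            g_i = rng.normal(var.side_g_mean, var.side_g_sd)
            if g_i < 0:
                truncated = True
                g_i = 0.0
        else:
            g_i = 0.0

    if var.poisson_n0:
        n0 = int(rng.poisson(cond.n0_mean))
    else:
        n0 = int(round(cond.n0_mean))

    primers = cond.primer_count
    if var.primer_variation and var.sigma_primer_rel > 0:
        factor = rng.normal(1.0, var.sigma_primer_rel)
        if factor <= 0:
            truncated = True
            factor = 1e-6
        primers *= factor

    if var.baseline:
        intercept = rng.normal(var.baseline_intercept_mean, var.baseline_intercept_sd)
        slope = rng.normal(var.baseline_slope_mean, var.baseline_slope_sd)
    else:
        intercept = 0.0
        slope = 0.0

    # The decline profile (beta1, beta2) is systematic — set by the nominal
    # starting conditions; between-repeat variation of the *true* initial
    # efficiency moves the intercept c = ln(ln emax_i) only.  Kinetic
    # variation (below) is the separate, explicit source of profile jitter.
    bil = replace(make_bilinear(cond.emax, links), c=math.log(math.log(emax_i)))
    if var.kinetic_variation and var.sigma_kinetic_rel > 0:
        # small independent relative jitter on the decline profile
        b1 = bil.beta1 * (1.0 + rng.normal(0.0, var.sigma_kinetic_rel))
        b2 = bil.beta2 * (1.0 + rng.normal(0.0, var.sigma_kinetic_rel))
        bil = replace(bil, beta1=min(b1, 0.0), beta2=b2)

    return RepeatDraw(
        n0=n0,
        emax_i=emax_i,
        g_i=g_i,
        primer_count=primers,
        baseline_intercept=intercept,
        baseline_slope=slope,
        bilinear=bil,
        truncated=truncated,
    )
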