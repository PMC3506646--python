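# Methods

## The model

`pcrsim` simulates real-time PCR amplification curves cycle by cycle from a
macroscopic kinetic model.  Reaction efficiency — the fold change in
amplicons per cycle, `E_n = F_n / F_{n-1}` on baseline-subtracted
fluorescence — is not constant: it declines as reagents are consumed.  The
decline is modelled on the double-log scale `y = ln(ln E)` as a function of
the previous cycle's amplicon fluorescence `F`, in two phases:

    y(F) = c + beta1 * u * exp(beta2 * u) + beta3 * (F - u)
    u(F) = F - [softplus(s (F - fc)) - softplus(-s fc)] / s,   s = |eta|

* **First phase (self-limiting).** `c = ln(ln Emax)` is the intercept, so
  the model evaluated at `F = 0` returns the reaction's initial efficiency
  exactly.  `beta1 < 0` is the initial speed of the decline; `beta2` is its
  acceleration: positive values give a convex profile that stays near
  `Emax` and then drops through a sharp knee (efficient reactions), while
  negative values give a concave, stalling profile (inhibited reactions).
  For `beta2 < 0` the expression is held at its stationary point
  `F = -1/beta2` so the decline is monotone by construction.
* **Second phase (primer depletion).** A straight decline of slope
  `beta3 = -8.5` per FU takes over at the phase-change fluorescence `fc`,
  joined smoothly by a softplus (log-logistic) transition of abruptness
  `|eta| = 0.04` per FU.  `fc` is *not* a free parameter: the engine sets it
  on the fly at the cycle in which 90% of the initial primers have been
  consumed.  With the standard primer load this transition kills the
  reaction within one or two cycles, producing the "angular" plateau of
  primer-depleted curves; with a 4x primer load the switch never fires and
  the curve rounds off at its kinetic ceiling instead.

The amplicon fluorescence is `F_n = f * N0 * prod_c E_c` by construction:
the engine multiplies copies by the cycle efficiency, converts to
fluorescence with the single-amplicon fluorescence `f` (default 1e-9
FU/amplicon, so the depletion plateau of a 260 nM / 25 uL reaction —
3.91e12 primers — sits near 3.9e3 FU), and book-keeps primers exactly: one
primer per new amplicon plus a per-repeat percentage `g` of the remaining
primers lost each cycle to unspecific side reactions.  The primer ledger

    primers[n-1] - primers[n] = (copies[n] - copies[n-1]) + side_loss[n]

holds to rounding on every cycle, and new copies are capped so primers can
never go negative (efficiency falls to 1 at exhaustion).

## Parameter links and calibration

Only `beta1` and `beta2` depend on the reaction's starting conditions:

    beta1 = -exp(a + b * ln(2.02 - Emax))            (slope link)
    beta2 = p + q * tanh(beta1 / 1e-3)               (curvature link)

Both are evaluated at the *nominal* `Emax` of the reaction setup: they are
systematic properties of the reaction chemistry, independent of `N0`, so
every repeat of a condition shares one decline profile.  The four
coefficients are calibrated once, by least squares, against five kinetic
anchors of the model (the package's reference behaviours): at
`N0 = 50,000`, `Emax = 1.90` the efficiency has declined by 0.01 at
fractional cycle 20.3 and passes 1.88 / 1.86 at fractional cycles 21.3 /
22.3; at `Emax = 1.95` the 5PLM second-derivative maximum falls at cycle
25.6 under excess primers; and, as structural constraints, uninhibited
reactions deplete their primers (switch near cycle 37 at `Emax = 1.90`)
while the self-limiting ceiling sits ~1.4x above the depletion plateau and
the switch never fires at 4x primers.  The depleting-scenario SDM lands at
26.4 (reference 26.7) — it was traded off against the structural
constraints.  The functional forms were chosen for qualitative fidelity
across the whole inhibition range: the slope link is strictly increasing
and negative on `(1, 2]` (a linear link would cross zero), and the
saturating curvature link keeps heavily inhibited declines concave and
finite instead of ever-steeper.  `beta2` changes sign across the range,
shifting the decline from convex over straight to concave as inhibition
grows.

## Variance components

Each technical repeat draws its stochastic inputs from independent,
separately switchable sources (codes in parentheses match the CLI):

| source | code | default | draw |
|---|---|---|---|
| template sampling | `i` | on | `N0 ~ Poisson(n0_mean)` (exact sampling; low-copy behaviour matters) |
| true initial efficiency | `E` | sd 0.01 | `emax_i ~ Normal(Emax, sigma)` truncated to (1, 2], entering through the intercept `c = ln(ln emax_i)` only |
| per-cycle efficiency error | `En` | rel. sd 0.002 | `E' = 1 + (E-1)(1+eps)`, `eps ~ Normal` — constant *relative* error, so the absolute perturbation shrinks toward the plateau and `E' >= 1` |
| primer pipetting | `p` | rel. sd 0.01 | scales the initial primer count |
| side reactions | `s` | `g ~ Normal(2.27, 0.47)` %/cycle, truncated >= 0 | fraction of remaining primers lost per cycle |
| kinetic jitter | `a` | rel. sd 0.02 | independent relative noise on `beta1`, `beta2` |
| baseline | — | intercept `~ N(200, 70)` FU, slope `~ N(0.7, 0.2)` FU/cycle | additive linear trend per repeat |
| camera | — | sd 1.75 FU | i.i.d. additive noise per cycle |

When `E` and `s` are both active their latent normals are coupled through a
Gaussian copula whose latent correlation is chosen so the *rank*
correlation between `emax_i` and retained-primer propensity (`-g`) equals
0.46: repeats destined to emerge early lose fewer primers and reach higher
plateaus.  With a rank correlation of 0.46 this is a pronounced tendency,
not a deterministic ordering — the emergence-order/plateau relation is
therefore tested as a negative Spearman correlation between Cq and plateau,
not as a strict argmin/argmax identity.

The `sigma_e_rel` and kinetic-jitter defaults are small stabilizing values
(no empirical magnitude exists for them); both are exposed in the config.
Per-cycle efficiency error is applied in both phases (config flag
`e_error_in_phase2`).

An emergent property worth noting: with only `E` variation active, the
plateau CV of depleting reactions is essentially independent of
`sigma_emax` (~0.012 at sigma 0.01, 0.05 and 0.1 alike).  The plateau is
pinned by the primer supply; what varies is only the sub-cycle phase at
which the depletion threshold is crossed, a band of relative width
`E_switch - 1 ~ 0.045` whose uniform spread gives CV ~ 0.045/sqrt(12).

## Quantification

* **Threshold Cq** — fractional first upward crossing of a cubic spline
  (not-a-knot end conditions) through the baseline-subtracted curve.
  Missing crossings return an explicit missing marker.  The default
  threshold policy for a repeat set places the threshold at the lowest
  fitted-curve fluorescence among the repeats' SDM positions, making it
  user-independent.
* **5PLM / SDM Cq** — a five-parameter logistic (Richards) curve
  `F = fb + (fmax - fb) (1 + exp(-(x - c)/b))^{-g}` fitted by multi-start
  Levenberg–Marquardt; the SDM is the first positive maximum of its
  analytic second derivative (for `g = 1`:
  `c - b ln(2 + sqrt(3))`).  `g` and `b` are restricted to [0.05, 20] and
  `c` to the data span ± one span: beyond these the Richards curve is
  numerically indistinguishable from its degenerate Gompertz limit
  (`g -> inf`, `c -> -inf` along a flat residual ridge), which makes the
  SDM of slow-plateau curves unstable.
* **Plateau** — mean of the final three baseline-subtracted cycles.

## Full-process-kinetics recovery

`fit_bilinear_to_curve` regresses `ln ln E_n` on `F_{n-1}` with the same
two-phase model family and reports `emax_hat = exp(exp(c_hat))`.  Numerical
choices: points are restricted to the rising portion of the curve (beyond
the plateau the ratio is 1 plus camera noise and keeping only the censored
ratios above 1 would bias the fit); the plateau-arrival cycle itself is
dropped (its realized efficiency is primer-capped, off the model curve);
weights follow the delta-method precision of `ln ln E` under additive
camera noise, `sd(y) ~ 1/(F E ln E)`; the curvature is profiled on a
sign-symmetric grid (the model is linear in `(c, beta1)` given `beta2`)
before Levenberg–Marquardt polish; and the two-phase variant (free `fc`) is
kept only when it clearly beats the single-phase fit, so excess-primer
curves fall back to the single-phase model.  At least 6 usable efficiency
points are required (config `min_points`) — on 60-cycle curves the decline
spans only ~8 cycles above the noise floor (3 camera sd, config), so a
stricter bound would discard a large share of noisy wells.

`estimate_initial_signal` back-propagates early-cycle fluorescence through
the fitted efficiency chain, `i0f = mean_n F_n / prod_{c<=n} E_hat_c`, over
the first `window = 5` cycles of the contiguous above-floor run that ends
at the curve maximum (isolated early floor crossings are
baseline-subtraction residue).  On noise-free curves this recovers
`f * N0` to well under 1%.

The dilution-series driver deliberately subtracts a *data-driven* linear
baseline (fitted to the ground phase) rather than the generated one: the
evaluation mimics an end-to-end analysis of thermocycler exports, and
baseline-estimation error is a real part of the recovery estimators'
dispersion.  Estimates outside the plausibility bound (1, 2.2] are excluded
and counted.  The per-source variance experiments, by contrast, use the
known generated baseline — there the question is the effect of a single
variance source, not baseline estimation.

## Problem sizes

The standard evaluations run at their natural sizes: 96 repeats per
variance experiment and a 9-point twofold dilution series (100,000 down to
~390 copies) with 89 repeats per point, trimmed to 800 reactions, analyzed
reaction by reaction.  A full acceptance run takes a few minutes on one
core.

## What the generator does and does not emulate

Simulated plates reproduce the dispersion structure of technical repeats:
Cq spread from template sampling and efficiency variation, plateau spread
from side-reaction competition, baseline and camera noise, and the
emergence-order/plateau coupling.  They do not emulate well-position
effects, inter-plate calibration, melting curves, sub-cycle chemistry
(annealing/elongation kinetics, polymerase inactivation) or sequence-
specific self-limiting behaviour; inhibition enters only through `Emax`.
Below `Emax ~ 1.7` the link extrapolation is qualitative only — declines
are very steep and reactions stall within a few FU — so conclusions there
rest on the model's contracts (monotone decline, no depletion within 60
cycles), not on quantitative anchors.

## Known limitations

* The recovery fit works with ~6–9 efficiency points per noisy curve, so
  per-curve efficiency estimates have sd ~0.03–0.05; about 10–15% of noisy
  wells fail the fit and are excluded (counted in the reports).
* The copy-estimate CV of the back-propagation estimator depends strongly
  on that fit dispersion (errors compound over ~20 cycles of the chain).
* The depleting-scenario SDM (26.4 vs the 26.7 reference) reflects the
  calibration trade-off described above.
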