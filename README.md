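# pcrsim

Stochastic simulation of real-time PCR (qPCR) amplification curves with
explicit, separately switchable variance components — and the estimators
needed to evaluate what those components do to downstream quantification.

qPCR results are routinely reported without a defensible measure of
precision, because the variation between technical repeats has many
entangled sources: Poisson sampling of template molecules, repeat-to-repeat
differences in true amplification efficiency, per-cycle efficiency noise,
pipetting, primer-consuming side reactions, baseline drift and camera
noise.  `pcrsim` generates realistic amplification curves from a
cycle-sequential kinetic model in which each of these sources can be turned
on and off individually, so their contribution to the spread of
quantification cycles (Cq) and plateau levels can be measured rather than
guessed.  It is aimed at assay developers and method researchers who want
to stress-test Cq estimators, efficiency-recovery algorithms or outlier
rules against data with a known ground truth.

## The model

Reaction efficiency `E_n` (fold change in amplicons per cycle) declines
with the accumulated amplicon fluorescence `F`.  On the double-log scale
the decline is bilinear with a curved first phase:

    ln ln E = c + β₁ u e^{β₂ u} + β₃ (F − u),      u = soft-min(F, F_c)

with intercept `c = ln ln E_max` (so the model at `F = 0` returns the
initial efficiency exactly), first-phase slope `β₁` and curvature `β₂`
linked to `E_max` by calibrated regressions, and a steep second phase
(`β₃ = −8.5`) that takes over at the phase-change fluorescence `F_c` —
determined on the fly at the cycle in which 90% of the primers have been
consumed.  Amplification is propagated cycle by cycle
(`F_n = f · N₀ · ∏ E_c`) with an exact primer ledger, including
side-reaction losses of `g` % of the remaining primers per cycle.  Cq is
estimated both by spline-interpolated fixed threshold and by the second-
derivative maximum (SDM) of a five-parameter logistic fit; a full-process-
kinetics fit recovers `E_max` and the initial signal from observed curves.
See `docs/methods.md` for the complete model description.

## Worked example

Simulate 96 technical repeats at 50,000 template copies with only
between-repeat efficiency variation active (`E_max ~ Normal(1.9, 0.01)`),
and summarize the repeat set:

```python
from pcrsim import ReactionConditions
from pcrsim.experiments import run_variance_experiment

cond = ReactionConditions(n0_mean=50_000, emax=1.90)
rep = run_variance_experiment(("E",), 96, cond, seed=11, sigma_emax=0.01)
print(f"sd(Cq, threshold) = {rep['sd_cq_threshold']:.3f} cycles")
print(f"sd(Cq, SDM)       = {rep['sd_cq_sdm']:.3f} cycles")
print(f"CV(plateau)       = {rep['cv_plateau']:.4f}")
```

prints

```
sd(Cq, threshold) = 0.201 cycles
sd(Cq, SDM)       = 0.198 cycles
CV(plateau)       = 0.0126
```

A 1% spread in true initial efficiency alone already produces a Cq spread
of ~0.2 cycles (the analytic sensitivity is `dCq/dE = Cq/(E ln E)`), while
the plateau stays within ~1.3% — the plateau of primer-depleted reactions
is pinned by the primer supply, so efficiency variation moves curves
sideways far more than it moves them up.

The same machinery drives a command-line generator:

```
pcrsim --n0 10000 --output-mode f --variation En,E,i,p,s,a \
       --baseline --reps 100 --seed 7 --out plate.csv
```

writes a 60-cycle × 100-well fluorescence table (modes: `i` amplicon
counts, `e` cycle efficiencies, `f` fluorescence, `p` the six model
parameters per reaction).

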