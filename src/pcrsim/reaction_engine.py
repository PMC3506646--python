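"""Cycle-sequential simulation of a single qPCR reaction.

Each cycle repeats three steps: the amplicon count of the previous cycle is
converted to fluorescence (F = f_amp * copies), the fluorescence yields the
cycle efficiency through the double-log model of the current phase, and the
amplicons are multiplied by that efficiency.  Primers are book-kept
explicitly: one primer is consumed per newly synthesized amplicon, and a
per-repeat percentage ``g`` of the remaining primers is additionally lost to
unspecific side reactions every cycle.  When 90% of the initial primers have
been consumed the reaction switches from the self-limiting first phase to
the primer-depletion second phase of the efficiency model; the phase-change
fluorescence ``fc`` is recorded on the fly at that cycle.

Amplicon counts are tracked as real numbers above the (integer) template
draw — the model is macroscopic and multiplicative.  Cycle 0 is the
pre-amplification state; reported curves are cycles 1..C, matching
thermocycler exports.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .efficiency_model import (
    BilinearParams,
    EFFICIENCY_FLOOR,
    ln2_efficiency,
    single_phase_ln2,
)
from .parameter_engine import (
    ReactionConditions,
    RepeatDraw,
    VariationConfig,
    draw_repeat_parameters,
)

__all__ = ["ReactionTrace", "CycleState", "advance_cycle", "check_phase_switch",
           "simulate_reaction", "add_observation_layer"]

#: fraction of initial primers whose consumption triggers the phase switch
PHASE_SWITCH_FRACTION = 0.10


@dataclass
class ReactionTrace:
    """Full per-cycle record of one simulated reaction.

    Arrays are indexed 0..cycles; index 0 is the pre-amplification state.
    ``observed`` (set by :func:`add_observation_layer`) covers cycles 1..C.
    """

    copies: np.ndarray
    eff: np.ndarray            # eff[0] is NaN; eff[n] is the realized efficiency of cycle n
    primers: np.ndarray
    f_amp: float
    switch_cycle: int | None
    fc_realized: float | None
    draw: RepeatDraw
    cond: ReactionConditions
    observed: np.ndarray | None = None

    @property
    def f_amp_fluor(self) -> np.ndarray:
        """Amplicon fluorescence per cycle, f_amp * copies (exact identity)."""
        return self.f_amp * self.copies

    @property
    def curve(self) -> np.ndarray:
        """Baseline-free amplicon fluorescence for cycles 1..C."""
        return self.f_amp_fluor[1:]

    @property
    def cycles(self) -> int:
        return len(self.copies) - 1


@dataclass
class CycleState:
    """Mutable per-cycle state threaded through :func:`advance_cycle`."""

    cycle: int
    copies: float
    primers: float
    phase: int                 # 1 = self-limiting, 2 = primer depletion
    p0: float                  # realized initial primer count
    params1: BilinearParams    # first-phase parameter set (fc = inf)
    params2: BilinearParams | None = None   # set at the phase switch
    switch_cycle: int | None = None
    fc_realized: float | None = None
    eff_last: float = math.nan


def advance_cycle(state: CycleState, draw: RepeatDraw, cond: ReactionConditions,
                  var: VariationConfig, rng: np.random.Generator | None = None) -> CycleState:
    """Advance the reaction by one cycle (efficiency, amplification, primers).

    New copies are capped so they never exceed the primers available after
    this cycle's side loss: primers can never go negative and the realized
    efficiency falls to 1 once they are exhausted.  The primer ledger is
    exact on every cycle:

        primers[n-1] - primers[n] = (copies[n] - copies[n-1]) + side_loss[n]
    """
    f_prev = cond.f_amp * state.copies
    if state.phase == 1:
        y = single_phase_ln2(f_prev, state.params1)
    else:
        y = ln2_efficiency(f_prev, state.params2)
    e = float(np.clip(math.exp(math.exp(y)), EFFICIENCY_FLOOR, 2.0))

    if var.e_cycle_error and var.sigma_e_rel > 0 and rng is not None \
            and (state.phase == 1 or var.e_error_in_phase2):
        # constant *relative* error on the increment keeps E >= 1 and shrinks
        # the absolute perturbation as the reaction plateaus
        e = 1.0 + (e - 1.0) * max(1.0 + rng.normal(0.0, var.sigma_e_rel), 0.0)

    side_loss = (draw.g_i / 100.0) * state.primers
    available = state.primers - side_loss
    delta = state.copies * (e - 1.0)
    if delta > available:
        delta = available
        e = 1.0 + delta / state.copies if state.copies > 0 else 1.0

    state.copies += delta
    state.primers -= delta + side_loss
    state.cycle += 1
    state.eff_last = e
    check_phase_switch(state, cond)
    return state


def check_phase_switch(state: CycleState, cond: ReactionConditions) -> bool:
    """Switch to phase II once primers have fallen to 10% of their start.

    Fires at most once; records the switch cycle and the phase-change
    fluorescence (the amplicon fluorescence of the cycle that crossed the
    threshold), which parameterizes the second-phase efficiency branch.
    """
    if state.phase == 1 and state.primers <= PHASE_SWITCH_FRACTION * state.p0:
        state.phase = 2
        state.switch_cycle = state.cycle
        state.fc_realized = max(cond.f_amp * state.copies, 1e-300)
        state.params2 = state.params1.with_fc(state.fc_realized)
        return True
    return state.phase == 2


def simulate_reaction(cond: ReactionConditions, var: VariationConfig,
                      rng: np.random.Generator | None = None,
                      draw: RepeatDraw | None = None) -> ReactionTrace:
    """Simulate one full reaction and return its trace.

    ``draw`` may be supplied to reuse a fixed set of repeat-level inputs;
    otherwise it is drawn from ``var`` using ``rng``.  With all variation
    off the trace is fully deterministic (identical across seeds).
    """
    if rng is None:
        rng = np.random.default_rng()
    if draw is None:
        draw = draw_repeat_parameters(cond, var, rng)

    n = cond.cycles
    copies = np.empty(n + 1)
    eff = np.full(n + 1, np.nan)
    primers = np.empty(n + 1)

    state = CycleState(
        cycle=0,
        copies=float(draw.n0),
        primers=draw.primer_count,
        phase=1,
        p0=draw.primer_count,
        params1=draw.bilinear,
    )
    copies[0] = state.copies
    primers[0] = state.primers
    for k in range(1, n + 1):
        advance_cycle(state, draw, cond, var, rng)
        copies[k] = state.copies
        primers[k] = state.primers
        eff[k] = state.eff_last

    trace = ReactionTrace(
        copies=copies, eff=eff, primers=primers, f_amp=cond.f_amp,
        switch_cycle=state.switch_cycle, fc_realized=state.fc_realized,
        draw=draw, cond=cond,
    )
    return trace


def add_observation_layer(trace: ReactionTrace, var: VariationConfig,
                          rng: np.random.Generator | None = None) -> np.ndarray:
    """Assemble the observed fluorescence for cycles 1..C.

    observed[n] = amplicon fluorescence + (intercept + slope * n) + camera
    noise.  The baseline is an independent additive process drawn once per
    repeat (stored in the trace's draw); camera noise is i.i.d. normal per
    cycle.  The result is stored on the trace and returned.
    """
    n = trace.cycles
    cyc = np.arange(1, n + 1, dtype=float)
    obs = trace.f_amp_fluor[1:].copy()
    obs += trace.draw.baseline_intercept + trace.draw.baseline_slope * cyc
    if var.camera and var.camera_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        obs += rng.normal(0.0, var.camera_sd, size=n)
    trace.observed = obs
    return obs
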