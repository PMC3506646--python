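import math
from dataclasses import replace

import numpy as np
import pytest

from pcrsim.efficiency_model import efficiency_at, single_phase_ln2
from pcrsim.parameter_engine import (
    ReactionConditions,
    VariationConfig,
    draw_repeat_parameters,
)
from pcrsim.reaction_engine import (
    PHASE_SWITCH_FRACTION,
    add_observation_layer,
    simulate_reaction,
)


def naive_reference_loop(cond, draw):
    """Second, deliberately naive implementation of the cycle loop."""
    copies, primers = float(draw.n0), draw.primer_count
    p = draw.bilinear
    phase, fc = 1, None
    out_c, out_p, out_e = [copies], [primers], [math.nan]
    for _ in range(cond.cycles):
        f = cond.f_amp * copies
        if phase == 1:
            y = single_phase_ln2(f, p)
        else:
            y = float(
                __import__("pcrsim.efficiency_model", fromlist=["ln2_efficiency"])
                .ln2_efficiency(f, p.with_fc(fc)))
        e = min(max(math.exp(math.exp(y)), 1 + 1e-12), 2.0)
        side = draw.g_i / 100.0 * primers
        delta = copies * (e - 1.0)
        avail = primers - side
        if delta > avail:
            delta = avail
            e = 1.0 + delta / copies if copies else 1.0
        copies += delta
        primers -= delta + side
        out_c.append(copies)
        out_p.append(primers)
        out_e.append(e)
        if phase == 1 and primers <= PHASE_SWITCH_FRACTION * draw.primer_count:
            phase, fc = 2, cond.f_amp * copies
    return np.array(out_c), np.array(out_p), np.array(out_e)


class TestAdvanceAndSimulate:
    def test_doubling_cycle(self, var_none):
        cond = ReactionConditions(n0_mean=100, emax=2.0, cycles=1)
        tr = simulate_reaction(cond, var_none, np.random.default_rng(0))
        assert tr.copies[1] == pytest.approx(200.0)

    def test_matches_naive_loop(self, var_none):
        cond = ReactionConditions(n0_mean=50_000, emax=1.93)
        draw = draw_repeat_parameters(cond, var_none, np.random.default_rng(0))
        draw = replace(draw, g_i=1.8)       # exercise side loss too
        tr = simulate_reaction(cond, var_none, np.random.default_rng(0), draw=draw)
        c, p, e = naive_reference_loop(cond, draw)
        np.testing.assert_allclose(tr.copies, c, rtol=1e-12)
        np.testing.assert_allclose(tr.primers, p, rtol=1e-12)
        np.testing.assert_allclose(tr.eff[1:], e[1:], rtol=1e-12)

    def test_primer_ledger_conservation(self, var_none):
        cond = ReactionConditions(n0_mean=20_000, emax=1.9)
        draw = draw_repeat_parameters(cond, var_none, np.random.default_rng(1))
        draw = replace(draw, g_i=2.27)
        tr = simulate_reaction(cond, var_none, np.random.default_rng(1), draw=draw)
        consumed = -np.diff(tr.primers)
        amplified = np.diff(tr.copies)
        side = draw.g_i / 100.0 * tr.primers[:-1]
        np.testing.assert_allclose(consumed, amplified + side, rtol=1e-12, atol=1e-3)

    def test_no_side_loss_conservation(self, var_none):
        cond = ReactionConditions(n0_mean=20_000, emax=1.9)
        tr = simulate_reaction(cond, var_none, np.random.default_rng(2))
        used = tr.primers[0] - tr.primers[-1]
        assert used == pytest.approx(tr.copies[-1] - tr.copies[0], rel=1e-12)

    def test_copies_monotone_primers_nonnegative(self, var_none):
        cond = ReactionConditions(n0_mean=100, emax=1.95)
        tr = simulate_reaction(cond, var_none, np.random.default_rng(3))
        assert np.all(np.diff(tr.copies) >= 0)
        assert np.all(tr.primers >= 0)

    def test_plateau_bounded_by_initial_reagents(self, var_none):
        cond = ReactionConditions(n0_mean=50_000, emax=1.95)
        tr = simulate_reaction(cond, var_none, np.random.default_rng(4))
        assert tr.copies[-1] <= tr.draw.n0 + tr.draw.primer_count + 1e-3
        assert tr.copies[-1] == pytest.approx(3.9e12, rel=0.05)

    def test_amplicon_fluorescence_identity(self, var_none):
        cond = ReactionConditions(n0_mean=1000, emax=1.9)
        tr = simulate_reaction(cond, var_none, np.random.default_rng(5))
        np.testing.assert_array_equal(tr.f_amp_fluor, cond.f_amp * tr.copies)

    def test_deterministic_across_seeds_without_variation(self, var_none):
        cond = ReactionConditions(n0_mean=777, emax=1.88)
        a = simulate_reaction(cond, var_none, np.random.default_rng(0))
        b = simulate_reaction(cond, var_none, np.random.default_rng(999))
        np.testing.assert_array_equal(a.copies, b.copies)


class TestPhaseSwitch:
    def test_switch_fires_at_90_percent_consumption(self, var_none):
        cond = ReactionConditions(n0_mean=50_000, emax=1.95)
        tr = simulate_reaction(cond, var_none, np.random.default_rng(0))
        k = tr.switch_cycle
        assert k is not None
        assert tr.primers[k] <= 0.1 * tr.draw.primer_count
        assert tr.primers[k - 1] > 0.1 * tr.draw.primer_count
        assert tr.fc_realized == pytest.approx(tr.f_amp_fluor[k])

    def test_no_switch_with_excess_primers(self, fig7_traces):
        assert fig7_traces["self_limiting"].switch_cycle is None
        assert fig7_traces["depleting"].switch_cycle is not None

    def test_depleting_plateau_more_angular(self, fig7_traces):
        # after the switch the depleting curve reaches its plateau within
        # a few cycles; the self-limiting curve keeps creeping
        dep = fig7_traces["depleting"]
        k = dep.switch_cycle
        assert dep.curve[min(k + 3, dep.cycles - 1)] >= 0.99 * dep.curve[-1]

    def test_plateau_saturates_beyond_depletion_point(self, var_none):
        # once primers are in excess, adding more barely moves the plateau
        plats = []
        for mult in (4.0, 8.0):
            cond = ReactionConditions(n0_mean=50_000, emax=1.95,
                                      primer_conc=260.0 * mult)
            tr = simulate_reaction(cond, var_none, np.random.default_rng(0))
            plats.append(tr.curve[-1])
        assert abs(plats[1] - plats[0]) / plats[0] < 0.05


class TestObservationLayer:
    def test_identity_without_baseline_and_camera(self, var_none):
        cond = ReactionConditions(n0_mean=1000, emax=1.9)
        tr = simulate_reaction(cond, var_none, np.random.default_rng(0))
        obs = add_observation_layer(tr, var_none, np.random.default_rng(0))
        np.testing.assert_array_equal(obs, tr.f_amp_fluor[1:])

    def test_baseline_is_exactly_linear(self):
        var = VariationConfig.none(baseline=True)
        cond = ReactionConditions(n0_mean=1000, emax=1.9)
        rng = np.random.default_rng(1)
        tr = simulate_reaction(cond, var, rng)
        obs = add_observation_layer(tr, var, rng)
        resid = obs - tr.f_amp_fluor[1:]
        # second difference of a linear sequence is zero
        np.testing.assert_allclose(np.diff(resid, 2), 0.0, atol=1e-9)

    def test_camera_noise_magnitude(self, var_none):
        var = VariationConfig.none(camera=True)
        cond = ReactionConditions(n0_mean=1000, emax=1.9)
        tr = simulate_reaction(cond, var_none, np.random.default_rng(2))
        rng = np.random.default_rng(3)
        resid = []
        for _ in range(200):
            obs = add_observation_layer(tr, var, rng)
            resid.extend(obs - tr.f_amp_fluor[1:])
        assert np.std(resid) == pytest.approx(1.75, rel=0.02)
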