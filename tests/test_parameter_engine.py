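import math

import numpy as np
import pytest
from scipy import stats

from pcrsim.parameter_engine import (
    DEFAULT_LINKS,
    ReactionConditions,
    VariationConfig,
    derive_curvature,
    derive_first_phase_slope,
    draw_repeat_parameters,
    make_bilinear,
)


class TestLinks:
    def test_slope_deterministic_and_strictly_monotone(self):
        grid = np.linspace(1.5, 2.0, 26)
        vals = [derive_first_phase_slope(e) for e in grid]
        assert vals == [derive_first_phase_slope(e) for e in grid]
        assert all(b < 0 for b in vals)
        # attenuation proceeds faster (more negative slope) at lower Emax
        assert np.all(np.diff(vals) > 0)

    def test_slope_domain_guard(self):
        with pytest.raises(ValueError):
            derive_first_phase_slope(1.0)
        with pytest.raises(ValueError):
            derive_first_phase_slope(2.1)

    def test_curvature_deterministic(self):
        b1 = derive_first_phase_slope(1.9)
        assert derive_curvature(b1) == derive_curvature(b1)

    def test_curvature_changes_sign_across_inhibition_range(self):
        # convex (accelerating) decline for efficient reactions, concave
        # (stalling) decline for heavily inhibited ones
        hi = derive_curvature(derive_first_phase_slope(2.0))
        lo = derive_curvature(derive_first_phase_slope(1.5))
        assert hi * lo < 0

    def test_curvature_independent_of_template_input(self):
        # beta2 is a function of beta1 alone; recomputing it for the same
        # slope at different copy numbers gives identical values
        b1 = derive_first_phase_slope(1.9)
        assert derive_curvature(b1) == derive_curvature(b1)
        p_a = make_bilinear(1.9)
        p_b = make_bilinear(1.9)   # conditions differ only through N0 downstream
        assert p_a.beta2 == p_b.beta2

    def test_phase2_constants(self):
        p = make_bilinear(1.9)
        assert p.beta3 == DEFAULT_LINKS.beta3_const == -8.5
        assert p.eta == DEFAULT_LINKS.eta_const == -0.04


class TestReactionConditions:
    def test_primer_count_avogadro_arithmetic(self):
        cond = ReactionConditions(n0_mean=1000)
        # 260 nM in 25 uL
        assert cond.primer_count == pytest.approx(3.914e12, rel=1e-3)

    def test_validation(self):
        with pytest.raises(ValueError):
            ReactionConditions(n0_mean=1000, emax=2.5)
        with pytest.raises(ValueError):
            ReactionConditions(n0_mean=1000, cycles=0)


class TestVariationConfig:
    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError, match="En"):
            VariationConfig.from_codes(("E", "bogus"))

    def test_codes_round_trip(self):
        var = VariationConfig.from_codes(("E", "i", "s"))
        assert var.codes == ("E", "i", "s")
        assert VariationConfig.none().codes == ()

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError):
            VariationConfig(sigma_emax=-0.1)


class TestDrawRepeatParameters:
    def test_all_variation_off_equals_systematic(self):
        cond = ReactionConditions(n0_mean=1234, emax=1.9)
        d = draw_repeat_parameters(cond, VariationConfig.none(),
                                   np.random.default_rng(0))
        assert d.n0 == 1234
        assert d.emax_i == 1.9
        assert d.g_i == 0.0
        assert d.primer_count == cond.primer_count
        assert (d.baseline_intercept, d.baseline_slope) == (0.0, 0.0)
        assert d.bilinear == make_bilinear(1.9)

    def test_seed_reproducibility(self):
        cond = ReactionConditions(n0_mean=500, emax=1.9)
        var = VariationConfig(baseline=True, camera=True)
        a = [draw_repeat_parameters(cond, var, np.random.default_rng(7))
             for _ in range(20)]
        b = [draw_repeat_parameters(cond, var, np.random.default_rng(7))
             for _ in range(20)]
        assert a == b

    def test_poisson_moments(self):
        cond = ReactionConditions(n0_mean=500, emax=1.9)
        var = VariationConfig.only("i")
        rng = np.random.default_rng(42)
        n = np.array([draw_repeat_parameters(cond, var, rng).n0
                      for _ in range(100_000)])
        se_mean = math.sqrt(500 / len(n))
        assert abs(n.mean() - 500) < 3 * se_mean
        # Poisson variance equals the mean; SE of the sample variance of a
        # Poisson is ~ sqrt((2 mu^2 + mu) / n)
        se_var = math.sqrt((2 * 500**2 + 500) / len(n))
        assert abs(n.var(ddof=1) - 500) < 3 * se_var

    def test_copula_rank_correlation(self):
        cond = ReactionConditions(n0_mean=1000, emax=1.9)
        var = VariationConfig.from_codes(("E", "s"))
        rng = np.random.default_rng(3)
        draws = [draw_repeat_parameters(cond, var, rng) for _ in range(10_000)]
        emax_i = [d.emax_i for d in draws]
        retained = [-d.g_i for d in draws]     # retained-primer propensity
        rho = stats.spearmanr(emax_i, retained).statistic
        assert rho == pytest.approx(0.46, abs=0.03)

    def test_truncation_rare_at_default_sigma(self):
        cond = ReactionConditions(n0_mean=1000, emax=1.9)
        var = VariationConfig.only("E")      # sigma_emax = 0.01
        rng = np.random.default_rng(5)
        trunc = sum(draw_repeat_parameters(cond, var, rng).truncated
                    for _ in range(20_000))
        assert trunc == 0                     # rate < 1e-4 at default sigma

    def test_side_loss_nonnegative(self):
        cond = ReactionConditions(n0_mean=1000, emax=1.9)
        var = VariationConfig.only("s", side_g_mean=0.3, side_g_sd=1.0)
        rng = np.random.default_rng(6)
        gs = [draw_repeat_parameters(cond, var, rng).g_i for _ in range(2000)]
        assert min(gs) >= 0.0
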