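import numpy as np
import pytest

from pcrsim import ReactionConditions, VariationConfig, simulate_reaction


@pytest.fixture
def var_none():
    return VariationConfig.none()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noise_free_trace(var_none):
    """Reference noise-free depleting reaction (N0=50,000, Emax=1.90)."""
    cond = ReactionConditions(n0_mean=50_000, emax=1.90)
    return simulate_reaction(cond, var_none, np.random.default_rng(0))


@pytest.fixture
def fig7_traces(var_none):
    """The two canonical Emax=1.95 scenarios: excess primers (self-limiting)
    and standard 1x primers (depleting)."""
    out = {}
    for key, mult in (("self_limiting", 4.0), ("depleting", 1.0)):
        cond = ReactionConditions(n0_mean=50_000, emax=1.95,
                                  primer_conc=260.0 * mult)
        out[key] = simulate_reaction(cond, var_none, np.random.default_rng(0))
    return out
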