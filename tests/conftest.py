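import numpy as np
import pytest

from phylosector import seqsim as sim

# The reference study conditions: L = 200 with a 20-site sector of mean
# effect 5 (variance 0.25) over a 0.5-mean background, kappa normalised so
# kappa * sum(D_i^2) = 10, favoured trait tau* = 90.
EFFECT_SEED = 12345


@pytest.fixture(scope="session")
def reference_effects() -> sim.EffectVector:
    return sim.make_effect_vector(seed=EFFECT_SEED)


@pytest.fixture(scope="session")
def reference_params(reference_effects) -> sim.SelectionParams:
    return sim.SelectionParams(
        kappa=sim.kappa_for_target(reference_effects.D), tau_star=90.0
    )


@pytest.fixture(scope="session")
def small_effects() -> sim.EffectVector:
    return sim.make_effect_vector(L=40, L_S=6, seed=7)


@pytest.fixture(scope="session")
def small_params(small_effects) -> sim.SelectionParams:
    return sim.SelectionParams(kappa=sim.kappa_for_target(small_effects.D), tau_star=18.0)


@pytest.fixture(scope="session")
def equilibrium_msa(reference_effects, reference_params) -> sim.BinaryMSA:
    """One M = 2048 equilibrium alignment under the reference conditions."""
    return sim.sample_equilibrium_msa(2048, reference_effects, reference_params, seed=401)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
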