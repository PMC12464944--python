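import numpy as np
import pytest

from contraconn import synthetic_cohort as syn


@pytest.fixture(scope="session")
def toy_atlas():
    """Small mirror-symmetric atlas: 10 ROIs per hemisphere on a 16^3 grid."""
    return syn.generate_atlas(10, (16, 16, 16), seed=7)


@pytest.fixture(scope="session")
def test_atlas():
    """Default-size test atlas: 20 ROIs per hemisphere on a 24^3 grid."""
    return syn.generate_atlas(20, (24, 24, 24), seed=1)


@pytest.fixture(scope="session")
def null_cohort(toy_atlas):
    """No-signal cohort (delta=0): patients and controls exchangeable."""
    return syn.generate_cohort(
        toy_atlas, 12, 20, syn.EffectConfig(delta=0.0, noise_sd=1.0, seed=11)
    )


@pytest.fixture(scope="session")
def effect_cohort(test_atlas):
    """Cohort with a strong injected group effect (delta=1.5)."""
    return syn.generate_cohort(
        test_atlas, 48, 107, syn.EffectConfig(delta=1.5, noise_sd=1.0, seed=42)
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
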