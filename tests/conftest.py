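import numpy as np
import pytest

from ulkswitch.model import (
    RateConstants,
    physiological_steady_state,
    reference_rates,
)


@pytest.fixture(scope="session")
def ref_rates() -> RateConstants:
    """The shipped reference (generator-truth) rate constants."""
    return reference_rates()


@pytest.fixture(scope="session")
def phys_state(ref_rates):
    """Physiological resting state of the reference model."""
    return physiological_steady_state(ref_rates)


@pytest.fixture(scope="session")
def uncoupled_rates() -> RateConstants:
    """Basal-only kinetics: all six interaction constants exactly zero.

    Basal rates are fast enough that the acute treatment transients carry
    information about them within the 60-min sampling window.
    """
    return RateConstants(
        ka_m=0.05, ki_m=0.05, ka_u=0.05, ki_u=0.05, ka_p=0.05, ki_p=0.05,
        k_a=0.0, k_b=0.0, k_c=0.0, k_d=0.0, k_e=0.0, k_f=0.0,
    )


def random_rates(rng: np.random.Generator, jitter_around=None) -> RateConstants:
    """Log-uniform random rate set, optionally jittered around a base set."""
    from ulkswitch.model import RATE_NAMES

    if jitter_around is None:
        vals = 10.0 ** rng.uniform(-2.5, 1.0, 12)
    else:
        vals = jitter_around.as_array() * 10.0 ** rng.uniform(-0.5, 0.5, 12)
    return RateConstants(**dict(zip(RATE_NAMES, vals)))
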