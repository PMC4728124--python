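import numpy as np
import pytest

from smfspipe.polymer import LoadingContext, bell_evans_params_for_mode
from smfspipe.simulate import (
    ComplexSpec,
    DomainSpec,
    SimulationConfig,
    default_complex,
)

DX = 0.4


@pytest.fixture
def loading():
    return LoadingContext(pulling_speed=800.0, effective_stiffness=15.0)


def make_domain(name, gain, fstar, loading=None):
    loading = loading or LoadingContext(800.0, 15.0)
    return DomainSpec(name, gain, bell_evans_params_for_mode(fstar, DX, loading))


def make_complex(p_a, sub_fstar=120.0, final_a=140.0, final_b=104.0, loading=None):
    loading = loading or LoadingContext(800.0, 15.0)
    return ComplexSpec(
        mode_A_probability=p_a,
        sub_barrier=bell_evans_params_for_mode(sub_fstar, DX, loading),
        final_barrier_A=bell_evans_params_for_mode(final_a, DX, loading),
        final_barrier_B=bell_evans_params_for_mode(final_b, DX, loading),
    )


@pytest.fixture
def clean_modea_config():
    """Deterministic pathway: weak fingerprint << weak sub-step << final.

    Every trace unfolds the fingerprint first, then the complex sub-step,
    then ruptures: no censoring, no early doubles.
    """
    return SimulationConfig(
        fingerprint=make_domain("xylanase", 89.0, 60.0),
        complex=make_complex(1.0, sub_fstar=95.0, final_a=140.0),
        force_noise_sd=1e-9,
    )


@pytest.fixture
def uncensored_config():
    """50/50 binding modes with a fingerprint too weak to censor anything."""
    return SimulationConfig(
        fingerprint=make_domain("xylanase", 89.0, 60.0),
        complex=make_complex(0.5, sub_fstar=95.0),
        force_noise_sd=1e-9,
    )
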