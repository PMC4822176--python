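import numpy as np
import pytest

from ppscct import synthgen


@pytest.fixture
def tiny_design():
    return synthgen.ExperimentDesign(
        groups=("control",), conditions=("real",),
        n_participants_per_group=1)


@pytest.fixture
def noise_free_effects():
    return synthgen.EffectSpec(
        error_rate=0.0, residual_sd_ms=0.0, participant_sd_ms=0.0,
        cce_contra_ms={"real": 30.0}, cce_ipsi_extra_ms={"real": 70.0})


@pytest.fixture
def rng():
    return np.random.default_rng(20260904)
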