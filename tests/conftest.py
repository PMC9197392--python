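import numpy as np
import pytest

from cerebellopipe import (
    EphysSimConfig,
    FootprintSequence,
    GaitSimConfig,
    gen_evoked_train,
    gen_footprints,
    gen_protocol,
)


@pytest.fixture
def low_freq_protocol():
    """150-pulse probing protocol (100 ms pulses at 0.25 Hz)."""
    return gen_protocol("low_freq", 600.0)


@pytest.fixture
def poisson_train(low_freq_protocol):
    """A null unit: homogeneous Poisson firing, no evoked response."""
    cfg = EphysSimConfig(evoked_delta={r: 0.0 for r in
                                       ("DN", "VAL", "CL", "M1", "DLS")},
                         seed=42)
    train, _ = gen_evoked_train(cfg, low_freq_protocol, "VAL", 600.0)
    return train


@pytest.fixture
def ideal_footprints():
    """Noiseless alternating gait: 5 cm steps, 3 cm lateral separation."""
    fp, truth = gen_footprints(GaitSimConfig(
        n_steps=11, step_length=5.0, gait_width=3.0, seed=0))
    return fp, truth


def make_footprints(x, y, sides):
    return FootprintSequence(np.asarray(x, float), np.asarray(y, float),
                             np.asarray(sides))
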