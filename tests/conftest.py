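"""Shared fixtures: all synthetic, generated at test time."""

from __future__ import annotations

import numpy as np
import pytest

from puffquant import quantify, synth
from puffquant.trace import PuffProtocol

PUFF_ONSET = 0.2


@pytest.fixture(scope="session")
def template_trace():
    """Noiseless mean-neuron voltage-clamp template, single 1 mM puff."""
    return synth.make_template_current()


@pytest.fixture(scope="session")
def template_baseline(template_trace):
    return quantify.estimate_baseline(template_trace, PUFF_ONSET)


@pytest.fixture(scope="session")
def cc_default():
    """Noiseless mean-neuron current-clamp response to a 1 mM puff."""
    return synth.synthesize_cc_recording(noise_sd=0.0, seed=0)


@pytest.fixture(scope="session")
def cc_noisy():
    """Same recording with the default recording noise."""
    return synth.synthesize_cc_recording(seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def single_puff(concentration: float = 1000.0) -> PuffProtocol:
    return PuffProtocol.single_puff(onset=PUFF_ONSET, concentration=concentration)
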