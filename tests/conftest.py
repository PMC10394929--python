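"""Shared fixtures: reduced network configurations and small synthetic ears."""

import numpy as np
import pytest

from spikecount.hrnet import HRNetConfig, build_network
from spikecount.synthetic import EarSpec, generate_ear


def tiny_config(**overrides):
    """A width- and depth-reduced network for fast training/inference tests."""
    kwargs = dict(
        base_width=4,
        stem_width=8,
        stage_modules=(1, 1, 1),
        stage1_blocks=2,
        blocks_per_branch=2,
    )
    kwargs.update(overrides)
    return HRNetConfig(**kwargs)


@pytest.fixture
def tiny_network():
    return build_network(tiny_config(), seed=7)


def small_ear_spec(**overrides):
    """Ears rendered natively at 112 px with proportionally large grains."""
    kwargs = dict(
        edge=112,
        grains_per_side=(4, 6),
        major_axis=(20.0, 26.0),
        minor_axis=(13.0, 17.0),
        adhesion=0.1,
    )
    kwargs.update(overrides)
    return EarSpec(**kwargs)


@pytest.fixture
def small_training_set():
    """Five 96-px ear sides as (image, mask) pairs keyed by id."""
    samples = {}
    for i in range(5):
        s = generate_ear(small_ear_spec(), seed=i)
        samples[i] = (s.image.astype(np.float32).transpose(2, 0, 1) / 255.0, s.mask)
    return samples
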