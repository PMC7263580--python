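"""Shared fixtures: small phantom sets and a trained toy network.

The trained fixture is session-scoped because training even a toy network
dominates test runtime; every test that needs "a trained network" shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

from braincbir.nn.network import MultiScaleNet, NetworkConfig
from braincbir.phantoms import PhantomSpec, generate_phantom_set
from braincbir.training import TrainConfig, train

TOY_NET_CFG = NetworkConfig(
    input_size=32, module_channels=(8, 16, 32), feature_dim=64, n_classes=3
)


@pytest.fixture(scope="session")
def phantom_set():
    """36 noise-free 32x32 phantoms, 3 classes, both modalities."""
    spec = PhantomSpec(
        image_size=32, n_classes=3, n_per_class=12, modality_mix=0.5,
        noise_sigma=0.0, seed=11,
    )
    return generate_phantom_set(spec)


@pytest.fixture(scope="session")
def trained_toy(phantom_set):
    """A toy network trained on the small phantom set, with its report."""
    net = MultiScaleNet(TOY_NET_CFG, seed=5)
    report = train(
        net,
        phantom_set,
        TrainConfig(epochs=25, batch_size=8, seed=7, val_fraction=0.2),
    )
    return net, report


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
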