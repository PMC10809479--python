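"""Shared small synthetic fixtures, session-scoped for speed."""
import numpy as np
import pytest

from picov.datatypes import DVC, SVC
from picov.synthetic import (build_perfusion_model, generate_vascular_network,
                             simulate_stack)

SIZE = 96


@pytest.fixture(scope="session")
def svc_network():
    return generate_vascular_network(11, SVC, SIZE)


@pytest.fixture(scope="session")
def dvc_network():
    return generate_vascular_network(12, DVC, SIZE)


@pytest.fixture(scope="session")
def dvc_stack(dvc_network):
    perf = build_perfusion_model(dvc_network, 0.15, seed=13)
    stack, gt = simulate_stack(dvc_network, perf, 10, 0.02, seed=14)
    return stack, gt


@pytest.fixture(scope="session")
def svc_stack(svc_network):
    perf = build_perfusion_model(svc_network, 0.12, seed=15)
    stack, gt = simulate_stack(svc_network, perf, 10, 0.02, seed=16)
    return stack, gt


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
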