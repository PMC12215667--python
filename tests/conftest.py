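"""Shared fixtures: toy architectures and small synthetic datasets."""

from __future__ import annotations

import numpy as np
import pytest

from ltadetect.ecgnet import ArchitectureSpec, build_model
from ltadetect.trainer import FtArrays


@pytest.fixture(scope="session")
def toy_spec() -> ArchitectureSpec:
    """Smallest valid backbone: 8 blocks (the minimum that maps 1792 -> 7),
    4 initial filters, short kernels — fast enough for contract tests."""
    return ArchitectureSpec(
        n_blocks=8, initial_filters=4, doubling_period=4, kernel=8, head="v1"
    )


@pytest.fixture()
def toy_model(toy_spec):
    return build_model(toy_spec, seed=123)


def random_ft_arrays(n: int, seed: int, separable: bool = True) -> FtArrays:
    """Random FT-style arrays; ``separable`` plants a bandlike feature so a
    model can learn the labels (high-variance oscillation for LTA)."""
    rng = np.random.default_rng(seed)
    labels = (rng.random((n, 7)) < 0.3).astype(int)
    mask = rng.random((n, 7)) > 0.05
    x = rng.normal(0, 0.3, size=(n, 1792)).astype(np.float32)
    if separable:
        t = np.arange(256) / 200.0
        burst = np.sin(2 * np.pi * 5.0 * t).astype(np.float32)
        for i in range(n):
            for j in range(7):
                if labels[i, j]:
                    x[i, j * 256 : (j + 1) * 256] += 2.0 * burst
    return FtArrays(x, labels, mask)


@pytest.fixture()
def tiny_ft():
    return random_ft_arrays(24, seed=0)


@pytest.fixture()
def tiny_ft_val():
    return random_ft_arrays(12, seed=1)
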