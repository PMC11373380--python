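"""Shared fixtures: small seeded SEM datasets with known structure."""

import numpy as np
import pytest

from pcnt import ExpressionMatrix


def make_collider(n: int, seed: int = 0, w1: float = 1.0, w2: float = 1.0) -> ExpressionMatrix:
    """X -> Y <- Z with unit Gaussian noise; columns ordered (X, Y, Z)."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    z = rng.normal(size=n)
    y = w1 * x + w2 * z + rng.normal(size=n)
    return ExpressionMatrix(np.column_stack([x, y, z]), ["X", "Y", "Z"])


def make_chain(n: int, seed: int = 0) -> ExpressionMatrix:
    """X -> Y -> Z, unit weights, unit Gaussian noise."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = x + rng.normal(size=n)
    z = y + rng.normal(size=n)
    return ExpressionMatrix(np.column_stack([x, y, z]), ["X", "Y", "Z"])


def make_independent(n: int, d: int = 3, seed: int = 0) -> ExpressionMatrix:
    rng = np.random.default_rng(seed)
    return ExpressionMatrix(rng.normal(size=(n, d)))


@pytest.fixture
def collider_data() -> ExpressionMatrix:
    return make_collider(10_000, seed=2)


@pytest.fixture
def chain_data() -> ExpressionMatrix:
    return make_chain(10_000, seed=2)
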