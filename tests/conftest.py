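import numpy as np
import pytest


class LinearEncoder:
    """Deterministic analytic encoder: fixed random linear map of the flat patch.

    Cheap, positionless, and exactly order-independent — the workhorse for
    arithmetic-identity tests where a trained network is irrelevant.
    """

    def __init__(self, patch_side: int, n_labels: int, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.W = rng.normal(0, 1, size=(patch_side * patch_side, n_labels))
        self.b = rng.normal(0, 1, size=n_labels)
        self.n_labels = n_labels
        self.patch_side = patch_side

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        return patches.reshape(patches.shape[0], -1) @ self.W + self.b


class ConstantEncoder:
    """Ignores input entirely; returns a fixed logit vector for every patch."""

    def __init__(self, vector):
        self.vector = np.asarray(vector, dtype=float)
        self.n_labels = self.vector.shape[0]

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        return np.tile(self.vector, (patches.shape[0], 1))


class CountingEncoder:
    """Wraps another encoder and counts forward-pass invocations."""

    def __init__(self, inner):
        self.inner = inner
        self.n_labels = inner.n_labels
        self.calls = 0
        self.patches_seen = 0

    def __call__(self, patches: np.ndarray) -> np.ndarray:
        self.calls += 1
        self.patches_seen += patches.shape[0]
        return self.inner(patches)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def linear_encoder():
    return LinearEncoder(patch_side=4, n_labels=3, seed=7)
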