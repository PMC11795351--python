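import numpy as np
import pandas as pd
import pytest

from gmethods import CausalFrame, ModelSpec, toy8


@pytest.fixture
def toy8_frame() -> CausalFrame:
    return toy8()


@pytest.fixture
def saturated_c() -> ModelSpec:
    """Saturated single-confounder spec for the toy8 fixture."""
    return ModelSpec(terms=("c",), saturated=True, include_intercept=False)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_two_arm_frame(n1: int, n0: int, p1: float, p0: float,
                       seed: int) -> CausalFrame:
    """Unconfounded two-arm Bernoulli frame (single dummy confounder)."""
    r = np.random.default_rng(seed)
    y = np.concatenate([r.binomial(1, p1, n1), r.binomial(1, p0, n0)])
    a = np.concatenate([np.ones(n1), np.zeros(n0)])
    c = r.integers(0, 2, n1 + n0)
    return CausalFrame(y, a, pd.DataFrame({"c": c}), {"c": "categorical"})
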