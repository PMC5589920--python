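import numpy as np
import pytest

from explobatch import DesignMatrix, ExpressionMatrix, build_design


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_expression(values) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return ExpressionMatrix(
        values,
        tuple(f"s{i}" for i in range(n)),
        tuple(f"g{j}" for j in range(p)),
    )


def intercept_only(n: int) -> DesignMatrix:
    return DesignMatrix(np.ones((n, 1)), ("intercept",), {})


@pytest.fixture
def correlated_expression(rng):
    """A 20 x 5 matrix with genuine low-rank structure."""
    U = rng.standard_normal((20, 2))
    W = rng.standard_normal((2, 5)) * [[2.0], [1.0]]
    return make_expression(U @ W + 0.3 * rng.standard_normal((20, 5)))


@pytest.fixture
def two_batch_design():
    return build_design(["a"] * 10 + ["b"] * 10)
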