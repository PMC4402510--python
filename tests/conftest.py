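import numpy as np
import pytest

from genelm.datamodel import DesignSpec, ExpressionMatrix


@pytest.fixture
def two_group_design():
    """3 vs 3 treatment-means design."""
    return DesignSpec.from_groups(["A"] * 3 + ["B"] * 3)


@pytest.fixture
def ba_contrast():
    """B - A contrast for the two-group design."""
    return np.array([-1.0, 1.0])


@pytest.fixture
def small_matrix():
    rng = np.random.default_rng(123)
    vals = rng.normal(8.0, 1.0, size=(50, 6))
    return ExpressionMatrix(vals, [f"g{i}" for i in range(50)],
                            [f"s{j}" for j in range(6)])
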