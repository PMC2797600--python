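import numpy as np
import pytest

from bpeqtl.data import ExpressionMatrix, GenotypeMatrix, Hyperparameters
from bpeqtl.simulate import (
    ModuleDesign,
    model_from_decomposition,
    simulate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_dataset(rng):
    """3 genes / 2 markers / 8 individuals with one true two-locus module."""
    design = [ModuleDesign(model_from_decomposition(0.5, 0.4, 0.1), 2, (0, 1),
                           h2=0.7, name="toy")]
    return simulate_dataset(design, rng, N=8, M=2, G=3)


@pytest.fixture
def small_dataset(rng):
    """Two small modules (one strongly marginal, one epistatic) plus noise."""
    designs = [
        ModuleDesign(model_from_decomposition(0.45, 0.45, 0.10), 6, (0, 1), name="add"),
        ModuleDesign(model_from_decomposition(0.05, 0.05, 0.90), 5, (3, 4), name="xor"),
    ]
    return simulate_dataset(designs, rng, N=40, M=8, G=16)


@pytest.fixture
def toy_expr():
    values = np.array([
        [1.0, 4.0, 2.0],
        [3.0, 2.0, 5.0],
    ])
    return ExpressionMatrix(values, ["g1", "g2"], ["i1", "i2", "i3"])


@pytest.fixture
def toy_geno():
    codes = np.array([[0, 1, 1], [1, 0, 1]])
    return GenotypeMatrix(codes, ["m1", "m2"], 2)


@pytest.fixture
def default_hp():
    return Hyperparameters(D=2, max_types=3)
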