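import numpy as np
import pandas as pd
import pytest

from trophonet.containers import ExpressionMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_expression(rng):
    """30 genes x 12 cells of Poisson counts, two groups of 6."""
    genes = [f"g{i:02d}" for i in range(30)]
    cells = [f"c{i:02d}" for i in range(12)]
    values = pd.DataFrame(
        rng.poisson(5.0, size=(30, 12)).astype(float), index=genes, columns=cells
    )
    groups = pd.Series(["a"] * 6 + ["b"] * 6, index=cells)
    return ExpressionMatrix(values, groups)


@pytest.fixture
def tiny_config(tmp_path):
    """A minimal valid pipeline config on synthetic data."""
    return {
        "seed": 11,
        "deg_alpha": 0.01,
        "localization_terms": [
            "extracellular space",
            "extracellular matrix",
            "proteinaceous extracellular matrix",
            "cell surface",
        ],
        "min_expressed_fraction": 0.1,
        "sd_multiplier": 1.0,
        "n_permutations": 10,
        "rf_iterations": 10,
        "simulate": {
            "n_genes": 300,
            "n_degs": 40,
            "n_interface": 12,
            "te": {
                "n_genes": 300,
                "n_polar": 40,
                "n_mural": 50,
                "module_size": 15,
                "polar_module_n": 5,
                "mural_module_n": 8,
                "module_overlap": 3,
            },
        },
    }
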