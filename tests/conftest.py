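import numpy as np
import pandas as pd
import pytest

from seedtx import synthetic_data as sd
from seedtx.io_formats import ExpressionMatrix, SampleDesign


@pytest.fixture(scope="session")
def default_compendium():
    """The full-size development compendium with planted truth (seed 17)."""
    cfg = sd.SimulationConfig(n_genes=5000)
    matrix, design, truth = sd.simulate_compendium(cfg, seed=17)
    return cfg, matrix, design, truth


@pytest.fixture(scope="session")
def coexpression_bundle():
    """Five 50-member TF modules over a 60-array compendium (seed 17)."""
    modules = [
        {"tf": f"g{i:05d}", "n_members": 50, "go_term": f"GO:{i:07d}"}
        for i in range(1, 6)
    ]
    matrix, truth = sd.simulate_coexpression_collection(
        n_arrays=60, modules=modules, seed=17, n_genes=2000
    )
    cats = sd.category_map_from_modules(truth, matrix.gene_ids, seed=1)
    return matrix, truth, cats


@pytest.fixture
def tiny_matrix():
    df = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0], [5.0, 5.0, 5.0, 5.0], [2.0, 1.0, 4.0, 3.0]],
        index=["g1", "g2", "g3"],
        columns=["a1", "a2", "b1", "b2"],
    )
    return ExpressionMatrix(df)


@pytest.fixture
def tiny_design():
    return SampleDesign(
        pd.DataFrame(
            {
                "tissue": ["embryo", "embryo", "root", "root"],
                "stage": [3, 3, None, None],
                "replicate": [1, 2, 1, 2],
                "treatment": ["control"] * 4,
            },
            index=pd.Index(["a1", "a2", "b1", "b2"], name="sample_id"),
        )
    )


def rng(seed=17):
    return np.random.default_rng(seed)
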