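import numpy as np
import pandas as pd
import pytest

from episcreen.config import RunConfig
from episcreen.io_formats import ExpressionMatrix
from episcreen import synthetic


@pytest.fixture
def config():
    return RunConfig()


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_culture_matrix(rng, n_genes=100, zero_fraction=0.15):
    """Random FPKM matrix over the six standard cultures, with zeros."""
    values = rng.gamma(1.0, 5.0, size=(n_genes, 6))
    values[rng.random(values.shape) < zero_fraction] = 0.0
    genes = [f"g{i:05d}" for i in range(n_genes)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes,
                            columns=list(synthetic.CULTURE_SAMPLES)),
        unit_tag="FPKM", group_map=dict(synthetic.CULTURE_GROUP_MAP))


def random_tissue_matrix(rng, n_genes=100, zero_fraction=0.15):
    """Random TPM matrix over the 52 standard tissue samples, with zeros."""
    values = rng.gamma(1.0, 5.0, size=(n_genes, 52))
    values[rng.random(values.shape) < zero_fraction] = 0.0
    genes = [f"g{i:05d}" for i in range(n_genes)]
    return ExpressionMatrix(
        values=pd.DataFrame(values, index=genes,
                            columns=list(synthetic.TISSUE_SAMPLES)),
        unit_tag="TPM", group_map=dict(synthetic.TISSUE_GROUP_MAP))


@pytest.fixture
def culture_matrix(rng):
    return random_culture_matrix(rng)


@pytest.fixture
def tissue_matrix(rng):
    return random_tissue_matrix(rng)


@pytest.fixture
def small_simulation():
    """Noise-free 100-gene simulation with every planted class present."""
    class_counts = {
        "dual_specific": 5, "myob_only": 8, "cbl_only": 8, "silent": 10,
        "zero_denominator_rescue": 2, "boundary_ratio": 2,
        "culture_ESC_specific": 3,
    }
    tissue, culture, manifest = synthetic.simulate_expression(
        100, class_counts, noise_sd=0.0, rng_seed=7)
    annotation = synthetic.simulate_annotation(
        100, {"chr1": 10_000_000}, rng_seed=7,
        biotypes=["protein_coding"] * 100)
    return tissue, culture, annotation, manifest
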