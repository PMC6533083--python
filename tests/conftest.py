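import numpy as np
import pytest

from copa_regulon import ExpressionCompendium


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_compendium(rng, n_genes=50, n_samples=20, n_lineages=4,
                      zero_fraction=0.1):
    """Random non-negative compendium with a sprinkling of exact zeros."""
    values = rng.lognormal(mean=1.0, sigma=1.5, size=(n_genes, n_samples))
    values[rng.random(values.shape) < zero_fraction] = 0.0
    gene_ids = [f"G{i:03d}" for i in range(n_genes)]
    sample_ids = [f"S{j:03d}" for j in range(n_samples)]
    lineages = {s: f"L{j % n_lineages}" for j, s in enumerate(sample_ids)}
    return ExpressionCompendium(gene_ids=gene_ids, sample_ids=sample_ids,
                                values=values, lineages=lineages)


@pytest.fixture
def small_compendium():
    values = np.array([
        [1.0, 1.0, 1.0, 1.0, 64.0],
        [5.0, 5.0, 5.0, 5.0, 5.0],
        [0.0, 0.0, 0.0, 2.0, 3.0],
    ])
    return ExpressionCompendium(
        gene_ids=("A", "B", "C"),
        sample_ids=("s1", "s2", "s3", "s4", "s5"),
        values=values,
        lineages={"s1": "ovary", "s2": "ovary", "s3": "lung",
                  "s4": "lung", "s5": "ovary"},
    )
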