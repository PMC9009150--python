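"""Shared fixtures: small synthetic datasets and random matrices."""

import numpy as np
import pandas as pd
import pytest

from netscreen import ExpressionMatrix, GeneSetCollection, SynthConfig, generate


@pytest.fixture(scope="session")
def small_cfg() -> SynthConfig:
    """A scaled-down pan-cancer layout for fast structural tests."""
    return SynthConfig(
        n_fav=2,
        n_poor=2,
        n_neutral=1,
        samples_per_type=80,
        normals_per_type=10,
        n_genes=200,
        n_signature=12,
        n_planted_nrg_per_class=10,
        n_emt_per_program=6,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_cfg):
    return generate(small_cfg)


def random_expression(rng: np.random.Generator, n_genes: int, n_samples: int):
    """A random expression matrix with generic gene/sample names."""
    data = pd.DataFrame(
        rng.normal(5.0, 2.0, size=(n_genes, n_samples)),
        index=[f"G{i:03d}" for i in range(n_genes)],
        columns=[f"S{j:02d}" for j in range(n_samples)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def toy_expr(rng) -> ExpressionMatrix:
    return random_expression(rng, 20, 10)


@pytest.fixture
def toy_sets(toy_expr) -> GeneSetCollection:
    genes = toy_expr.gene_ids
    return GeneSetCollection({"A": genes[:5], "B": genes[5:12], "C": genes[::4]})
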