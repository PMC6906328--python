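import numpy as np
import pandas as pd
import pytest

import graftpath as gp


def make_expression(values: dict[tuple[str, str], list[float]], genes: list[str]) -> gp.ExpressionMatrix:
    """Build a tiny expression matrix from explicit per-sample vectors."""
    df = pd.DataFrame(
        {k: v for k, v in values.items()},
        index=pd.Index(genes, name="gene_id"),
    )
    df.columns = pd.MultiIndex.from_tuples(values.keys(), names=["subject", "timepoint"])
    return gp.ExpressionMatrix(df)


@pytest.fixture(scope="session")
def small_config() -> gp.SimulationConfig:
    return gp.SimulationConfig(
        n_genes=400,
        n_pathways=20,
        n_categories=5,
        pathway_size_range=(5, 15),
        activated_pathways=3,
        ppi_edges_per_node=3,
        rng_seed=0,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config) -> gp.SyntheticDataset:
    return gp.generate_dataset(small_config)


@pytest.fixture(scope="session")
def null_dataset() -> gp.SyntheticDataset:
    """fold = 1: DE genes listed in the manifest but no expression effect."""
    cfg = gp.SimulationConfig(
        n_genes=400,
        n_pathways=20,
        n_categories=5,
        pathway_size_range=(5, 15),
        activated_pathways=3,
        activation_fold=1.0,
        ppi_edges_per_node=3,
        rng_seed=0,
    )
    return gp.generate_dataset(cfg)
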