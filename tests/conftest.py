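"""Shared fixtures: one default synthetic panel and one full pipeline run,
computed once per session and reused across test modules."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

from receptorfunc.pipeline import PipelineConfig, run_tissue
from receptorfunc.synthetic import SyntheticConfig, generate_dataset


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic panel: 8 modules x 200 genes, 200 samples, r = 0.6."""
    return generate_dataset(SyntheticConfig(seed=7))


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    """Full single-tissue pipeline run on the default panel."""
    expr, meta, genesets, catalog, labels, truth = dataset
    metabolic = labels.index[labels["label"] == "metabolic"].tolist()
    inflammatory = labels.index[labels["label"] == "inflammatory"].tolist()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = run_tissue(
            expr, meta, genesets, catalog, metabolic, inflammatory, [],
            PipelineConfig(seed=11),
        )
    return result


@pytest.fixture(scope="session")
def truth(dataset):
    return dataset[5]


@pytest.fixture(scope="session")
def detected_to_planted(pipeline_result, truth):
    """Map detected module id -> planted module id by majority membership."""
    return {
        m: int(truth.gene_module.loc[pipeline_result.partition.members(m)].mode()[0])
        for m in pipeline_result.partition.module_ids
    }


def small_config(seed: int = 3) -> SyntheticConfig:
    """A miniature panel for fast integration tests."""
    return SyntheticConfig(
        n_samples=120,
        n_modules=3,
        genes_per_module=60,
        n_background_genes=240,
        n_pathways=9,
        n_receptors_per_class=30,
        unlabeled_fraction=0.3,
        pathway_size=20,
        n_low_expression_genes=30,
        seed=seed,
    )


def small_pipeline_config(seed: int = 5, **overrides) -> PipelineConfig:
    defaults = dict(n_folds=5, pu_k=21, pu_iterations=50, seed=seed)
    defaults.update(overrides)
    return PipelineConfig(**defaults)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
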