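"""Shared fixtures: one synthetic dataset and its preprocessed form per session."""

import numpy as np
import pytest

from agingnet import pipeline, preprocess, simulate


@pytest.fixture(scope="session")
def dataset():
    """Default synthetic aging dataset, seed 1."""
    return simulate.simulate_dataset(seed=1)


@pytest.fixture(scope="session")
def preprocessed(dataset):
    """VST expression + aligned metadata after the full QC chain."""
    cfg = pipeline.PipelineConfig(seed=1)
    pre = pipeline.preprocess_stage(dataset.counts, dataset.samples, "simulated", cfg)
    return pre


@pytest.fixture(scope="session")
def pipeline_result(dataset):
    """One full pipeline run on the default synthetic dataset."""
    cfg = pipeline.PipelineConfig(seed=1)
    return pipeline.run_tissue_pipeline(
        dataset.counts, dataset.samples, dataset.gene_sets, "simulated", cfg
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)
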