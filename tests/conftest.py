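"""Shared fixtures.

The expensive trained-model fixtures are session-scoped so the directional
(simulation-based) tests and the acceptance suite share one set of
training runs.
"""

from __future__ import annotations

import numpy as np
import pytest

from diplonet.model import LossParams, ModelConfig, build_model
from diplonet.pipeline import run_synthetic_comparison
from diplonet.synthetic import SimConfig, simulate_panel
from diplonet.training import (
    TrainConfig,
    build_training_set,
    partition_folds,
    train_ensemble,
)


@pytest.fixture(scope="session")
def tiny_panel():
    """A small panel: 12 chromosomes, 36 elements, 10 individuals."""
    return simulate_panel(SimConfig(genome_length=8000, n_chromosomes=12,
                                    n_individuals=10, n_elements=36, n_snps=900,
                                    causal_fraction=0.4, effect_window=200,
                                    maf_range=(0.2, 0.5), seed=11))


@pytest.fixture(scope="session")
def tiny_model_config():
    return ModelConfig(input_length=200, output_length=100, scale_factor=0.125,
                       tower_layers=4)


@pytest.fixture(scope="session")
def tiny_ensemble_world(tiny_panel, tiny_model_config):
    """A 9-replicate ensemble trained briefly on the tiny panel, for fold
    hygiene and compositing tests."""
    panel = tiny_panel
    chroms = list(panel.chrom_lengths)
    partition = partition_folds(panel.chrom_lengths, k=10, seed=0,
                                pinned_fold0=chroms[:2])
    dataset = build_training_set(panel, partition, tiny_model_config,
                                 jitter_max=25, seed=0)
    ensemble = train_ensemble(dataset, partition, tiny_model_config,
                              TrainConfig(max_epochs=2, patience=2, batch_size=64,
                                          learning_rate=0.005),
                              LossParams(lam=2.0), seed=0)
    return {"panel": panel, "partition": partition, "dataset": dataset,
            "ensemble": ensemble, "model_config": tiny_model_config}


@pytest.fixture(scope="session")
def desk_runs():
    """Three seeds of the full desk-scale personalized-vs-reference
    comparison (the expensive end-to-end fixture)."""
    return {seed: run_synthetic_comparison(seed=seed) for seed in (1, 2, 3)}


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
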