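"""Shared fixtures: hand-made multiset datasets and a fitted pipeline."""

from __future__ import annotations

import numpy as np
import pytest

from damacy import (
    MFCDataset,
    PipelineConfig,
    fit_pipeline,
    preset_scenarios,
    simulate_cohort,
)


def make_dataset(blocks, groups, marker_names=None, ids=None) -> MFCDataset:
    """Build an MFCDataset from a list of per-individual cell matrices."""
    blocks = [np.atleast_2d(np.asarray(b, dtype=float)) for b in blocks]
    counts = [b.shape[0] for b in blocks]
    j = blocks[0].shape[1]
    return MFCDataset(
        values=np.vstack(blocks),
        cell_to_individual=np.repeat(np.arange(len(blocks)), counts),
        individual_ids=ids or [f"ind{i}" for i in range(len(blocks))],
        group_labels=np.asarray(groups),
        marker_names=marker_names or [f"M{k + 1}" for k in range(j)],
    )


@pytest.fixture
def two_individual_dataset() -> MFCDataset:
    """Two individuals with per-marker means [0, 2] and [2, 4], unequal N."""
    rng = np.random.default_rng(7)
    a = rng.normal([0.0, 2.0], 0.5, size=(10, 2))
    b = rng.normal([2.0, 4.0], 0.5, size=(1000, 2))
    a += [0.0, 2.0] - a.mean(axis=0)  # pin the means exactly
    b += [2.0, 4.0] - b.mean(axis=0)
    return make_dataset([a, b], groups=[1, 2])


@pytest.fixture(scope="session")
def small_config() -> PipelineConfig:
    return PipelineConfig.for_small_cohorts()


@pytest.fixture(scope="session")
def lps_cohort():
    """The planted-effect preset cohort with its ground truth (seed 1)."""
    dataset, truth = simulate_cohort(preset_scenarios()["lps_like"], seed=1)
    return dataset, truth


@pytest.fixture(scope="session")
def lps_model(lps_cohort, small_config):
    dataset, _ = lps_cohort
    return fit_pipeline(dataset, small_config)
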