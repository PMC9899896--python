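"""Shared fixtures: small labeled training sets and simulated studies."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from gentox.design import build_series
from gentox.simulate import CompoundSpec, SimulationConfig
from gentox.tgxddi import DDI, NON_DDI, TrainingSet


@pytest.fixture
def small_training() -> TrainingSet:
    """6 chemicals x 4 genes, well-separated classes, fixed values."""
    rng = np.random.default_rng(42)
    genes = ["g1", "g2", "g3", "g4"]
    ddi_mean = np.array([2.0, 1.5, -2.0, -1.5])
    rows, labels = {}, {}
    for i in range(3):
        rows[f"D{i}"] = ddi_mean + rng.normal(0, 0.2, 4)
        labels[f"D{i}"] = DDI
    for i in range(3):
        rows[f"N{i}"] = rng.normal(0, 0.2, 4)
        labels[f"N{i}"] = NON_DDI
    return TrainingSet(
        matrix=pd.DataFrame(rows, index=genes).T, labels=pd.Series(labels)
    )


@pytest.fixture
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=123)


@pytest.fixture
def bmc_study_config() -> SimulationConfig:
    """A potency/design pairing that brackets the dose-response: the series
    covers both the foot and the saturating shoulder of the curve."""
    return SimulationConfig(
        seed=7,
        n_biomarker_genes=16,
        n_replicates=3,
        concentrations=build_series(1000.0, 10).concentrations,
        compounds=(
            CompoundSpec("DDI-X", is_ddi=True, moa="clastogen", potency_b=600.0),
        ),
    )


def brute_force_average_linkage(X: np.ndarray, k: int = 2) -> list[set[int]]:
    """Naive agglomerative average-linkage clustering down to k clusters.

    Average linkage distance between clusters A and B is the mean of all
    pairwise Euclidean distances; ties broken by first-found pair.
    """
    d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
    clusters: list[set[int]] = [{i} for i in range(len(X))]
    while len(clusters) > k:
        best, pair = np.inf, None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if dist < best - 1e-12:
                    best, pair = dist, (i, j)
        i, j = pair
        clusters[i] |= clusters[j]
        del clusters[j]
    return clusters
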