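"""Shared fixtures: tiny hand matrices and synthetic studies at several scales."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from phenocoex import (
    ExpressionMatrix,
    SyntheticSpec,
    classify_study,
    generate_study,
    template_design,
)
from phenocoex.scenarios import call_scenarios_table


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """4 genes x 6 samples with one all-zero gene."""
    genes = ["G1", "G2", "G3", "G0"]
    samples = [f"s{i}" for i in range(1, 7)]
    data = np.array(
        [
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [2.0, 4.1, 5.9, 8.2, 9.8, 12.1],
            [5.0, 1.0, 4.0, 2.0, 6.0, 3.0],
            [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],
        ]
    )
    return ExpressionMatrix(pd.DataFrame(data, index=genes, columns=samples))


def micro_spec(seed: int, **overrides) -> SyntheticSpec:
    """A very small planted study for fast property tests."""
    defaults = dict(
        n_background_genes=10,
        n_ds1_pairs=2,
        n_ds2_pairs=2,
        n_ds3_pairs=0,
        n_nondiff_pairs=2,
        n_na_genes=2,
        planted_cluster_sizes=(),
        hub_degree=0,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


@pytest.fixture(scope="session")
def small_study():
    """A small but structurally complete study shared across tests."""
    spec = SyntheticSpec(
        n_background_genes=30,
        n_ds1_pairs=5,
        n_ds2_pairs=5,
        n_nondiff_pairs=4,
        n_na_genes=4,
        planted_cluster_sizes=(5,),
        hub_degree=3,
        seed=101,
    )
    matrix, design, truth = generate_study(spec)
    return spec, matrix, design, truth


@pytest.fixture(scope="session")
def small_study_calls(small_study):
    spec, matrix, design, truth = small_study
    group_stats = classify_study(matrix, design, seed=5)
    calls = call_scenarios_table(group_stats, design)
    return group_stats, calls


@pytest.fixture(scope="session")
def benchmark_study():
    """The full-size planted benchmark used by the recovery criteria."""
    spec = SyntheticSpec(seed=11)
    matrix, design, truth = generate_study(spec)
    group_stats = classify_study(matrix, design, seed=12)
    calls = call_scenarios_table(group_stats, design)
    return spec, matrix, design, truth, group_stats, calls


@pytest.fixture
def paper_design():
    return template_design()
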