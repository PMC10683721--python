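"""Shared fixtures.

Two tiers: a small dataset/model for unit tests (seconds), and one
session-scoped default-scale run (30 hospitals x 700 patients, seed 0)
shared by every acceptance test that needs the full pipeline, so the
expensive SHAP interaction tensor is computed exactly once.
"""

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pytest

from thrombolysis_ml.explain import (ShapInteractionTensor, ShapMatrix,
                                     compute_interactions, compute_shap)
from thrombolysis_ml.model import (ModelConfig, ThrombolysisClassifier,
                                   fit_all_data, fit_holdout)
from thrombolysis_ml.synthetic import (GeneratorConfig, HospitalProfile,
                                       TrueDecisionModel, generate_dataset)


def small_config(seed: int = 7) -> GeneratorConfig:
    return GeneratorConfig(seed=seed, n_hospitals=6, patients_per_hospital=150)


@pytest.fixture(scope="session")
def small_data():
    table, hospitals, truth = generate_dataset(small_config())
    return table, hospitals, truth


@pytest.fixture(scope="session")
def small_model(small_data) -> ThrombolysisClassifier:
    table, _, _ = small_data
    return fit_all_data(table, ModelConfig(seed=7))


@pytest.fixture(scope="session")
def small_shap(small_model, small_data) -> ShapMatrix:
    table, _, _ = small_data
    return compute_shap(small_model, table)


@pytest.fixture(scope="session")
def small_slice(small_data) -> pd.DataFrame:
    """A 200-row strided slice of the small table covering every hospital."""
    table, _, _ = small_data
    idx = np.linspace(0, len(table) - 1, 200).astype(int)
    return table.iloc[idx]


@pytest.fixture(scope="session")
def small_tensor(small_model, small_slice) -> ShapInteractionTensor:
    # tensor on a slice: enough rows for the structural checks, cheap
    return compute_interactions(small_model, small_slice)


@dataclass
class DefaultRun:
    """One default-scale pipeline run shared across acceptance tests."""

    table: pd.DataFrame
    hospitals: list[HospitalProfile]
    truth: TrueDecisionModel
    model: ThrombolysisClassifier          # all-data fit
    shap: ShapMatrix
    tensor: ShapInteractionTensor
    hold_model: ThrombolysisClassifier = None
    cohort: pd.DataFrame = None
    _extras: dict = field(default_factory=dict)


@pytest.fixture(scope="session")
def default_run() -> DefaultRun:
    cfg = GeneratorConfig(seed=0)  # 30 x 700
    table, hospitals, truth = generate_dataset(cfg)
    model = fit_all_data(table, ModelConfig(seed=0))
    shap = compute_shap(model, table)
    tensor = compute_interactions(model, table)
    hold_model, cohort = fit_holdout(
        table, ModelConfig(variant="holdout10k", holdout_size=5000, seed=0))
    return DefaultRun(table=table, hospitals=hospitals, truth=truth,
                      model=model, shap=shap, tensor=tensor,
                      hold_model=hold_model, cohort=cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(123)
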