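"""Unit tests for the SHAP decomposition module."""

import math

import numpy as np
import pandas as pd
import pytest
import xgboost as xgb
from scipy.special import expit

from thrombolysis_ml import explain
from thrombolysis_ml.model import fit_all_data, ModelConfig


# -- closed-form single-stump oracle --------------------------------------

def _stump_booster(a: float, b: float, threshold: float = 0.5):
    """One depth-1 tree splitting feature 0 at ``threshold``; leaves a, b.

    Trained to convergence on two-point data so the leaf values are known
    analytically is fiddly; instead build the tree through training on a
    deterministic dataset and read the achieved leaves back.
    """
    X = np.array([[0.0], [1.0]])
    y = np.array([a, b])
    dm = xgb.DMatrix(X, label=y)
    booster = xgb.train({"objective": "reg:squarederror", "max_depth": 1,
                         "eta": 1.0, "lambda": 0.0, "base_score": 0.0},
                        dm, num_boost_round=1)
    return booster


def test_stump_shap_closed_form():
    # single binary split, equal cover: phi = (1 - p)(leaf_own - leaf_other)
    # with p = weight share of the row's own leaf (here 1/2)
    booster = _stump_booster(-1.0, 2.0)
    dm = xgb.DMatrix(np.array([[0.0], [1.0]]))
    contribs = booster.predict(dm, pred_contribs=True)
    # base = mean leaf = 0.5; phi(x=0) = -1 - 0.5; phi(x=1) = 2 - 0.5
    assert contribs[0, -1] == pytest.approx(0.5, abs=1e-6)
    assert contribs[0, 0] == pytest.approx(-1.5, abs=1e-6)
    assert contribs[1, 0] == pytest.approx(1.5, abs=1e-6)


def test_depth_one_model_has_no_interactions(small_data):
    table, _, _ = small_data
    clf = fit_all_data(table, ModelConfig(max_depth=1, n_rounds=20, seed=3))
    tensor = explain.compute_interactions(clf, table.head(50))
    off_diag = tensor.values.copy()
    for i in range(off_diag.shape[1]):
        off_diag[:, i, i] = 0.0
    assert np.abs(off_diag).max() < 1e-5


# -- structural invariants on the fitted model -----------------------------

def test_additivity(small_shap):
    assert small_shap.additivity_error() < 1e-4


def test_tensor_symmetry_and_row_sums(small_tensor, small_shap, small_slice):
    assert small_tensor.symmetry_error() < 1e-4
    total = small_tensor.total_shap()
    # the tensor was computed on the strided slice: compare the same rows
    ref = small_shap.values.loc[small_slice.index].reset_index(drop=True)
    assert np.abs(total[ref.columns].to_numpy() - ref.to_numpy()).max() < 1e-4


def test_team_block_aggregated(small_shap, small_tensor):
    assert "stroke_team" in small_shap.values.columns
    assert not any(c.startswith("team_") for c in small_shap.values.columns)
    assert "stroke_team" in small_tensor.feature_names


def test_main_effect_unknown_feature_raises(small_tensor):
    with pytest.raises(KeyError):
        small_tensor.main_effect("bogus")


# -- subset SHAP -----------------------------------------------------------

def test_subset_all_in_one_recovers_total(small_tensor):
    partition = {f: "all" for f in small_tensor.feature_names}
    attr = explain.subset_shap(small_tensor, partition)
    total = small_tensor.total_shap()
    assert np.abs(attr.values.to_numpy() - total.to_numpy()).max() < 1e-9
    assert np.abs(attr.cross_subset_mass).max() < 1e-9


def test_subset_singletons_recover_main_effects(small_tensor):
    partition = {f: f for f in small_tensor.feature_names}
    attr = explain.subset_shap(small_tensor, partition)
    for f in small_tensor.feature_names:
        np.testing.assert_allclose(attr.values[f].to_numpy(),
                                   small_tensor.main_effect(f), atol=1e-9)


def test_subset_conservation(small_tensor):
    # subset sums plus excluded cross-subset mass = total SHAP sum
    partition = {f: ("hospital" if f in ("stroke_team", "arrival_to_scan_min")
                     else "patient") for f in small_tensor.feature_names}
    attr = explain.subset_shap(small_tensor, partition)
    lhs = attr.values.sum(axis=1).to_numpy() + attr.cross_subset_mass
    rhs = small_tensor.total_shap().sum(axis=1).to_numpy()
    np.testing.assert_allclose(lhs, rhs, atol=1e-9)
    assert set(np.unique(list(attr.subsets.values()))) == {"hospital",
                                                           "patient"}


def test_subset_missing_feature_raises(small_tensor):
    with pytest.raises(KeyError):
        explain.subset_shap(small_tensor, {"nihss": "patient"})
    attr = explain.subset_shap(
        small_tensor, {f: "all" for f in small_tensor.feature_names})
    with pytest.raises(KeyError):
        attr.subset_sum("nope")


# -- waterfall --------------------------------------------------------------

def test_waterfall_contracts(small_shap):
    row = small_shap.values.iloc[0]
    wf = explain.waterfall(row, small_shap.base_value)
    assert list(wf.columns) == ["feature", "contribution",
                                "cumulative_log_odds",
                                "cumulative_probability"]
    # ordered by decreasing |contribution|
    mags = wf["contribution"].abs().to_numpy()
    assert (np.diff(mags) <= 1e-12).all()
    # final probability equals logistic(base + sum) exactly
    expected = expit(small_shap.base_value + row.sum())
    assert wf["cumulative_probability"].iloc[-1] == pytest.approx(
        expected, abs=1e-12)
    assert ((0 <= wf["cumulative_probability"])
            & (wf["cumulative_probability"] <= 1)).all()


# -- binned summaries --------------------------------------------------------

def test_binned_summary_binary_feature(small_data, small_shap):
    table, _, _ = small_data
    s = explain.shap_vs_value_summary(table, small_shap, "onset_during_sleep")
    assert set(s.table["bin"]) == {0, 1}
    assert s.table["n"].sum() == len(table)
    # sleep onset lowers the odds: median SHAP lower for 1 than 0
    assert s.median(1) < s.median(0)
    assert s.fold_change(0, 1) == pytest.approx(
        math.exp(s.median(0) - s.median(1)))


def test_binned_summary_continuous_bins(small_data, small_shap):
    table, _, _ = small_data
    bins = [0, 30, 60, 120, 360]
    s = explain.shap_vs_value_summary(table, small_shap,
                                      "arrival_to_scan_min", bins)
    assert s.table["n"].sum() == len(table)  # half-open bins partition
    assert (s.table["q1"] <= s.table["median"]).all()
    assert (s.table["median"] <= s.table["q3"]).all()


def test_binned_summary_empty_bin_warns(small_data, small_shap):
    table, _, _ = small_data
    with pytest.warns(UserWarning, match="empty bin"):
        s = explain.shap_vs_value_summary(
            table, small_shap, "nihss", [0, 43, 100, 200])
    assert len(s.table) == 1  # only [0, 43) is populated


def test_binned_summary_unknown_feature(small_data, small_shap):
    table, _, _ = small_data
    with pytest.raises(KeyError):
        explain.shap_vs_value_summary(table, small_shap, "bogus")
    s = explain.shap_vs_value_summary(table, small_shap, "nihss")
    with pytest.raises(KeyError):
        s.median("no-such-bin")


def test_endpoint_fold_change_linear_trend():
    # synthetic summary with an exactly linear trend: endpoint estimate
    # must recover exp(slope * span) regardless of bin placement
    t = pd.DataFrame({
        "bin": ["a", "b", "c"],
        "midpoint": [10.0, 60.0, 110.0],
        "n": [100, 100, 100],
        "median": [-0.01 * 10, -0.01 * 60, -0.01 * 110],
        "q1": 0.0, "q3": 0.0,
    })
    s = explain.BinnedShapSummary(feature="x", table=t)
    assert s.endpoint_fold_change(0.0, 120.0) == pytest.approx(
        math.exp(0.01 * 120.0))
    with pytest.raises(ValueError):
        s.endpoint_fold_change(0.0, 5.0)  # fewer than 2 bins inside
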