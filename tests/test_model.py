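"""Unit tests for the model-training module."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from thrombolysis_ml import model as mdl
from thrombolysis_ml.synthetic import LABEL_COLUMN


# -- encoder -------------------------------------------------------------

def test_encoder_round_trip(small_data):
    table, _, _ = small_data
    enc = mdl.HospitalOneHotEncoder().fit(table)
    X = enc.transform(table)
    block = X[enc.team_columns()].to_numpy()
    assert (block.sum(axis=1) == 1).all()          # exactly one hot
    assert set(np.unique(block)) == {0.0, 1.0}
    back = enc.inverse_transform(X)
    orig = table.drop(columns=LABEL_COLUMN).reset_index(drop=True)
    pd.testing.assert_frame_equal(back[orig.columns], orig, check_dtype=False)


def test_encoder_unseen_team_raises(small_data):
    table, _, _ = small_data
    enc = mdl.HospitalOneHotEncoder().fit(table)
    bad = table.head(3).copy()
    bad["stroke_team"] = "UNSEEN"
    with pytest.raises(ValueError, match="UNSEEN"):
        enc.transform(bad)


def test_encoder_reassign(small_data):
    table, _, _ = small_data
    enc = mdl.HospitalOneHotEncoder().fit(table)
    X = enc.transform(table.head(20))
    team = enc.teams_[2]
    moved = enc.reassign(X, team)
    assert (moved[mdl.TEAM_PREFIX + team] == 1.0).all()
    others = [c for c in enc.team_columns() if c != mdl.TEAM_PREFIX + team]
    assert (moved[others].to_numpy() == 0.0).all()
    # numeric block untouched
    pd.testing.assert_frame_equal(moved[enc.numeric_columns_],
                                  X[enc.numeric_columns_])
    with pytest.raises(ValueError):
        enc.reassign(X, "UNSEEN")


# -- classifier ----------------------------------------------------------

def test_margin_proba_consistency(small_model, small_data):
    table, _, _ = small_data
    m = small_model.predict_margin(table.head(100))
    p = small_model.predict_proba(table.head(100))[:, 1]
    np.testing.assert_allclose(p, expit(m), atol=1e-6)
    assert (small_model.predict(table.head(100))
            == (p >= 0.5).astype(int)).all()


def test_classifier_rejects_bad_labels(small_data):
    table, _, _ = small_data
    with pytest.raises(ValueError):
        mdl.ThrombolysisClassifier().fit(
            table.drop(columns=LABEL_COLUMN), np.full(len(table), 2))
    with pytest.raises(ValueError):
        mdl.ThrombolysisClassifier().fit(table.drop(columns=LABEL_COLUMN))


def test_classifier_is_deterministic(small_data):
    table, _, _ = small_data
    a = mdl.fit_all_data(table, mdl.ModelConfig(seed=5))
    b = mdl.fit_all_data(table, mdl.ModelConfig(seed=5))
    assert a.booster_.save_raw() == b.booster_.save_raw()


def test_config_validation():
    with pytest.raises(ValueError):
        mdl.ModelConfig(n_folds=1).validate()
    with pytest.raises(ValueError):
        mdl.ModelConfig(variant="bogus").validate()


# -- k-fold --------------------------------------------------------------

@pytest.fixture(scope="module")
def kfold_run(small_data):
    table, _, _ = small_data
    return mdl.fit_kfold(table, mdl.ModelConfig(variant="kfold", n_folds=5,
                                                seed=7, n_rounds=30))


def test_kfold_oof_coverage(kfold_run, small_data):
    table, _, _ = small_data
    models, report, oof = kfold_run
    assert len(models) == 5
    assert len(oof) == len(table)
    assert np.isfinite(oof).all()
    assert ((0 <= oof) & (oof <= 1)).all()


def test_kfold_metrics_sane(kfold_run):
    _, report, _ = kfold_run
    assert 0.5 < report.roc_auc <= 1.0
    assert 0.5 < report.accuracy <= 1.0
    assert 0.0 <= report.balanced_value <= 1.0
    assert report.hospital_mae_percent >= 0.0


def test_anti_leakage_label_never_a_feature(small_data):
    # the label column is stripped before encoding: a classifier fit on a
    # table whose label column is shuffled relative to y must not see it
    table, _, _ = small_data
    y = table[LABEL_COLUMN].to_numpy()
    shuffled = table.copy()
    shuffled[LABEL_COLUMN] = np.random.default_rng(0).permutation(y)
    a = mdl.ThrombolysisClassifier(seed=1, n_rounds=20).fit(table, y)
    b = mdl.ThrombolysisClassifier(seed=1, n_rounds=20).fit(shuffled, y)
    assert a.booster_.save_raw() == b.booster_.save_raw()
    assert LABEL_COLUMN not in a.feature_names_


def test_kfold_requires_both_classes(small_data):
    table, _, _ = small_data
    bad = table.copy()
    bad[LABEL_COLUMN] = 1
    with pytest.raises(ValueError):
        mdl.fit_kfold(bad)


# -- holdout -------------------------------------------------------------

def test_holdout_partition(small_data):
    table, _, _ = small_data
    clf, cohort = mdl.fit_holdout(
        table, mdl.ModelConfig(variant="holdout10k", holdout_size=200, seed=7))
    assert len(cohort) == 200
    assert len(np.intersect1d(cohort.index, clf.train_index_)) == 0
    assert len(cohort) + len(clf.train_index_) == len(table)
    # encoder knows every team, even cohort-only ones
    assert set(clf.encoder_.teams_) == set(table["stroke_team"].unique())


def test_holdout_too_large(small_data):
    table, _, _ = small_data
    with pytest.raises(ValueError):
        mdl.fit_holdout(table, mdl.ModelConfig(variant="holdout10k",
                                               holdout_size=len(table)))


# -- threshold metrics ---------------------------------------------------

def test_equal_sens_spec_perfect_scores():
    y = np.array([0, 0, 0, 1, 1, 1])
    s = np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9])
    _, value = mdl.equal_sens_spec_point(s, y)
    assert value == pytest.approx(1.0)


def test_equal_sens_spec_flipped_scores():
    y = np.array([0, 0, 0, 1, 1, 1])
    s = np.array([0.9, 0.8, 0.7, 0.3, 0.2, 0.1])
    _, value = mdl.equal_sens_spec_point(s, y)
    assert value == pytest.approx(0.0, abs=1e-9)


def test_equal_sens_spec_random_scores_near_half(rng):
    y = rng.integers(0, 2, size=20_000)
    s = rng.random(20_000)
    _, value = mdl.equal_sens_spec_point(s, y)
    assert value == pytest.approx(0.5, abs=0.02)


def test_equal_sens_spec_single_class_raises():
    with pytest.raises(ValueError):
        mdl.equal_sens_spec_point(np.array([0.1, 0.9]), np.array([1, 1]))


# -- hospital-level agreement --------------------------------------------

def test_hospital_agreement_perfect(small_data):
    table, _, _ = small_data
    # predicted probability == label -> per-hospital means agree exactly
    probs = table[LABEL_COLUMN].to_numpy().astype(float)
    r2, mae = mdl.hospital_level_agreement(probs, table)
    assert r2 == pytest.approx(1.0)
    assert mae == pytest.approx(0.0, abs=1e-12)


def test_hospital_agreement_constant_prediction(small_data):
    table, _, _ = small_data
    rate = table[LABEL_COLUMN].mean()
    probs = np.full(len(table), rate)
    _, mae = mdl.hospital_level_agreement(probs, table)
    # MAE equals the mean absolute deviation of hospital rates, in points
    per_hosp = table.groupby("stroke_team")[LABEL_COLUMN].mean()
    assert mae == pytest.approx(float((per_hosp - rate).abs().mean()) * 100)
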