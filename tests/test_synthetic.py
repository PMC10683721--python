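"""Unit tests for the synthetic registry generator."""

import math

import numpy as np
import pandas as pd
import pytest

from thrombolysis_ml import synthetic as syn


def cfg(**kw):
    base = dict(seed=3, n_hospitals=5, patients_per_hospital=100)
    base.update(kw)
    return syn.GeneratorConfig(**base)


# -- hospitals ---------------------------------------------------------------

def test_offset_span_is_exact():
    hospitals = syn.sample_hospitals(cfg())
    offsets = np.array([h.true_offset for h in hospitals])
    assert math.isclose(math.exp(offsets.max() - offsets.min()), 13.0,
                        rel_tol=1e-12)
    assert abs(offsets.mean()) < 1e-12


def test_offset_span_follows_config():
    hospitals = syn.sample_hospitals(cfg(hospital_offset_span_fold=4.0))
    offsets = np.array([h.true_offset for h in hospitals])
    assert math.isclose(math.exp(offsets.max() - offsets.min()), 4.0,
                        rel_tol=1e-12)


def test_single_hospital_offset_zero():
    hospitals = syn.sample_hospitals(cfg(n_hospitals=1))
    assert len(hospitals) == 1
    assert hospitals[0].true_offset == 0.0


def test_null_span_gives_zero_offsets():
    hospitals = syn.sample_hospitals(cfg(hospital_offset_span_fold=1.0))
    assert all(h.true_offset == 0.0 for h in hospitals)


def test_process_coupling_direction():
    # strongly coupled: higher offset -> faster scan-to-needle
    hospitals = syn.sample_hospitals(cfg(n_hospitals=30, process_coupling=30.0,
                                         scan_to_needle_sd=0.0))
    off = np.array([h.true_offset for h in hospitals])
    stn = np.array([h.median_scan_to_needle_min for h in hospitals])
    assert np.corrcoef(off, stn)[0, 1] < -0.95


# -- patients ----------------------------------------------------------------

def test_patient_table_schema_and_domains():
    c = cfg(n_hospitals=8, patients_per_hospital=250)
    table, _, _ = syn.generate_dataset(c)
    syn.validate_table(table)
    assert list(table.columns) == syn.FEATURE_COLUMNS + [syn.LABEL_COLUMN]
    assert len(table) == 8 * 250
    assert (table["onset_to_arrival_min"] <= 240).all()
    assert (table["onset_to_arrival_min"] > 0).all()
    assert table["nihss"].between(0, 42).all()
    assert table["age_midpoint"].isin(syn.AGE_MIDPOINTS).all()


def test_determinism():
    a, _, _ = syn.generate_dataset(cfg())
    b, _, _ = syn.generate_dataset(cfg())
    pd.testing.assert_frame_equal(a, b)


def test_different_seeds_differ():
    a, _, _ = syn.generate_dataset(cfg(seed=1))
    b, _, _ = syn.generate_dataset(cfg(seed=2))
    assert not a.equals(b)


def test_haemorrhage_fraction_matches_config():
    c = cfg(n_hospitals=10, patients_per_hospital=2000)  # 20,000 rows
    table, _, _ = syn.generate_dataset(c)
    frac = 1.0 - table["infarction"].mean()
    se = math.sqrt(0.15 * 0.85 / len(table))
    assert abs(frac - 0.15) < 2 * se


def test_haemorrhage_never_thrombolysed():
    table, _, _ = syn.generate_dataset(cfg(n_hospitals=10,
                                           patients_per_hospital=500))
    assert (table.loc[table["infarction"] == 0, syn.LABEL_COLUMN] == 0).all()


def test_all_haemorrhage_table_all_zero_labels(small_data):
    table, _, truth = small_data
    t = table.drop(columns=syn.LABEL_COLUMN).copy()
    t["infarction"] = 0
    labelled = syn.assign_labels(t, truth, seed=0)
    assert (labelled[syn.LABEL_COLUMN] == 0).all()


def test_decoy_columns():
    table, _, _ = syn.generate_dataset(cfg(decoy_feature_count=3))
    assert [c for c in table.columns if c.startswith("decoy_")] == \
        ["decoy_00", "decoy_01", "decoy_02"]
    # decoys are independent noise: adding them must not change the rest
    base, _, _ = syn.generate_dataset(cfg())
    pd.testing.assert_frame_equal(table[base.columns], base)


def test_empty_patient_table():
    c = cfg()
    hospitals = syn.sample_hospitals(c)
    t = syn.sample_patients(c, hospitals, n_patients=0)
    assert len(t) == 0
    assert list(t.columns) == syn.FEATURE_COLUMNS


def test_every_hospital_receives_patients():
    table, hospitals, _ = syn.generate_dataset(cfg())
    assert set(table["stroke_team"]) == {h.team_id for h in hospitals}


# -- true decision model -----------------------------------------------------

def test_effect_shapes_at_breakpoints(small_data):
    _, _, truth = small_data
    # arrival-to-scan: ln(9) drop over 0 -> 120 min, flatter tail beyond
    assert truth.f_arrival_to_scan(0.0) == 0.0
    assert math.isclose(float(truth.f_arrival_to_scan(120.0)), -math.log(9))
    tail = float(truth.f_arrival_to_scan(240.0) - truth.f_arrival_to_scan(120.0))
    assert math.isclose(tail, -0.25 * math.log(9))
    # NIHSS: ln(30) rise to the 15-25 plateau, ln(5) fall to 42
    assert math.isclose(float(truth.f_nihss(0)), -math.log(30))
    assert float(truth.f_nihss(15)) == 0.0 == float(truth.f_nihss(25))
    assert math.isclose(float(truth.f_nihss(42)), -math.log(5))
    # age: flat below 80
    assert float(truth.f_age(77.5)) == 0.0
    assert float(truth.f_age(80.0)) == 0.0
    assert math.isclose(float(truth.f_age(92.5)),
                        -math.log(2) * 12.5 / 30.0)
    # binary flags
    assert math.isclose(float(truth.f_sleep(1)), -math.log(4))
    assert float(truth.f_sleep(0)) == 0.0


def test_true_log_odds_rejects_haemorrhage(small_data):
    table, _, truth = small_data
    with pytest.raises(ValueError):
        syn.true_log_odds(table.drop(columns=syn.LABEL_COLUMN), truth)


def test_true_log_odds_unknown_team(small_data):
    table, _, truth = small_data
    t = table[table["infarction"] == 1].drop(columns=syn.LABEL_COLUMN).copy()
    t.iloc[0, t.columns.get_loc("stroke_team")] = "NOWHERE"
    with pytest.raises(KeyError):
        syn.true_log_odds(t, truth)


def test_label_rate_consistent_with_true_probability(small_data):
    # Monte-Carlo: observed label mean within 3 s.e. of mean true probability
    table, _, truth = small_data
    infarct = table[table["infarction"] == 1]
    lo = syn.true_log_odds(infarct.drop(columns=syn.LABEL_COLUMN), truth)
    p = 1.0 / (1.0 + np.exp(-lo))
    se = math.sqrt(float((p * (1 - p)).sum())) / len(p)
    assert abs(infarct[syn.LABEL_COLUMN].mean() - p.mean()) < 3 * se


# -- schema validation -------------------------------------------------------

def test_schema_error_names_missing_column(small_data):
    table, _, _ = small_data
    with pytest.raises(syn.SchemaError, match="nihss"):
        syn.validate_table(table.drop(columns="nihss"))


def test_schema_error_names_out_of_domain_column(small_data):
    table, _, _ = small_data
    bad = table.copy()
    bad.loc[bad.index[0], "onset_to_arrival_min"] = 500.0
    with pytest.raises(syn.SchemaError, match="onset_to_arrival_min"):
        syn.validate_table(bad)


def test_schema_error_unknown_column(small_data):
    table, _, _ = small_data
    with pytest.raises(syn.SchemaError, match="mystery"):
        syn.validate_table(table.assign(mystery=1))


def test_schema_error_age_off_grid(small_data):
    table, _, _ = small_data
    bad = table.copy()
    bad.loc[bad.index[0], "age_midpoint"] = 70.0  # not a band midpoint
    with pytest.raises(syn.SchemaError, match="age_midpoint"):
        syn.validate_table(bad)


# -- persistence -------------------------------------------------------------

def test_write_read_round_trip(tmp_path, small_data):
    table, hospitals, truth = small_data
    path = tmp_path / "data.csv"
    syn.write_dataset(table, path, hospitals, truth)
    back = syn.read_dataset(path)
    pd.testing.assert_frame_equal(
        back, table.reset_index(drop=True), check_dtype=False,
        check_exact=False, rtol=1e-12)
    hosp2, truth2 = syn.read_truth(path)
    assert {h.team_id: h.true_offset for h in hosp2} == truth.offsets
    assert truth2.intercept == truth.intercept


def test_config_validation_errors():
    with pytest.raises(ValueError):
        cfg(n_hospitals=0).validate()
    with pytest.raises(ValueError):
        cfg(hospital_offset_span_fold=0.0).validate()
    with pytest.raises(ValueError):
        syn.EffectParams(sleep_fold=-1.0).validate()
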