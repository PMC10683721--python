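"""Hospital propensity to thrombolyse: SHAP main effects and counterfactuals.

Two complementary views of how the hospital attended, rather than the
patients it receives, drives thrombolysis use: (1) the mean SHAP main
effect of the hospital-attended pseudo-feature among a hospital's own
patients, compared with its observed rate; (2) a counterfactual analysis
that sends one fixed held-out cohort to every hospital in turn (by
rewriting the one-hot hospital encoding) and records the predicted rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats

from .explain import ShapInteractionTensor, compute_interactions
from .model import ThrombolysisClassifier
from .synthetic import LABEL_COLUMN, HospitalProfile

__all__ = [
    "HospitalEffectTable",
    "CounterfactualResult",
    "mean_hospital_main_effect",
    "counterfactual_cohort",
    "process_correlates",
]


@dataclass
class HospitalEffectTable:
    """Per-hospital mean SHAP main effect and observed thrombolysis rate."""

    table: pd.DataFrame  # index: team id; columns: mean_main_effect,
    #                      observed_rate, n [+ descriptors]

    def with_descriptors(self, hospitals: list[HospitalProfile]
                         ) -> "HospitalEffectTable":
        desc = pd.DataFrame({
            "admissions_per_year": {h.team_id: h.admissions_per_year
                                    for h in hospitals},
            "median_scan_to_needle_min": {h.team_id: h.median_scan_to_needle_min
                                          for h in hospitals},
        })
        return HospitalEffectTable(self.table.join(desc, how="left"))


@dataclass
class CounterfactualResult:
    """Predicted thrombolysis rate for one fixed cohort at every hospital."""

    cohort_id: str
    table: pd.DataFrame  # index: team id; columns: predicted_rate,
    #                      mean_main_effect (on counterfactual rows)


def mean_hospital_main_effect(tensor: ShapInteractionTensor,
                              table: pd.DataFrame) -> HospitalEffectTable:
    """Average the hospital-attended SHAP main effect per hospital.

    Groups patients by the hospital they attended and averages the
    diagonal entry of the aggregated "stroke_team" pseudo-feature. When
    the model was trained without the hospital feature all means are 0.
    """
    if len(table) != tensor.values.shape[0]:
        raise ValueError("tensor is not aligned to the table rows")
    if "stroke_team" in tensor.feature_names:
        main = tensor.main_effect("stroke_team")
    else:
        main = np.zeros(len(table))
    df = pd.DataFrame({
        "team": table["stroke_team"].to_numpy(),
        "main": main,
        "label": table[LABEL_COLUMN].to_numpy()
        if LABEL_COLUMN in table.columns else np.nan,
    })
    grouped = df.groupby("team").agg(
        mean_main_effect=("main", "mean"),
        observed_rate=("label", "mean"),
        n=("main", "size"),
    )
    grouped.index.name = "team_id"
    return HospitalEffectTable(grouped)


def counterfactual_cohort(model: ThrombolysisClassifier,
                          cohort: pd.DataFrame,
                          hospitals: list[str] | None = None,
                          cohort_id: str = "holdout",
                          with_main_effects: bool = True,
                          main_effect_rows: int = 300,
                          seed: int = 0) -> CounterfactualResult:
    """Predicted thrombolysis rate for the identical cohort at each hospital.

    Every cohort row is reassigned to each hospital in turn (all columns
    other than the team indicators stay byte-identical) and the mean
    predicted probability is recorded. Raises if cohort rows overlap the
    model's training rows (leakage guard; compared on the row index).

    When ``with_main_effects`` (and the model uses the hospital feature),
    also records the mean hospital SHAP main effect on the counterfactual
    rows per hospital. Because the interaction tensor is the expensive
    part of the pipeline, the main-effect mean is taken over a fixed
    random subsample of ``main_effect_rows`` cohort rows (the same rows
    at every hospital); set it >= len(cohort) to use the full cohort.
    """
    if hasattr(model, "train_index_"):
        overlap = np.intersect1d(np.asarray(cohort.index),
                                 model.train_index_)
        if len(overlap):
            raise ValueError(
                f"cohort overlaps {len(overlap)} training rows (leakage)")
    if hospitals is None:
        hospitals = model.encoder_.teams_
    X = model.encoded(cohort)
    if with_main_effects and model.use_hospital:
        k = min(main_effect_rows, len(cohort))
        sub_idx = np.random.default_rng(seed).choice(
            len(cohort), size=k, replace=False)
        sub = cohort.iloc[np.sort(sub_idx)]
    rows = []
    for team in hospitals:
        if model.use_hospital:
            Xh = model.encoder_.reassign(
                model.encoder_.transform(cohort), team)
            Xh = Xh[model.feature_names_]
        else:
            Xh = X
        dm = xgb.DMatrix(Xh, feature_names=model.feature_names_)
        p = model.booster_.predict(dm)
        entry = {"team_id": team, "predicted_rate": float(p.mean())}
        if with_main_effects and model.use_hospital:
            cf = sub.copy()
            cf["stroke_team"] = team
            tensor = compute_interactions(model, cf)
            entry["mean_main_effect"] = float(
                tensor.main_effect("stroke_team").mean())
        rows.append(entry)
    table = pd.DataFrame(rows).set_index("team_id")
    return CounterfactualResult(cohort_id=cohort_id, table=table)


def process_correlates(effects: HospitalEffectTable,
                       descriptors: list[str] | None = None) -> pd.DataFrame:
    """Correlate hospital process descriptors with the mean SHAP main effect.

    Ordinary least squares per descriptor; reports slope, r-squared
    (squared Pearson correlation) and the two-sided p-value of the
    correlation test, unadjusted. Constant descriptors are skipped with a
    warning.
    """
    df = effects.table
    if descriptors is None:
        descriptors = [c for c in df.columns
                       if c not in ("mean_main_effect", "observed_rate", "n")]
    rows = []
    for d in descriptors:
        x = df[d].to_numpy(dtype=float)
        y = df["mean_main_effect"].to_numpy(dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 3 or np.std(x[ok]) == 0:
            warnings.warn(f"descriptor skipped (constant or too few): {d}",
                          stacklevel=2)
            continue
        res = stats.linregress(x[ok], y[ok])
        rows.append({"descriptor": d, "slope": res.slope,
                     "r2": res.rvalue ** 2, "p_value": res.pvalue,
                     "n": int(ok.sum())})
    return pd.DataFrame(rows)
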