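"""Observed and counterfactually predicted thrombolysis rates for patient
subgroups.

Eleven subgroups: one "ideally" thrombolysable profile, nine subgroups
each defined by a single sub-optimal feature, and one combining two
sub-optimal features (low severity with estimated onset time). Interval
conventions: time windows like 60-90 min are half-open [60, 90); the
NIHSS 10-25 range is inclusive; "age 80+" means an age-band midpoint of
80 or above.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd
import xgboost as xgb

from .model import ThrombolysisClassifier
from .synthetic import LABEL_COLUMN

__all__ = [
    "SubgroupDefinition",
    "builtin_subgroups",
    "observed_subgroup_rates",
    "predicted_subgroup_rates",
    "summarize_matrix",
]


@dataclass
class SubgroupDefinition:
    """A named predicate over patient-table rows (vectorised)."""

    name: str
    predicate: Callable[[pd.DataFrame], np.ndarray]

    def mask(self, table: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.predicate(table), dtype=bool)


def builtin_subgroups() -> list[SubgroupDefinition]:
    """The 11 standard subgroups, ideal profile first."""

    def ideal(t):
        return ((t["infarction"] == 1)
                & (t["arrival_to_scan_min"] < 30)
                & (t["nihss"] >= 10) & (t["nihss"] <= 25)
                & (t["precise_onset"] == 1)
                & (t["prior_mrs"] == 0)
                & (t["anticoagulant"] == 0)
                & (t["onset_to_arrival_min"] < 90)
                & (t["age_midpoint"] < 80)
                & (t["onset_during_sleep"] == 0))

    return [
        SubgroupDefinition("ideal", ideal),
        SubgroupDefinition("haemorrhagic stroke",
                           lambda t: t["infarction"] == 0),
        SubgroupDefinition("arrival-to-scan 60-90 min",
                           lambda t: (t["arrival_to_scan_min"] >= 60)
                           & (t["arrival_to_scan_min"] < 90)),
        SubgroupDefinition("NIHSS <5", lambda t: t["nihss"] < 5),
        SubgroupDefinition("estimated onset time",
                           lambda t: t["precise_onset"] == 0),
        SubgroupDefinition("pre-stroke disability (mRS >2)",
                           lambda t: t["prior_mrs"] > 2),
        SubgroupDefinition("on AF anticoagulants",
                           lambda t: t["anticoagulant"] == 1),
        SubgroupDefinition("onset-to-arrival 150-180 min",
                           lambda t: (t["onset_to_arrival_min"] >= 150)
                           & (t["onset_to_arrival_min"] < 180)),
        SubgroupDefinition("age 80+",
                           lambda t: t["age_midpoint"] >= 80),
        SubgroupDefinition("onset during sleep",
                           lambda t: t["onset_during_sleep"] == 1),
        SubgroupDefinition("NIHSS <5 and estimated onset",
                           lambda t: (t["nihss"] < 5)
                           & (t["precise_onset"] == 0)),
    ]


def observed_subgroup_rates(table: pd.DataFrame,
                            subgroups: list[SubgroupDefinition] | None = None,
                            min_count: int = 5) -> pd.DataFrame:
    """Observed thrombolysis rate per hospital and subgroup.

    Tidy frame (team_id, subgroup, n, rate); rate is NaN when the cell
    has fewer than ``min_count`` patients (count still reported).
    """
    subgroups = subgroups or builtin_subgroups()
    teams = table["stroke_team"].to_numpy()
    labels = table[LABEL_COLUMN].to_numpy()
    rows = []
    for sg in subgroups:
        mask = sg.mask(table)
        df = pd.DataFrame({"team": teams[mask], "label": labels[mask]})
        counts = df.groupby("team")["label"].agg(["size", "mean"])
        for team in np.unique(teams):
            if team in counts.index:
                n = int(counts.loc[team, "size"])
                rate = float(counts.loc[team, "mean"]) if n >= min_count \
                    else np.nan
            else:
                n, rate = 0, np.nan
            rows.append({"team_id": team, "subgroup": sg.name,
                         "n": n, "rate": rate})
    return pd.DataFrame(rows)


def predicted_subgroup_rates(model: ThrombolysisClassifier,
                             cohort: pd.DataFrame,
                             subgroups: list[SubgroupDefinition] | None = None,
                             hospitals: list[str] | None = None,
                             min_count: int = 5) -> pd.DataFrame:
    """Counterfactually predicted rate per hospital and subgroup.

    The fixed cohort is reassigned to each hospital (as in the
    counterfactual analysis) and the mean predicted probability is taken
    within each subgroup. Cells with fewer than ``min_count`` cohort rows
    are NaN.
    """
    subgroups = subgroups or builtin_subgroups()
    if hasattr(model, "train_index_"):
        overlap = np.intersect1d(np.asarray(cohort.index), model.train_index_)
        if len(overlap):
            raise ValueError(
                f"cohort overlaps {len(overlap)} training rows (leakage)")
    if hospitals is None:
        hospitals = model.encoder_.teams_
    masks = {sg.name: sg.mask(cohort) for sg in subgroups}
    encoded = model.encoder_.transform(cohort)
    rows = []
    for team in hospitals:
        Xh = model.encoder_.reassign(encoded, team)[model.feature_names_]
        p = model.booster_.predict(
            xgb.DMatrix(Xh, feature_names=model.feature_names_))
        for sg in subgroups:
            mask = masks[sg.name]
            n = int(mask.sum())
            rate = float(p[mask].mean()) if n >= min_count else np.nan
            rows.append({"team_id": team, "subgroup": sg.name,
                         "n": n, "rate": rate})
    return pd.DataFrame(rows)


def summarize_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Five-number summary of rates per subgroup across hospitals.

    ``matrix`` is a tidy frame from :func:`observed_subgroup_rates` or
    :func:`predicted_subgroup_rates`; missing cells are excluded. A
    subgroup with no valid cells is reported with NaN summaries and
    ``n_hospitals`` 0.
    """
    rows = []
    for sg, grp in matrix.groupby("subgroup", sort=False):
        rates = grp["rate"].dropna().to_numpy()
        if len(rates) == 0:
            rows.append({"subgroup": sg, "n_hospitals": 0,
                         "min": np.nan, "q1": np.nan, "median": np.nan,
                         "q3": np.nan, "max": np.nan})
            continue
        q1, med, q3 = np.percentile(rates, [25, 50, 75])
        rows.append({"subgroup": sg, "n_hospitals": int(len(rates)),
                     "min": float(rates.min()), "q1": q1, "median": med,
                     "q3": q3, "max": float(rates.max())})
    return pd.DataFrame(rows)
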