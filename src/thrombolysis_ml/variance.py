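"""Partition between-hospital variance into patient-mix and hospital parts.

Each of the 10 features is assigned to one of two subsets: patient
descriptive (characteristics of the person) or hospital descriptive
(identity and in-hospital processes — the hospital attended and the
arrival-to-scan time it achieves). Subset SHAP values are averaged per
hospital and the observed thrombolysis rate is regressed on the
patient-subset mean, the hospital-subset mean, and both, giving the
share of between-hospital variance each explains.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .explain import ShapInteractionTensor, SubsetAttribution, subset_shap
from .synthetic import LABEL_COLUMN

__all__ = [
    "PATIENT_FEATURES",
    "HOSPITAL_FEATURES",
    "default_subset_assignment",
    "SubsetAssignment",
    "PartitionReport",
    "per_hospital_subset_means",
    "regress_partition",
]

PATIENT_FEATURES = [
    "age_midpoint", "nihss", "prior_mrs", "onset_to_arrival_min",
    "infarction", "precise_onset", "anticoagulant", "onset_during_sleep",
]
HOSPITAL_FEATURES = ["arrival_to_scan_min", "stroke_team"]


def default_subset_assignment() -> dict[str, str]:
    """Feature -> {"patient", "hospital"} for the 10 model features."""
    out = {f: "patient" for f in PATIENT_FEATURES}
    out.update({f: "hospital" for f in HOSPITAL_FEATURES})
    return out


@dataclass
class SubsetAssignment:
    """Validated feature partition into patient/hospital subsets.

    The assignment of arrival-to-scan time is configurable: it is treated
    as a hospital process by default, but can be moved to the patient
    subset to probe sensitivity of the variance split.
    """

    mapping: dict[str, str] = field(default_factory=default_subset_assignment)

    def validate(self, features: list[str]) -> None:
        missing = [f for f in features if f not in self.mapping]
        if missing:
            raise KeyError(f"features missing from assignment: {missing}")
        bad = {s for s in self.mapping.values()
               if s not in ("patient", "hospital")}
        if bad:
            raise ValueError(f"unknown subset name(s): {sorted(bad)}")


@dataclass
class PartitionReport:
    """Hospital-level regressions of observed rate on subset SHAP means."""

    hospital_means: pd.DataFrame  # per hospital: patient_mean, hospital_mean,
    #                               observed_rate_percent, n
    fits: pd.DataFrame            # per model (patient/hospital/combined):
    #                               r2, p_value, coefficients

    def r2(self, which: str) -> float:
        return float(self.fits.loc[self.fits["model"] == which, "r2"].iloc[0])


def per_hospital_subset_means(attribution: SubsetAttribution,
                              table: pd.DataFrame) -> pd.DataFrame:
    """Mean per-subset SHAP sums for the patients attending each hospital.

    Returns one row per hospital with the mean patient-subset sum, the
    mean hospital-subset sum, the observed thrombolysis rate (percent)
    and the patient count. Hospitals with no rows are simply absent.
    """
    if len(table) != len(attribution.values):
        raise ValueError("attribution not aligned to table rows")
    subsets = sorted(set(attribution.subsets.values()))
    df = pd.DataFrame({"team": table["stroke_team"].to_numpy()})
    for s in subsets:
        df[f"{s}_sum"] = attribution.subset_sum(s)
    if LABEL_COLUMN in table.columns:
        df["label"] = table[LABEL_COLUMN].to_numpy()
    agg = {f"{s}_mean": (f"{s}_sum", "mean") for s in subsets}
    agg["n"] = ("team", "size")
    if LABEL_COLUMN in table.columns:
        agg["observed_rate_percent"] = ("label", "mean")
    out = df.groupby("team").agg(**agg)
    if "observed_rate_percent" in out.columns:
        out["observed_rate_percent"] *= 100.0
    out.index.name = "team_id"
    return out


def _ols(y: np.ndarray, X: np.ndarray) -> tuple[float, float, np.ndarray]:
    model = sm.OLS(y, sm.add_constant(X)).fit()
    return float(model.rsquared), float(model.f_pvalue), model.params


def regress_partition(tensor: ShapInteractionTensor, table: pd.DataFrame,
                      assignment: SubsetAssignment | dict[str, str] | None = None
                      ) -> PartitionReport:
    """Fit the three hospital-level regressions of the variance partition.

    Observed per-hospital thrombolysis rate (percentage points, hospitals
    weighted equally) is regressed on (a) the mean patient-subset SHAP
    sum, (b) the mean hospital-subset SHAP sum, (c) both. Reports r² and
    the overall-F p-value for each.
    """
    if assignment is None:
        assignment = SubsetAssignment()
    elif isinstance(assignment, dict):
        assignment = SubsetAssignment(mapping=assignment)
    assignment.validate(tensor.feature_names)
    attribution = subset_shap(tensor, assignment.mapping)
    means = per_hospital_subset_means(attribution, table)
    if len(means) < 3:
        raise ValueError("need at least 3 hospitals for the regressions")
    y = means["observed_rate_percent"].to_numpy()
    xp = means["patient_mean"].to_numpy()
    xh = means["hospital_mean"].to_numpy()
    rows = []
    for name, X in [("patient", xp[:, None]), ("hospital", xh[:, None]),
                    ("combined", np.column_stack([xp, xh]))]:
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(y)), X])) \
                < X.shape[1] + 1:
            raise ValueError(f"rank-deficient design for {name} model")
        r2, p, params = _ols(y, X)
        rows.append({"model": name, "r2": r2, "p_value": p,
                     "coefficients": list(params)})
    return PartitionReport(hospital_means=means, fits=pd.DataFrame(rows))
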