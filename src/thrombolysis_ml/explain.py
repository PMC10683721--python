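"""SHAP decomposition of the fitted decision model, in log-odds.

Per-patient attributions come from exact TreeSHAP on the boosted
ensemble (path-dependent expectations, training data as background, as
implemented natively by XGBoost), so for every patient

    base_value + sum_k phi_k = raw margin (log-odds).

The pairwise decomposition refines each phi_k into a main effect (the
tensor diagonal) plus halved symmetric interaction terms whose row sums
recover phi_k. The hospital one-hot block is aggregated by summation
into a single "stroke_team" pseudo-feature on every axis, since only one
indicator is hot per row and the analysis treats hospital attended as
one feature.

The "subset SHAP value" restricts a feature's attribution to its main
effect plus interactions with features in the same named subset only —
the statistic used to separate patient-mix from hospital components of
between-hospital variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy.special import expit

from .model import TEAM_PREFIX, ThrombolysisClassifier

__all__ = [
    "ShapMatrix",
    "ShapInteractionTensor",
    "SubsetAttribution",
    "compute_shap",
    "compute_interactions",
    "subset_shap",
    "waterfall",
    "shap_vs_value_summary",
    "BinnedShapSummary",
]


@dataclass
class ShapMatrix:
    """Per-patient SHAP values (log-odds), hospital block aggregated.

    ``values`` has one column per reported feature; ``base_value`` is the
    model's expected margin; ``margins`` the per-row raw margin, so
    ``base_value + values.sum(axis=1) == margins`` up to float accumulation.
    """

    values: pd.DataFrame
    base_value: float
    margins: np.ndarray

    @property
    def feature_names(self) -> list[str]:
        return list(self.values.columns)

    def additivity_error(self) -> float:
        """Max absolute error of base + sum(contributions) vs raw margin."""
        return float(np.abs(self.base_value + self.values.sum(axis=1).to_numpy()
                            - self.margins).max())


@dataclass
class ShapInteractionTensor:
    """Per-patient symmetric feature-by-feature SHAP interaction tensor.

    ``values[p, i, j]``: diagonal entries are main effects; off-diagonal
    entries hold half the pairwise interaction (so ``t_ij + t_ji`` is the
    full interaction between i and j) and rows sum to the feature's total
    SHAP value. All entries in log-odds. Hospital block aggregated on
    both axes.
    """

    values: np.ndarray  # (n_patients, n_features, n_features)
    feature_names: list[str]
    base_value: float

    def _idx(self, feature: str) -> int:
        try:
            return self.feature_names.index(feature)
        except ValueError:
            raise KeyError(f"feature not in tensor: {feature}") from None

    def main_effect(self, feature: str) -> np.ndarray:
        i = self._idx(feature)
        return self.values[:, i, i]

    def total_shap(self) -> pd.DataFrame:
        """Row sums: total SHAP value per feature per patient."""
        return pd.DataFrame(self.values.sum(axis=2),
                            columns=self.feature_names)

    def symmetry_error(self) -> float:
        return float(np.abs(self.values - np.transpose(
            self.values, (0, 2, 1))).max())


@dataclass
class SubsetAttribution:
    """Per-patient per-feature subset SHAP values under a feature partition.

    ``value(i) = main_effect(i) + sum over same-subset partners j of the
    full interaction (t_ij + t_ji)``; interactions crossing subsets are
    excluded and their total is recorded in ``cross_subset_mass``.
    """

    values: pd.DataFrame
    subsets: dict[str, str]  # feature -> subset name
    cross_subset_mass: np.ndarray

    def subset_sum(self, subset: str) -> np.ndarray:
        cols = [f for f, s in self.subsets.items() if s == subset]
        if not cols:
            raise KeyError(f"no features in subset: {subset}")
        return self.values[cols].sum(axis=1).to_numpy()


def _aggregate_columns(feature_names: list[str]) -> tuple[list[str], list[np.ndarray]]:
    """Group encoded column indices: team one-hot block -> 'stroke_team'."""
    team_idx = [i for i, f in enumerate(feature_names)
                if f.startswith(TEAM_PREFIX)]
    groups: list[tuple[str, list[int]]] = []
    for i, f in enumerate(feature_names):
        if not f.startswith(TEAM_PREFIX):
            groups.append((f, [i]))
    if team_idx:
        groups.append(("stroke_team", team_idx))
    names = [g[0] for g in groups]
    idx = [np.array(g[1]) for g in groups]
    return names, idx


def compute_shap(model: ThrombolysisClassifier, table: pd.DataFrame) -> ShapMatrix:
    """Exact TreeSHAP values for every row of ``table``.

    Hospital indicator columns are summed into one "stroke_team"
    contribution. Additivity (base + contributions = raw margin) holds by
    construction of the tree traversal.
    """
    X = model.encoded(table)
    dm = xgb.DMatrix(X, feature_names=model.feature_names_)
    contribs = model.booster_.predict(dm, pred_contribs=True).astype(float)
    base = float(contribs[0, -1])
    margins = model.booster_.predict(dm, output_margin=True)
    names, groups = _aggregate_columns(model.feature_names_)
    cols = {name: contribs[:, idx].sum(axis=1) for name, idx in zip(names, groups)}
    return ShapMatrix(values=pd.DataFrame(cols), base_value=base,
                      margins=np.asarray(margins, dtype=float))


def compute_interactions(model: ThrombolysisClassifier,
                         table: pd.DataFrame) -> ShapInteractionTensor:
    """Exact TreeSHAP interaction tensor for every row of ``table``.

    The team one-hot block is aggregated on both axes, so the diagonal
    entry for "stroke_team" is the full main effect of the hospital
    attended (within-block interactions included).
    """
    X = model.encoded(table)
    dm = xgb.DMatrix(X, feature_names=model.feature_names_)
    inter = model.booster_.predict(dm, pred_interactions=True).astype(float)
    base = float(inter[0, -1, -1])
    inter = inter[:, :-1, :-1]  # drop bias row/column
    names, groups = _aggregate_columns(model.feature_names_)
    k = len(names)
    out = np.empty((inter.shape[0], k, k), dtype=float)
    for i, gi in enumerate(groups):
        block = inter[:, gi, :]
        for j, gj in enumerate(groups):
            out[:, i, j] = block[:, :, gj].sum(axis=(1, 2))
    return ShapInteractionTensor(values=out, feature_names=names,
                                 base_value=base)


def subset_shap(tensor: ShapInteractionTensor,
                partition: dict[str, str]) -> SubsetAttribution:
    """Subset SHAP values under a named feature partition.

    ``partition`` maps every tensor feature to a subset name. For feature
    i, the subset SHAP value keeps the main effect and the interactions
    with same-subset partners only; interactions that cross subsets are
    excluded and accumulated into ``cross_subset_mass`` so that

        sum_i value(i) + cross_subset_mass = total SHAP sum per patient.
    """
    missing = [f for f in tensor.feature_names if f not in partition]
    if missing:
        raise KeyError(f"features missing from partition: {missing}")
    names = tensor.feature_names
    subset_of = np.array([partition[f] for f in names])
    same = subset_of[:, None] == subset_of[None, :]
    t = tensor.values
    masked = np.where(same[None, :, :], t, 0.0)
    values = pd.DataFrame(masked.sum(axis=2), columns=names)
    cross = np.where(~same[None, :, :], t, 0.0).sum(axis=(1, 2))
    return SubsetAttribution(values=values,
                             subsets={f: partition[f] for f in names},
                             cross_subset_mass=cross)


def waterfall(shap_row: pd.Series, base_value: float) -> pd.DataFrame:
    """Per-feature probability-space steps for one patient.

    Features are ordered by decreasing absolute contribution; partial
    log-odds sums are transformed through the logistic function. The last
    cumulative probability equals the SHAP-implied predicted probability
    ``logistic(base + sum of contributions)`` exactly.
    """
    order = shap_row.abs().sort_values(ascending=False).index
    contributions = shap_row.loc[order]
    cum_logodds = base_value + np.cumsum(contributions.to_numpy())
    return pd.DataFrame({
        "feature": list(order),
        "contribution": contributions.to_numpy(),
        "cumulative_log_odds": cum_logodds,
        "cumulative_probability": expit(cum_logodds),
    })


@dataclass
class BinnedShapSummary:
    """Binned medians/quartiles of a feature's SHAP values."""

    feature: str
    table: pd.DataFrame  # per bin: label, midpoint, n, median, q1, q3

    def median(self, bin_label) -> float:
        row = self.table[self.table["bin"] == bin_label]
        if row.empty:
            raise KeyError(f"no such bin: {bin_label}")
        return float(row["median"].iloc[0])

    def fold_change(self, bin_a, bin_b) -> float:
        """Odds ratio implied by the median SHAP difference between bins."""
        return float(np.exp(self.median(bin_a) - self.median(bin_b)))

    def endpoint_fold_change(self, lo: float, hi: float) -> float:
        """Odds-ratio span of the SHAP trend between two feature values.

        A bin's median SHAP value sits at the bin's median feature value,
        not at its edge, so the raw ``fold_change`` between the extreme
        bins understates a span quoted between feature-value endpoints
        (e.g. a decline "over the first 120 min"). This estimator fits a
        weighted least-squares line through the (bin midpoint, median
        SHAP) points of the bins inside [lo, hi] and evaluates it at the
        endpoints: ``exp(fit(lo) - fit(hi))``.
        """
        t = self.table.dropna(subset=["midpoint"])
        sel = (t["midpoint"] >= lo) & (t["midpoint"] <= hi)
        t = t[sel]
        if len(t) < 2:
            raise ValueError("need at least 2 bins inside [lo, hi]")
        x = t["midpoint"].to_numpy(dtype=float)
        y = t["median"].to_numpy(dtype=float)
        w = t["n"].to_numpy(dtype=float)
        W = np.diag(w)
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ W @ X, X.T @ W @ y)
        return float(np.exp((beta[0] + beta[1] * lo)
                            - (beta[0] + beta[1] * hi)))


def shap_vs_value_summary(table: pd.DataFrame, shap: ShapMatrix,
                          feature: str, bins=None) -> BinnedShapSummary:
    """Relationship between a feature's values and its SHAP values.

    ``bins``: edge sequence for continuous features (half-open [lo, hi)
    intervals, last bin closed), or None to use the distinct feature
    values as bins (binary/ordinal features). Empty bins are omitted with
    a warning.
    """
    if feature not in shap.values.columns:
        raise KeyError(f"feature not in SHAP matrix: {feature}")
    x = table[feature].to_numpy()
    phi = shap.values[feature].to_numpy()
    rows = []
    if bins is None:
        for v in np.unique(x):
            sel = x == v
            mid = float(v) if np.isreal(v) and not isinstance(v, str) else np.nan
            rows.append((v, mid, sel))
    else:
        edges = np.asarray(bins, dtype=float)
        for lo, hi in zip(edges[:-1], edges[1:]):
            last = hi == edges[-1]
            sel = (x >= lo) & ((x <= hi) if last else (x < hi))
            label = f"[{lo:g}, {hi:g}{']' if last else ')'}"
            rows.append((label, (lo + hi) / 2.0, sel))
    out = []
    for label, mid, sel in rows:
        if not sel.any():
            warnings.warn(f"empty bin omitted: {label}", stacklevel=2)
            continue
        q1, med, q3 = np.percentile(phi[sel], [25, 50, 75])
        out.append({"bin": label, "midpoint": mid, "n": int(sel.sum()),
                    "median": med, "q1": q1, "q3": q3})
    return BinnedShapSummary(feature=feature, table=pd.DataFrame(out))
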