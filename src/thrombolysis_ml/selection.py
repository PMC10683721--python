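"""Greedy forward feature selection scored by out-of-fold ROC AUC.

Starting from an empty set, each round adds the candidate feature whose
addition maximises the mean cross-validated AUC (ties broken
lexicographically), stopping once the selected model's AUC is within
``epsilon`` of the AUC of the model using every candidate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model import ModelConfig, ThrombolysisClassifier
from .synthetic import LABEL_COLUMN

__all__ = ["SelectionTrace", "forward_select", "pairwise_feature_r2"]


@dataclass
class SelectionTrace:
    """Result of a forward-selection run."""

    selected: list[str]
    auc_path: list[float]
    full_model_auc: float
    stopped_early: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "round": np.arange(1, len(self.selected) + 1),
            "feature": self.selected,
            "auc": self.auc_path,
        })


def _cv_auc(table: pd.DataFrame, features: list[str], y: np.ndarray,
            config: ModelConfig, pooled: bool) -> float:
    """Mean (or pooled) out-of-fold AUC of a model on ``features`` only."""
    skf = StratifiedKFold(n_splits=config.n_folds, shuffle=True,
                          random_state=config.seed)
    sub = table[features].copy()
    use_hospital = "stroke_team" in features
    if not use_hospital:
        # classifier requires the column; supply a constant dummy team
        sub = sub.assign(stroke_team="_none_")
    aucs, oof = [], np.full(len(y), np.nan)
    for tr, te in skf.split(np.zeros(len(y)), y):
        clf = ThrombolysisClassifier(
            n_rounds=config.n_rounds, max_depth=config.max_depth,
            learning_rate=config.learning_rate, subsample=config.subsample,
            reg_lambda=config.reg_lambda, seed=config.seed,
            use_hospital=use_hospital)
        clf.fit(sub.iloc[tr].reset_index(drop=True), y[tr])
        p = clf.predict_proba(sub.iloc[te])[:, 1]
        oof[te] = p
        aucs.append(roc_auc_score(y[te], p))
    if pooled:
        return float(roc_auc_score(y, oof))
    return float(np.mean(aucs))


def forward_select(table: pd.DataFrame, candidates: list[str],
                   k_folds: int = 5, epsilon: float | None = 0.001,
                   config: ModelConfig | None = None,
                   pooled: bool = False,
                   max_rounds: int | None = None) -> SelectionTrace:
    """Greedy forward selection over ``candidates``.

    Parameters
    ----------
    table
        Labelled patient table (thrombolysis column required).
    candidates
        Feature column names to choose among ("stroke_team" allowed and
        one-hot encoded when evaluated).
    epsilon
        Stop once best AUC >= full-candidate-model AUC - epsilon; None
        disables early stopping (ranks every candidate).
    pooled
        Score candidates on pooled out-of-fold predictions instead of the
        per-fold mean AUC.
    max_rounds
        Cap on the number of selection rounds (None = no cap); useful when
        only the head of the ranking matters.
    """
    if not candidates:
        raise ValueError("candidate list is empty")
    if epsilon is not None and epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if max_rounds is not None and max_rounds < 1:
        raise ValueError("max_rounds must be >= 1")
    config = config or ModelConfig(variant="kfold")
    config.n_folds = k_folds
    y = table[LABEL_COLUMN].to_numpy()
    full_auc = _cv_auc(table, sorted(candidates), y, config, pooled)
    selected: list[str] = []
    auc_path: list[float] = []
    remaining = sorted(candidates)
    while remaining:
        scores = {c: _cv_auc(table, selected + [c], y, config, pooled)
                  for c in remaining}
        best = min(c for c in remaining
                   if scores[c] == max(scores.values()))  # lexicographic ties
        selected.append(best)
        auc_path.append(scores[best])
        remaining.remove(best)
        if epsilon is not None and scores[best] >= full_auc - epsilon:
            return SelectionTrace(selected, auc_path, full_auc,
                                  stopped_early=True)
        if max_rounds is not None and len(selected) >= max_rounds:
            return SelectionTrace(selected, auc_path, full_auc,
                                  stopped_early=True)
    return SelectionTrace(selected, auc_path, full_auc)


def pairwise_feature_r2(table: pd.DataFrame,
                        features: list[str]) -> pd.DataFrame:
    """Symmetric matrix of pairwise r-squared between numeric features.

    Binary features are treated as 0/1 numerics. r-squared is the squared
    Pearson correlation (equivalently the OLS coefficient of
    determination for a simple regression either way around). A constant
    feature yields 0 against everything (with a warning); the diagonal
    is 1.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 features")
    X = table[features].astype(float)
    out = pd.DataFrame(np.eye(len(features)), index=features, columns=features)
    sd = X.std(ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"constant feature(s), r2 recorded as 0: {constant}",
                      stacklevel=2)
    for i, a in enumerate(features):
        for b in features[i + 1:]:
            if a in constant or b in constant:
                r2 = 0.0
            else:
                r2 = float(np.corrcoef(X[a], X[b])[0, 1] ** 2)
            out.loc[a, b] = out.loc[b, a] = r2
    return out
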