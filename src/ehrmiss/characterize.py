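"""Missingness diagnostics.

Two complementary views of missingness structure:

* a completeness *ranking curve*: variables ordered from least to most
  missing, with the complete-case fraction of every rank prefix — the basis
  for choosing how many variables imputation can reasonably support;
* *presence prediction*: a cross-validated random-forest classifier per
  variable, predicting whether the value is recorded from the values of all
  variables outside the target's panel.  AUROC near 0.5 is consistent with
  MCAR; high AUROC indicates that observed data explain the missingness
  (MAR), the regime in which imputation from observed values is defensible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline

from .preprocess import LabMatrix


@dataclass(frozen=True)
class PresencePredictionResult:
    target: str
    fold_aurocs: tuple[float, ...]
    mean_auroc: float
    features: tuple[str, ...]


def missingness_ranking(matrix: LabMatrix) -> pd.DataFrame:
    """Rank variables by missingness and accumulate complete-case rates.

    Returns one row per rank ``r`` (ascending missingness, ties broken by
    variable name): the variable, its percent of patients missing, and the
    percent of patients complete for *all* variables of rank <= r.
    Percentages are exact counts over n.
    """
    values = matrix.values
    if values.shape[0] == 0 or values.shape[1] == 0:
        raise ValueError("matrix must have at least one row and column")
    n = values.shape[0]
    observed = values.notna()
    missing_counts = (~observed).sum(axis=0)
    order = sorted(values.columns, key=lambda c: (missing_counts[c], str(c)))
    rows = []
    complete = np.ones(n, dtype=bool)
    for rank, col in enumerate(order, start=1):
        complete &= observed[col].to_numpy()
        rows.append(
            {
                "rank": rank,
                "variable": col,
                "n_missing": int(missing_counts[col]),
                "pct_missing": 100.0 * missing_counts[col] / n,
                "pct_complete": 100.0 * complete.sum() / n,
            }
        )
    return pd.DataFrame(rows)


def auroc(labels, scores) -> float:
    """Area under the ROC curve by the trapezoidal rule.

    Tied scores contribute half credit (the trapezoid over a tie group),
    making the result identical to the concordant-pair fraction
    (pairs with tied scores counted 1/2).
    """
    labels = np.asarray(labels).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.ndim != 1:
        raise ValueError("labels and scores must be 1-D and equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUROC")
    # descending-score sweep; one ROC vertex per distinct score
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.nonzero(np.diff(sorted_scores))[0]
    boundaries = np.r_[distinct, sorted_labels.size - 1]
    tp = np.cumsum(sorted_labels)[boundaries]
    fp = (boundaries + 1) - tp
    tpr = np.r_[0.0, tp / n_pos]
    fpr = np.r_[0.0, fp / n_neg]
    return float(np.trapezoid(tpr, fpr))


def predict_presence(
    matrix: LabMatrix,
    target: str,
    panel_map: dict[str, str] | None = None,
    folds: int = 10,
    seed: int = 0,
    n_estimators: int = 100,
) -> PresencePredictionResult:
    """Cross-validated random-forest prediction of a variable's presence.

    Labels are the target's observation mask; features are the values of all
    variables outside the target's panel (co-panel members are excluded
    because panels are ordered jointly, which would leak the label).
    Missing feature cells are mean-filled inside each training fold and
    accompanied by per-variable missing-indicator features.
    """
    panel_map = panel_map if panel_map is not None else (matrix.panel_map or {})
    if target not in matrix.values.columns:
        raise KeyError(f"unknown target variable {target!r}")
    target_panel = panel_map.get(target)
    features = [
        c
        for c in matrix.values.columns
        if c != target
        and (target_panel is None or panel_map.get(c) != target_panel)
    ]
    if not features:
        raise ValueError(
            f"no eligible features: all variables share {target!r}'s panel"
        )
    y = matrix.values[target].notna().to_numpy()
    if y.all() or not y.any():
        raise ValueError(
            f"target {target!r} must have both observed and missing patients"
        )
    x = matrix.values[features].to_numpy(dtype=float)

    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_aurocs = []
    for i, (train, test) in enumerate(skf.split(x, y)):
        model = make_pipeline(
            SimpleImputer(strategy="mean", add_indicator=True),
            RandomForestClassifier(
                n_estimators=n_estimators, random_state=seed + i, n_jobs=1
            ),
        )
        model.fit(x[train], y[train])
        scores = model.predict_proba(x[test])[:, 1]
        fold_aurocs.append(auroc(y[test], scores))
    return PresencePredictionResult(
        target=target,
        fold_aurocs=tuple(fold_aurocs),
        mean_auroc=float(np.mean(fold_aurocs)),
        features=tuple(features),
    )
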