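"""Single-feature biomarker evaluation: cross-validated ROC curves and AUC.

Each candidate feature is scored alone: a univariate logistic model is fit
on the training folds of a stratified k-fold split (default k = 5) and
applied to the held-out samples; the pooled out-of-fold scores give the ROC
curve, whose area is computed with the Mann-Whitney estimator

    AUC = (#{case > control} + 0.5 * #{ties}) / (n_case * n_control).

A "raw" mode skips the fitting and scores samples by their expression value
directly, for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigError, DesignError
from .io import CASE, ExpressionStudy


@dataclass
class AucResult:
    feature: str
    auc: float
    roc: np.ndarray  # (n_points, 2) array of (FPR, TPR)
    orientation: str  # "case-high" | "case-low"
    k: int
    seed: int
    fold_assignments: np.ndarray
    scores: np.ndarray


def auc_mann_whitney(scores, labels) -> float:
    """Mann-Whitney AUC of ``scores`` for separating case from control."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    case = labels == CASE
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise DesignError("AUC needs at least one case and one control")
    ranks = rankdata(scores)
    return float((ranks[case].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def roc_points(scores, labels) -> np.ndarray:
    """ROC curve of pooled scores: (FPR, TPR) from (0,0) to (1,1), one step
    per distinct score (ties produce diagonal segments)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=object)
    case = labels == CASE
    n1, n0 = int(case.sum()), int((~case).sum())
    if n1 == 0 or n0 == 0:
        raise DesignError("ROC needs at least one case and one control")
    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_case = case[order].astype(int)
    # group ties: cut at strictly decreasing score boundaries
    distinct = np.r_[np.diff(sorted_scores) != 0, True]
    tps = np.cumsum(sorted_case)[distinct]
    fps = np.cumsum(1 - sorted_case)[distinct]
    tpr = np.r_[0.0, tps / n1]
    fpr = np.r_[0.0, fps / n0]
    return np.column_stack([fpr, tpr])


def trapezoidal_auc(roc: np.ndarray) -> float:
    return float(np.trapezoid(roc[:, 1], roc[:, 0]))


def cv_feature_auc(
    study: ExpressionStudy,
    feature_id: str,
    k: int = 5,
    seed: int = 0,
    *,
    method: str = "logistic",
) -> AucResult:
    """Stratified k-fold out-of-fold AUC for a single feature.

    ``method="logistic"`` fits a univariate logistic score on the training
    samples of each fold; ``method="raw"`` uses the expression value itself
    (no fitting).  Deterministic for a fixed seed.
    """
    if k < 2:
        raise ConfigError("k must be >= 2")
    x = study.feature_values(feature_id)
    y = (study.labels == CASE).astype(int)
    if min(int(y.sum()), int((1 - y).sum())) < k:
        raise DesignError(
            f"class too small for {k}-fold stratification; use a smaller k"
        )

    folds = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    if method == "raw":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
        for i, (_, test) in enumerate(skf.split(x.reshape(-1, 1), y)):
            folds[test] = i
        scores[:] = x
    elif method == "logistic":
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed) % 2**31)
        for i, (train, test) in enumerate(skf.split(x.reshape(-1, 1), y)):
            folds[test] = i
            model = LogisticRegression(max_iter=1000)
            model.fit(x[train].reshape(-1, 1), y[train])
            scores[test] = model.decision_function(x[test].reshape(-1, 1))
    else:
        raise ConfigError(f"unknown scoring method {method!r}")

    auc = auc_mann_whitney(scores, study.labels)
    roc = roc_points(scores, study.labels)
    case_mean = x[study.case_mask].mean()
    ctrl_mean = x[study.control_mask].mean()
    orientation = "case-high" if case_mean >= ctrl_mean else "case-low"
    return AucResult(
        feature=feature_id,
        auc=auc,
        roc=roc,
        orientation=orientation,
        k=k,
        seed=seed,
        fold_assignments=folds,
        scores=scores,
    )


def evaluate_features(
    study: ExpressionStudy,
    features,
    k: int = 5,
    seed: int = 0,
    *,
    method: str = "logistic",
) -> pd.DataFrame:
    """Per-feature CV AUC table, sorted by AUC descending."""
    rows = []
    for f in features:
        if f not in study.feature_ids:
            continue
        res = cv_feature_auc(study, f, k=k, seed=seed, method=method)
        rows.append({"feature": f, "auc": res.auc, "orientation": res.orientation,
                     "k": k, "seed": seed})
    table = pd.DataFrame(rows, columns=["feature", "auc", "orientation", "k", "seed"])
    return table.sort_values(["auc", "feature"], ascending=[False, True]).reset_index(drop=True)
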