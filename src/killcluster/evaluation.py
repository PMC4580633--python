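"""Classification performance: ROC/AUC, balanced cut-off, k-fold CV.

The AUC equals the Mann–Whitney probability that a random feeding cluster
scores above a random non-feeding cluster (ties counted half).  The
probability cut-off is chosen to balance sensitivity (true-positive rate)
against specificity (true-negative rate): among candidate thresholds (the
midpoints between adjacent distinct scores plus both extremes) the one
minimizing |sensitivity - specificity| is returned, ties broken toward the
smaller cut-off.  A cluster is classified as feeding when its score is at
or above the cut-off.

Cross-validated AUC uses stratified k-fold partitions (default k = 20,
seeded): the model is refitted on each training remainder, held-out scores
are computed and the unweighted mean of the per-fold AUCs is reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .model import FeedingModel, ModelSpec, SeparationError, complete_cases

__all__ = ["EvalResult", "auc", "choose_cutoff", "kfold_auc", "evaluate_model"]


def _check_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or (~labels).all():
        raise ValueError("both classes must be present")
    return labels


def auc(scores, labels) -> float:
    """Area under the ROC curve (rank / Mann–Whitney statistic)."""
    labels = _check_labels(np.asarray(labels))
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def choose_cutoff(scores, labels) -> tuple[float, float, float]:
    """Balanced sensitivity/specificity threshold.

    Returns ``(cutoff, sensitivity, specificity)`` under the rule
    predict-feeding when ``score >= cutoff``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = _check_labels(labels)
    distinct = np.unique(scores)
    candidates = np.concatenate(
        ([distinct[0]], (distinct[:-1] + distinct[1:]) / 2.0, [distinct[-1]])
    )
    n_pos = labels.sum()
    n_neg = (~labels).sum()
    best = None
    for c in candidates:
        pred = scores >= c
        sens = (pred & labels).sum() / n_pos
        spec = (~pred & ~labels).sum() / n_neg
        gap = abs(sens - spec)
        if best is None or gap < best[0] - 1e-15:
            best = (gap, float(c), float(sens), float(spec))
    assert best is not None
    return best[1], best[2], best[3]


def kfold_auc(
    df: pd.DataFrame,
    spec: ModelSpec,
    k: int = 20,
    seed: int = 0,
    response: str = "FEEDING",
) -> float:
    """Mean held-out AUC over a seeded stratified k-fold partition."""
    data = complete_cases(df, [spec]).reset_index(drop=True)
    n = len(data)
    if k < 2 or k > n:
        raise ValueError(f"k must be in [2, n]; got k={k}, n={n}")
    y = data[response].to_numpy(dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"cannot stratify {k} folds with class counts {counts.tolist()}"
        )
    folds = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    aucs = []
    skipped = 0
    for train, test in folds.split(np.zeros(n), y):
        try:
            res = FeedingModel.from_dataframe(
                data.iloc[train], spec, response
            ).fit()
        except SeparationError:
            skipped += 1
            continue
        scores = res.predict(data.iloc[test])
        aucs.append(auc(scores, y[test]))
    if not aucs:
        raise RuntimeError("every CV training fold separated; cannot fit")
    if skipped:
        warnings.warn(
            f"kfold_auc: {skipped}/{k} folds separated during refit and were "
            "skipped",
            stacklevel=2,
        )
    return float(np.mean(aucs))


@dataclass(frozen=True)
class EvalResult:
    """Apparent and cross-validated performance of one model."""

    cutoff: float
    sensitivity: float
    specificity: float
    auc: float
    cv_auc: float | None
    k_folds: int
    seed: int


def evaluate_model(
    df: pd.DataFrame,
    spec: ModelSpec,
    k: int = 20,
    seed: int = 0,
    response: str = "FEEDING",
    cv: bool = True,
) -> EvalResult:
    """Apparent AUC, balanced cut-off and (optionally) k-fold CV AUC."""
    data = complete_cases(df, [spec]).reset_index(drop=True)
    res = FeedingModel.from_dataframe(data, spec, response).fit()
    scores = res.fittedvalues()
    y = data[response].to_numpy(dtype=bool)
    apparent = auc(scores, y)
    cutoff, sens, specf = choose_cutoff(scores, y)
    cv_auc = kfold_auc(data, spec, k=k, seed=seed, response=response) if cv else None
    return EvalResult(
        cutoff=cutoff,
        sensitivity=sens,
        specificity=specf,
        auc=apparent,
        cv_auc=cv_auc,
        k_folds=k if cv else 0,
        seed=seed,
    )
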