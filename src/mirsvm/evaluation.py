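"""ROC evaluation: full AUC, the truncated ROC_10*n score, and feature ablation.

The full AUC equals the probability that a random positive outranks a random
negative (ties counted 1/2).  ROC_10*n is a truncated variant of ROC_50: the
area under the (FPR, TPR) curve restricted to the first 10*n false positives,
where n is the number of miRNAs in the evaluation set.  The x-axis remains
the false-positive *rate* over all negatives, so the maximum attainable
score is 10*n / #negatives — of order 1e-2 on genome-scale gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_curve as _sk_roc_curve

__all__ = ["EvalResult", "roc_curve_auc", "roc_truncated", "ablation_study"]


@dataclass
class EvalResult:
    """ROC curve with summary scores.

    ``fp``/``tp`` are false/true positive *counts* at each threshold;
    ``fpr``/``tpr`` the corresponding rates.  ``fold_aucs`` carries per-fold
    scores when the result summarises a cross-validation.
    """

    fpr: np.ndarray
    tpr: np.ndarray
    fp: np.ndarray
    tp: np.ndarray
    auc: float
    roc_10n: Optional[float] = None
    n_mirnas: Optional[int] = None
    fold_aucs: Optional[np.ndarray] = None

    @property
    def mean_fold_auc(self) -> float:
        return float(np.mean(self.fold_aucs))

    @property
    def sem_fold_auc(self) -> float:
        k = len(self.fold_aucs)
        return float(np.std(self.fold_aucs, ddof=1) / np.sqrt(k))


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("ROC evaluation requires both positive and negative labels")


def roc_curve_auc(scores, labels) -> EvalResult:
    """Threshold-sweep ROC curve and its area.

    ``labels`` are 0/1 (1 = positive).  Tied scores are handled by
    trapezoidal interpolation, so the area equals the pairwise rank
    statistic with ties counted 1/2.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    _check_labels(labels)
    fpr, tpr, _ = _sk_roc_curve(labels, scores, drop_intermediate=False)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    auc = float(np.trapezoid(tpr, fpr))
    return EvalResult(
        fpr=fpr,
        tpr=tpr,
        fp=np.round(fpr * n_neg).astype(int),
        tp=np.round(tpr * n_pos).astype(int),
        auc=auc,
    )


def roc_truncated(scores, labels, n_mirnas: int) -> float:
    """ROC_10*n: area under the ROC curve up to 10*n false positives.

    The FPR axis is measured against all negatives; when the cutoff covers
    every negative the value equals the full AUC.
    """
    if n_mirnas < 1:
        raise ValueError("n_mirnas must be >= 1")
    res = roc_curve_auc(scores, labels)
    labels = np.asarray(labels)
    n_neg = int((labels == 0).sum())
    cutoff = 10 * n_mirnas
    if cutoff >= n_neg:
        return res.auc
    fpr_max = cutoff / n_neg
    fpr, tpr = res.fpr, res.tpr
    # Clip the curve at fpr_max, interpolating the TPR on the last segment.
    idx = np.searchsorted(fpr, fpr_max, side="right")
    fpr_clip = np.concatenate([fpr[:idx], [fpr_max]])
    tpr_at_max = np.interp(fpr_max, fpr, tpr)
    tpr_clip = np.concatenate([tpr[:idx], [tpr_at_max]])
    return float(np.trapezoid(tpr_clip, fpr_clip))


def ablation_study(
    features: pd.DataFrame,
    labels,
    feature_groups: Dict[str, Sequence[str]],
    spec,
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Leave-one-feature-group-out cross-validation comparison.

    Each group is removed in turn and the k-fold cross-validated mean AUC is
    recomputed with the identical fold partition (same ``seed``), so the
    ``delta_auc`` column (full-model AUC minus ablated AUC) is directly
    comparable across groups.
    """
    from .site_svm import crossval_discriminants

    if len(feature_groups) < 2:
        raise ValueError("ablation requires at least two feature groups")
    for name, cols in feature_groups.items():
        unknown = [c for c in cols if c not in features.columns]
        if unknown:
            raise ValueError(f"feature group {name!r} names unknown features: {unknown}")

    full = crossval_discriminants(features, labels, spec, k=k, seed=seed)
    full_auc = full.eval.mean_fold_auc
    rows = []
    for name, cols in feature_groups.items():
        reduced = features.drop(columns=list(cols))
        res = crossval_discriminants(reduced, labels, spec, k=k, seed=seed)
        rows.append(
            {
                "omitted_group": name,
                "mean_cv_auc": res.eval.mean_fold_auc,
                "delta_auc": full_auc - res.eval.mean_fold_auc,
            }
        )
    table = pd.DataFrame(rows, columns=["omitted_group", "mean_cv_auc", "delta_auc"])
    table.attrs["full_model_auc"] = full_auc
    return table
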