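"""Site-level SVM: training, cross-validated discriminants, scoring.

The site classifier separates sites on down-regulated genes (positive) from
sites on unaffected genes.  The default kernel is a homogeneous polynomial
K(x, y) = (gamma x.y)^d with degree 5 and cost factor C = 2; "homogeneous"
means a zero constant term (coef0 = 0).  Discriminant values — the raw SVM
decision-function outputs, positive for predicted functional sites — are the
predicted regulatory strength of each site and feed the mRNA-level stage.

For training-set genes the discriminants come from stratified 10-fold
cross-validation: each site is scored only by the model from whose training
folds it was excluded, so the downstream mRNA features never see a
discriminant produced by a model trained on that site.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass
from typing import Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .evaluation import EvalResult, roc_curve_auc
from .site_features import Normalizer

__all__ = [
    "KernelSpec",
    "DEFAULT_SITE_KERNEL",
    "SiteModel",
    "CrossvalResult",
    "train_site_model",
    "crossval_discriminants",
    "score_sites",
    "parameter_grid",
    "grid_search_kernel",
]

KERNEL_KINDS = ("linear", "gaussian", "homogeneous_poly", "inhomogeneous_poly")

# Tie-break order for grid search: simpler kernels first.
_KIND_COMPLEXITY = {
    "linear": 0,
    "homogeneous_poly": 1,
    "inhomogeneous_poly": 2,
    "gaussian": 3,
}


@dataclass(frozen=True)
class KernelSpec:
    """SVM kernel and its parameters (cost factor C, gamma, degree)."""

    kind: str = "homogeneous_poly"
    C: float = 2.0
    gamma: float = 1.0
    degree: int = 5

    def __post_init__(self):
        if self.kind not in KERNEL_KINDS:
            raise ValueError(f"unknown kernel kind {self.kind!r}")

    def make_svc(self) -> SVC:
        common = dict(C=self.C, cache_size=500)
        if self.kind == "linear":
            return SVC(kernel="linear", **common)
        if self.kind == "gaussian":
            return SVC(kernel="rbf", gamma=self.gamma, **common)
        coef0 = 0.0 if self.kind == "homogeneous_poly" else 1.0
        return SVC(
            kernel="poly", degree=self.degree, gamma=self.gamma, coef0=coef0, **common
        )

    @property
    def complexity(self) -> tuple:
        degree = self.degree if "poly" in self.kind else 0
        return (_KIND_COMPLEXITY[self.kind], degree, self.C, self.gamma)


#: Best site-level kernel: homogeneous polynomial, degree 5, cost factor 2.
#: gamma = 2^-5 (from the search grid) keeps kernel values (gamma x.y)^5 of
#: order one for ~20 features normalized to [-1, 1].
DEFAULT_SITE_KERNEL = KernelSpec(kind="homogeneous_poly", C=2.0, gamma=2.0 ** -5, degree=5)

#: Default gene-level kernel: linear with default cost factor.
DEFAULT_MRNA_KERNEL = KernelSpec(kind="linear", C=1.0)


def parameter_grid() -> List[KernelSpec]:
    """The kernel/parameter search grid: C = 2^(2n-5) for 0 <= n <= 11,
    gamma = 2^(2n-13) for 0 <= n <= 10, degree d = 2..8."""
    cs = [2.0 ** (2 * n - 5) for n in range(12)]
    gammas = [2.0 ** (2 * n - 13) for n in range(11)]
    degrees = list(range(2, 9))
    grid: List[KernelSpec] = []
    grid += [KernelSpec("linear", C=c) for c in cs]
    grid += [KernelSpec("gaussian", C=c, gamma=g) for c, g in itertools.product(cs, gammas)]
    for kind in ("homogeneous_poly", "inhomogeneous_poly"):
        grid += [
            KernelSpec(kind, C=c, gamma=g, degree=d)
            for c, g, d in itertools.product(cs, gammas, degrees)
        ]
    return grid


@dataclass
class SiteModel:
    """Fitted site-level classifier with its normalizer and feature schema."""

    svc: SVC
    kernel: KernelSpec
    normalizer: Optional[Normalizer]
    feature_names: tuple
    schema_version: str
    model_id: str = ""

    def __post_init__(self):
        if not self.model_id:
            self.model_id = _model_fingerprint(self.svc, self.kernel)


def _model_fingerprint(svc: SVC, kernel: KernelSpec) -> str:
    h = hashlib.sha256()
    h.update(repr(kernel).encode())
    for arr in (svc.support_vectors_, svc.dual_coef_, svc.intercept_):
        h.update(np.ascontiguousarray(arr).tobytes())
    return h.hexdigest()[:16]


def _check_two_classes(y: np.ndarray) -> None:
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("training data contains a single class")


def train_site_model(
    features: pd.DataFrame,
    labels,
    spec: KernelSpec = DEFAULT_SITE_KERNEL,
    seed: int = 0,
    normalizer: Optional[Normalizer] = None,
    schema_version: str = "",
) -> SiteModel:
    """Fit the soft-margin SVM on normalized site features.

    ``labels`` are 0/1 with 1 = site on a down-regulated gene.  Training is
    deterministic given the data; ``seed`` is accepted for interface
    symmetry with the stochastic stages.
    """
    y = np.asarray(labels)
    _check_two_classes(y)
    svc = spec.make_svc()
    svc.fit(features.to_numpy(dtype=float), y)
    return SiteModel(
        svc=svc,
        kernel=spec,
        normalizer=normalizer,
        feature_names=tuple(features.columns),
        schema_version=schema_version or f"site-svm/{len(features.columns)}",
    )


def score_sites(model: SiteModel, features: pd.DataFrame) -> np.ndarray:
    """Discriminant values for a feature table; positive = predicted
    functional site.  The feature schema must match the model's."""
    if tuple(features.columns) != model.feature_names:
        raise ValueError(
            "feature schema mismatch: model expects "
            f"{list(model.feature_names)}, got {list(features.columns)}"
        )
    return model.svc.decision_function(features.to_numpy(dtype=float))


@dataclass
class CrossvalResult:
    """Per-record cross-validation discriminants and fold assignment."""

    discriminants: np.ndarray
    fold_assignment: np.ndarray
    eval: EvalResult


def crossval_discriminants(
    features: pd.DataFrame,
    labels,
    spec: KernelSpec = DEFAULT_SITE_KERNEL,
    k: int = 10,
    seed: int = 0,
) -> CrossvalResult:
    """Stratified k-fold cross-validation discriminants.

    Every record lands in exactly one test fold and its discriminant comes
    only from the model not trained on it.  Per-fold ROC scores are
    collected in ``eval.fold_aucs``; the pooled ROC curve over all held-out
    discriminants is also reported.
    """
    y = np.asarray(labels)
    _check_two_classes(y)
    _, counts = np.unique(y, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class count ({counts.min()})"
        )
    X = features.to_numpy(dtype=float)
    n = len(y)
    disc = np.empty(n, dtype=float)
    fold_of = np.empty(n, dtype=int)
    fold_aucs = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    for fold, (train_idx, test_idx) in enumerate(skf.split(X, y)):
        svc = spec.make_svc()
        svc.fit(X[train_idx], y[train_idx])
        d = svc.decision_function(X[test_idx])
        disc[test_idx] = d
        fold_of[test_idx] = fold
        fold_aucs.append(roc_curve_auc(d, y[test_idx]).auc)
    pooled = roc_curve_auc(disc, y)
    pooled.fold_aucs = np.asarray(fold_aucs)
    return CrossvalResult(discriminants=disc, fold_assignment=fold_of, eval=pooled)


def grid_search_kernel(
    features: pd.DataFrame,
    labels,
    grid: Optional[Iterable[KernelSpec]] = None,
    k: int = 10,
    seed: int = 0,
) -> tuple:
    """Pick the kernel with the best mean CV AUC over ``grid``.

    Ties are broken toward simpler kernels (linear before polynomial, lower
    degree first).  Returns ``(best_spec, results_table)``.
    """
    specs = list(grid) if grid is not None else parameter_grid()
    rows = []
    for spec in specs:
        res = crossval_discriminants(features, labels, spec, k=k, seed=seed)
        rows.append((spec, res.eval.mean_fold_auc))
    best_spec, _ = min(rows, key=lambda r: (-r[1], r[0].complexity))
    table = pd.DataFrame(
        [(s.kind, s.C, s.gamma, s.degree, auc) for s, auc in rows],
        columns=["kind", "C", "gamma", "degree", "mean_cv_auc"],
    )
    return best_spec, table
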