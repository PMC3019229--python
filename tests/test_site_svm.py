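"""Site-level SVM: training, discriminants, cross-validation, grid search."""

import numpy as np
import pandas as pd
import pytest
from sklearn.datasets import make_blobs

from mirsvm import (
    DEFAULT_SITE_KERNEL,
    KernelSpec,
    crossval_discriminants,
    grid_search_kernel,
    roc_curve_auc,
    score_sites,
    train_site_model,
)


def _blobs(n=120, seed=0, sep=8.0):
    X, y = make_blobs(
        n_samples=n, centers=[[-sep / 2, 0], [sep / 2, 0]], cluster_std=1.0,
        random_state=seed,
    )
    return pd.DataFrame(X, columns=["f0", "f1"]), y


def test_separable_data_trains_to_perfect_accuracy():
    X, y = _blobs()
    model = train_site_model(X, y, KernelSpec("linear", C=1.0))
    assert (model.svc.predict(X.to_numpy()) == y).all()
    disc = score_sites(model, X)
    assert roc_curve_auc(disc, y).auc == 1.0


def test_training_is_deterministic():
    X, y = _blobs(seed=3)
    d1 = score_sites(train_site_model(X, y, seed=5), X)
    d2 = score_sites(train_site_model(X, y, seed=5), X)
    assert np.array_equal(d1, d2)


def test_single_class_input_rejected():
    X, y = _blobs()
    with pytest.raises(ValueError, match="single class"):
        train_site_model(X, np.zeros_like(y))


def test_schema_mismatch_rejected():
    X, y = _blobs()
    model = train_site_model(X, y)
    with pytest.raises(ValueError, match="schema mismatch"):
        score_sites(model, X.rename(columns={"f0": "other"}))


def test_decision_function_matches_manual_kernel_expansion():
    """The homogeneous polynomial decision function equals the explicit dual
    expansion sum_i alpha_i (gamma x.sv_i)^d + b — confirming a zero
    constant term."""
    X, y = _blobs(n=60, seed=9, sep=4.0)
    spec = KernelSpec("homogeneous_poly", C=2.0, gamma=1.0, degree=5)
    model = train_site_model(X, y, spec)
    svc = model.svc
    Xv = X.to_numpy()
    manual = (
        svc.dual_coef_ @ (spec.gamma * (svc.support_vectors_ @ Xv.T)) ** spec.degree
    ).ravel() + svc.intercept_
    assert np.allclose(manual, svc.decision_function(Xv), atol=1e-10)


def test_homogeneous_kernel_scaling_property():
    """K(a x, y) = a^d K(x, y) for the homogeneous polynomial kernel, hence
    scaling all inputs rescales decision values without reordering them."""
    X, y = _blobs(n=80, seed=2, sep=3.0)
    spec = KernelSpec("homogeneous_poly", C=2.0, degree=5)
    model = train_site_model(X, y, spec)
    d = score_sites(model, X)
    a = 1.7
    sv = model.svc.support_vectors_
    k1 = (a * X.to_numpy() @ sv.T) ** spec.degree
    k2 = a ** spec.degree * (X.to_numpy() @ sv.T) ** spec.degree
    assert np.allclose(k1, k2)
    assert np.array_equal(np.argsort(d), np.argsort(score_sites(model, X * a)))


def test_crossval_folds_partition_records():
    X, y = _blobs(n=100, seed=1)
    res = crossval_discriminants(X, y, KernelSpec("linear", C=1.0), k=10, seed=0)
    folds = res.fold_assignment
    assert len(folds) == 100
    assert set(folds) == set(range(10))
    counts = np.bincount(folds)
    assert counts.sum() == 100 and counts.max() == counts.min() == 10
    assert len(res.eval.fold_aucs) == 10


def test_crossval_discriminants_come_from_held_out_fold_models():
    """Refitting fold 0's training complement reproduces fold 0's
    discriminants exactly — the held-out record never trains its own model."""
    X, y = _blobs(n=100, seed=6, sep=2.5)
    spec = KernelSpec("linear", C=1.0)
    res = crossval_discriminants(X, y, spec, k=5, seed=3)
    test_idx = np.where(res.fold_assignment == 0)[0]
    train_idx = np.where(res.fold_assignment != 0)[0]
    refit = train_site_model(X.iloc[train_idx], y[train_idx], spec)
    again = score_sites(refit, X.iloc[test_idx])
    assert np.allclose(again, res.discriminants[test_idx], atol=1e-12)


def test_crossval_errors_when_k_exceeds_class_count():
    X, y = _blobs(n=30, seed=0)
    with pytest.raises(ValueError, match="exceeds the smallest class"):
        crossval_discriminants(X, y, k=20)


def test_crossval_consistent_with_holdout_on_strong_signal():
    X, y = _blobs(n=200, seed=12, sep=3.0)
    res = crossval_discriminants(X, y, KernelSpec("linear", C=1.0), k=10, seed=0)
    half = len(y) // 2
    model = train_site_model(X.iloc[:half], y[:half], KernelSpec("linear", C=1.0))
    holdout_auc = roc_curve_auc(score_sites(model, X.iloc[half:]), y[half:]).auc
    assert abs(res.eval.mean_fold_auc - holdout_auc) <= 0.05


def test_grid_search_breaks_ties_toward_simpler_kernels():
    X, y = _blobs(n=80, seed=4)  # widely separable: every kernel reaches AUC 1
    grid = [
        KernelSpec("homogeneous_poly", C=2.0, degree=3),
        KernelSpec("linear", C=1.0),
        KernelSpec("homogeneous_poly", C=2.0, degree=2),
    ]
    best, table = grid_search_kernel(X, y, grid, k=5, seed=0)
    assert best.kind == "linear"
    assert len(table) == 3
    assert table["mean_cv_auc"].max() == 1.0
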