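"""Discriminant binning and mRNA-level feature construction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from mirsvm import (
    BIN_PERCENTILES,
    MRNA_FEATURE_NAMES,
    assemble_training_set,
    bin_values,
    compute_mrna_features,
    fit_binner,
    select_training_genes,
)


def test_binner_on_standard_normal_matches_gaussian_tail():
    rng = np.random.default_rng(0)
    values = rng.normal(size=1000)
    binner = fit_binner(values)
    counts = bin_values(binner, values)
    assert counts.sum() == 1000
    upper_fraction = counts[-1] / 1000
    expected = norm.sf(2.0)  # ~0.0228
    assert abs(upper_fraction - expected) < 0.015  # well within binomial error
    assert np.all(np.diff(binner.cuts) >= 0)


def test_degenerate_constant_input_handled_without_error():
    binner = fit_binner([3.0] * 50)
    assert binner.degenerate
    counts = bin_values(binner, [3.0, 3.0, 4.0])
    assert counts[1] == 3 and counts.sum() == 3  # all mass in first interior bin


def test_last_cut_point_is_max_of_non_extreme_values():
    rng = np.random.default_rng(1)
    values = rng.normal(size=500)
    binner = fit_binner(values)
    interior = values[
        (values >= binner.lower_threshold) & (values <= binner.upper_threshold)
    ]
    assert binner.cuts[-1] == pytest.approx(interior.max())


def test_binner_requires_twenty_values():
    with pytest.raises(ValueError, match="at least 20"):
        fit_binner(np.arange(10))


def test_value_exactly_at_cut_goes_to_lower_bin():
    values = np.arange(100, dtype=float)
    binner = fit_binner(values)
    cut = binner.cuts[3]
    counts = bin_values(binner, [cut])
    assert counts[4] == 1  # bin 4 = (cuts[2], cuts[3]]: closed upper edge


def test_empty_value_list_gives_all_zero_counts():
    binner = fit_binner(np.arange(30, dtype=float))
    assert bin_values(binner, []).sum() == 0


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    st.integers(0, 2**31 - 1),
    st.integers(1, 12),
)
def test_bin_counts_always_sum_to_site_count(seed, n_sites):
    """Conservation: every discriminant lands in exactly one of 16 bins,
    including values far outside the training range."""
    rng = np.random.default_rng(seed)
    binner = fit_binner(rng.normal(size=200))
    values = rng.normal(scale=10.0, size=n_sites)  # mostly outside the cuts
    counts = bin_values(binner, values)
    assert counts.sum() == n_sites
    assert (counts >= 0).all()


def test_gene_with_three_sites_contributes_three_counts():
    binner = fit_binner(np.linspace(-1, 1, 100))
    features = compute_mrna_features([100, 130, 200], [0.5, -0.2, 0.1], 1000, binner)
    bins = [features[f"disc_bin_{i:02d}"] for i in range(16)]
    assert sum(bins) == 3.0
    assert features["n_sites"] == 3.0


def test_pair_distance_window_and_flags():
    binner = fit_binner(np.linspace(-1, 1, 100))
    f = compute_mrna_features([100, 120], [0.1, 0.2], 1000, binner)
    assert f["pairs_17_35"] == 1.0  # distance 20 is inside [17, 35]
    assert f["min_pair_dist_log"] == pytest.approx(math.log10(21))
    assert f["few_sites_flag"] == 1.0
    assert f["site_density"] == pytest.approx(0.002)
    assert f["max_discriminant"] == 0.2

    many = compute_mrna_features(
        list(range(100, 100 + 9 * 50, 50)), [0.0] * 9, 1000, binner
    )
    assert many["few_sites_flag"] == 0.0  # 9 sites
    assert many["pairs_17_35"] == 0.0

    five = compute_mrna_features([100, 200, 300, 400, 500], [0.0] * 5, 1000, binner)
    assert five["few_sites_flag"] == 1.0  # 5 < 7


def test_zero_site_gene_rejected():
    binner = fit_binner(np.linspace(-1, 1, 100))
    with pytest.raises(ValueError, match="zero sites"):
        compute_mrna_features([], [], 1000, binner)


def _gene_pool(n_low, n_high, n_pos, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_pos):
        rows.append(("p%d" % i, "m1", "down_regulated", int(rng.integers(1, 5))))
    for i in range(n_low):
        rows.append(("l%d" % i, "m1", "unaffected", int(rng.integers(1, 8))))
    for i in range(n_high):
        rows.append(("h%d" % i, "m1", "unaffected", int(rng.integers(8, 30))))
    return pd.DataFrame(
        rows, columns=["transcript_id", "mirna_id", "label", "n_sites"]
    )


def test_high_site_negative_augmentation_counts():
    pool = _gene_pool(n_low=500, n_high=5000, n_pos=50)
    selected = select_training_genes(pool, seed=1, negative_cap=400)
    high = selected[(selected["label"] == "unaffected") & (selected["n_sites"] > 7)]
    low = selected[(selected["label"] == "unaffected") & (selected["n_sites"] <= 7)]
    assert len(high) == 1000  # exactly 1000 high-site negatives added
    assert len(low) == 400  # capped
    assert (selected["label"] == "down_regulated").sum() == 50

    small_pool = _gene_pool(n_low=100, n_high=800, n_pos=20)
    selected = select_training_genes(small_pool, seed=1)
    high = selected[(selected["label"] == "unaffected") & (selected["n_sites"] > 7)]
    assert len(high) == 800  # all available when fewer than 1000 exist


def test_selection_reproducible_and_requires_positives():
    pool = _gene_pool(n_low=300, n_high=50, n_pos=10)
    s1 = select_training_genes(pool, seed=9, negative_cap=100)
    s2 = select_training_genes(pool, seed=9, negative_cap=100)
    assert s1.equals(s2)
    negatives_only = pool[pool["label"] == "unaffected"]
    with pytest.raises(ValueError, match="no positive"):
        select_training_genes(negatives_only)


def test_assemble_training_set_aligns_features_with_selection():
    pool = _gene_pool(n_low=60, n_high=10, n_pos=15, seed=3)
    features = pd.DataFrame(
        np.random.default_rng(0).normal(size=(len(pool), len(MRNA_FEATURE_NAMES))),
        columns=MRNA_FEATURE_NAMES,
    )
    X, y, selected = assemble_training_set(pool, features, seed=2, negative_cap=30)
    assert len(X) == len(y) == len(selected)
    assert y.sum() == 15
    assert (X.index == selected.index).all()
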