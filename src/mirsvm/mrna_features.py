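"""mRNA-level features: the 16-bin discriminant distribution and gene traits.

SVMs need fixed-length inputs, but genes have varying numbers of target
sites.  Each gene's site discriminants are therefore re-encoded as counts
over 16 bins of the *training* discriminant distribution: one bin for lower
extremes (values below mean - 2 sd), 14 interior bins bounded by the 25.00,
43.75, 57.81, 68.36, 76.27, 82.20, 86.65, 89.99, 92.49, 94.37, 95.78,
97.19, 98.6 and 100 percentiles of the distribution with extremes removed,
and one bin for upper extremes (above mean + 2 sd).  The uneven thresholds
put high resolution on the upper tail, where strong sites live.

The remaining gene-level features capture site number and spacing: site
count, UTR length, site density, a binary "fewer than 7 sites" flag, the
number of site pairs at the cooperativity-prone 17-35 nt spacing, the
minimum pairwise seed distance, and the strongest single-site discriminant.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log10
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BIN_PERCENTILES",
    "N_BINS",
    "MRNA_FEATURE_NAMES",
    "MRNA_SCHEMA_VERSION",
    "DiscriminantBinner",
    "fit_binner",
    "bin_values",
    "compute_mrna_features",
    "select_training_genes",
    "assemble_training_set",
]

BIN_PERCENTILES = (
    25.00, 43.75, 57.81, 68.36, 76.27, 82.20, 86.65,
    89.99, 92.49, 94.37, 95.78, 97.19, 98.6, 100.0,
)
N_BINS = 16
MRNA_SCHEMA_VERSION = "mrna-features-1"

#: Site pairs whose seed-start spacing falls in this window act cooperatively.
SYNERGY_DISTANCE = (17, 35)

#: Genes with fewer sites than this get the binary "few sites" flag.
FEW_SITES_THRESHOLD = 7

#: Cap applied to the minimum pairwise distance before log-scaling; also the
#: value used for genes with a single site.
MIN_DIST_CAP = 10_000

BIN_FEATURES = [f"disc_bin_{i:02d}" for i in range(N_BINS)]

MRNA_FEATURE_NAMES: List[str] = BIN_FEATURES + [
    "n_sites",
    "utr_length_log",
    "site_density",
    "few_sites_flag",
    "pairs_17_35",
    "min_pair_dist_log",
    "max_discriminant",
]


@dataclass(frozen=True)
class DiscriminantBinner:
    """Binning of discriminant values fitted on the training distribution.

    ``cuts`` are the 14 percentile cut points of the distribution with
    extremes (|v - mean| > 2 sd) removed.  A binner fitted on a constant
    distribution (sd = 0) is degenerate: all values fall in the first
    interior bin and the extreme bins stay empty.
    """

    mean: float
    sd: float
    cuts: tuple

    @property
    def lower_threshold(self) -> float:
        return self.mean - 2.0 * self.sd

    @property
    def upper_threshold(self) -> float:
        return self.mean + 2.0 * self.sd

    @property
    def degenerate(self) -> bool:
        return self.sd == 0.0

    def to_dict(self) -> dict:
        return {"mean": self.mean, "sd": self.sd, "cuts": list(self.cuts)}

    @classmethod
    def from_dict(cls, d: Mapping) -> "DiscriminantBinner":
        return cls(mean=float(d["mean"]), sd=float(d["sd"]), cuts=tuple(d["cuts"]))


def fit_binner(values, min_count: int = 20) -> DiscriminantBinner:
    """Fit the binner on all training discriminant values (>= ``min_count``).

    Mean and sd (sample, ddof=1) are computed on all values; extremes beyond
    two standard deviations are removed before the percentile cut points are
    taken with linear interpolation.
    """
    v = np.asarray(values, dtype=float)
    if v.size < min_count:
        raise ValueError(f"binner requires at least {min_count} values, got {v.size}")
    mean = float(np.mean(v))
    sd = float(np.std(v, ddof=1))
    if sd == 0.0:
        return DiscriminantBinner(mean=mean, sd=0.0, cuts=(mean,) * len(BIN_PERCENTILES))
    lo, hi = mean - 2.0 * sd, mean + 2.0 * sd
    interior = v[(v >= lo) & (v <= hi)]
    cuts = np.percentile(interior, BIN_PERCENTILES)  # linear interpolation
    return DiscriminantBinner(mean=mean, sd=sd, cuts=tuple(float(c) for c in cuts))


def bin_values(binner: DiscriminantBinner, values) -> np.ndarray:
    """16 counts for one gene's site discriminants; counts sum to len(values).

    Bin 0 counts values below mean - 2 sd, bin 15 values above mean + 2 sd.
    Interior bin i covers (cut_{i-1}, cut_i] (half-open, closed upper edge,
    so a value exactly at a cut point goes to the lower-indexed bin); the
    first interior bin is bounded below by the lower extreme threshold.
    Unseen values above the last cut but within the extreme thresholds fall
    in the last interior bin.
    """
    counts = np.zeros(N_BINS, dtype=int)
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return counts
    if binner.degenerate:
        counts[1] = v.size
        return counts
    lower = v < binner.lower_threshold
    upper = v > binner.upper_threshold
    counts[0] = int(lower.sum())
    counts[N_BINS - 1] = int(upper.sum())
    mid = v[~lower & ~upper]
    if mid.size:
        idx = np.searchsorted(np.asarray(binner.cuts), mid, side="left")
        idx = np.minimum(idx, len(BIN_PERCENTILES) - 1)
        np.add.at(counts, 1 + idx, 1)
    return counts


def compute_mrna_features(
    seed_starts: Sequence[int],
    discriminants: Sequence[float],
    utr_length: int,
    binner: DiscriminantBinner,
) -> Dict[str, float]:
    """Raw mRNA-level feature values for one (transcript, miRNA) pair.

    ``seed_starts`` are the resolved sites' 1-based seed starts;
    ``discriminants`` their site-level discriminant values (held-out fold
    values during training, final-model values at prediction time).  Genes
    with zero sites are not representable and raise.
    """
    n_sites = len(seed_starts)
    if n_sites == 0:
        raise ValueError("a gene with zero sites has no mRNA-level features")
    if len(discriminants) != n_sites:
        raise ValueError("one discriminant per site is required")
    counts = bin_values(binner, discriminants)
    starts = np.asarray(seed_starts, dtype=float)
    if n_sites >= 2:
        dists = np.abs(starts[:, None] - starts[None, :])[
            np.triu_indices(n_sites, k=1)
        ]
        lo, hi = SYNERGY_DISTANCE
        pairs_in_window = int(((dists >= lo) & (dists <= hi)).sum())
        min_dist = float(dists.min())
    else:
        pairs_in_window = 0
        min_dist = float(MIN_DIST_CAP)
    values = {name: float(counts[i]) for i, name in enumerate(BIN_FEATURES)}
    values.update(
        {
            "n_sites": float(n_sites),
            "utr_length_log": log10(1.0 + utr_length),
            "site_density": n_sites / utr_length,
            "few_sites_flag": 1.0 if n_sites < FEW_SITES_THRESHOLD else 0.0,
            "pairs_17_35": float(pairs_in_window),
            "min_pair_dist_log": log10(1.0 + min(min_dist, MIN_DIST_CAP)),
            "max_discriminant": float(np.max(discriminants)),
        }
    )
    return values


def select_training_genes(
    gene_table: pd.DataFrame,
    seed: int = 0,
    negative_cap: int = 4000,
    n_high_site_negatives: int = 1000,
    high_site_threshold: int = FEW_SITES_THRESHOLD,
) -> pd.DataFrame:
    """Select the gene-level training set from scanned, labelled genes.

    ``gene_table`` needs columns ``label`` ("down_regulated"/"unaffected")
    and ``n_sites``; rows with zero sites are ignored.  Positives are all
    down-regulated genes with at least one site.  Negatives are sampled in
    two pools: unaffected genes with 1..high_site_threshold sites, up to
    ``negative_cap``; plus exactly ``min(n_high_site_negatives, available)``
    unaffected genes with more than ``high_site_threshold`` sites — added
    explicitly because random sampling would underrepresent genes with long
    UTRs and many candidate sites.  Sampling is reproducible from ``seed``.
    """
    eligible = gene_table[gene_table["n_sites"] >= 1]
    positives = eligible[eligible["label"] == "down_regulated"]
    if len(positives) == 0:
        raise ValueError("no positive (down-regulated) genes with target sites")
    negatives = eligible[eligible["label"] == "unaffected"]
    low = negatives[negatives["n_sites"] <= high_site_threshold]
    high = negatives[negatives["n_sites"] > high_site_threshold]
    rng = np.random.default_rng(seed)
    if len(low) > negative_cap:
        keep = rng.choice(len(low), size=negative_cap, replace=False)
        low = low.iloc[np.sort(keep)]
    if len(high) > n_high_site_negatives:
        keep = rng.choice(len(high), size=n_high_site_negatives, replace=False)
        high = high.iloc[np.sort(keep)]
    selected = pd.concat([positives, low, high])
    return selected.sort_index()


def assemble_training_set(
    gene_table: pd.DataFrame,
    features: pd.DataFrame,
    seed: int = 0,
    negative_cap: int = 4000,
    n_high_site_negatives: int = 1000,
) -> tuple:
    """Labelled mRNA-level training matrix.

    ``features`` is the raw mRNA feature table aligned with ``gene_table``
    (same index).  Returns ``(X, y, selected_gene_table)`` with y = 1 for
    down-regulated genes.
    """
    selected = select_training_genes(
        gene_table,
        seed=seed,
        negative_cap=negative_cap,
        n_high_site_negatives=n_high_site_negatives,
    )
    X = features.loc[selected.index]
    y = (selected["label"] == "down_regulated").to_numpy(dtype=int)
    return X, y, selected
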