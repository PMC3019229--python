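"""Site-level feature construction and [-1, 1] min/max normalization.

The feature vector covers the site-level determinants of miRNA targeting:
the seed-type identity (one-hot), 3' supplementary pairing (duplex alignment
score, overall and restricted to miRNA positions 13-16), the AU-rich local
context 30 nt up- and downstream of the seed match, positional features
(distance from the stop codon, distance to the nearest UTR end, relative
position), UTR length with the >2000 nt flag, and base composition of the
seed match and site region.  Distances and lengths are log-scaled as
log10(1 + x) to bound their dynamic range before normalization.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log10
from typing import Dict, Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd

from .duplex import align_duplex
from .seeds import SEED_TYPES, TargetSite

__all__ = [
    "SITE_FEATURE_NAMES",
    "SITE_SCHEMA_VERSION",
    "compute_site_features",
    "Normalizer",
    "fit_normalizer",
    "apply_normalizer",
]

SITE_SCHEMA_VERSION = "site-features-1"

CONTEXT_WINDOW = 30  # nt of flanking sequence for the AU-context features
LONG_UTR_THRESHOLD = 2000

SEED_TYPE_FEATURES = [f"seed_type_{t}" for t in SEED_TYPES]

SITE_FEATURE_NAMES: List[str] = SEED_TYPE_FEATURES + [
    "duplex_total_score",
    "duplex_score_13_16",
    "au_fraction_upstream",
    "au_fraction_downstream",
    "dist_from_stop_log",
    "dist_to_utr_end_log",
    "relative_position",
    "utr_length_log",
    "long_utr_flag",
    "seed_au_fraction",
    "site_gc_fraction",
]


def _fraction(seq: str, bases: str) -> float:
    """Fraction of ``bases`` in ``seq``; 0.0 for an empty window (boundary
    truncation is defined behaviour, not an error)."""
    if not seq:
        return 0.0
    return sum(seq.count(b) for b in bases) / len(seq)


def _log1p10(x: float) -> float:
    return log10(1.0 + x)


def compute_site_features(site: TargetSite, transcript, mirna=None) -> Dict[str, float]:
    """Raw (un-normalized) feature values for one target site.

    The duplex alignment is taken from ``site.duplex`` when present,
    otherwise computed from ``mirna``.  Flanking windows are truncated at
    the UTR boundaries.
    """
    duplex = site.duplex
    if duplex is None:
        if mirna is None:
            raise ValueError("site has no duplex alignment and no miRNA was given")
        duplex = align_duplex(mirna, site, transcript)

    utr = transcript.utr
    L = len(utr)
    ss0 = site.seed_start - 1  # 0-based
    upstream = utr[max(0, ss0 - CONTEXT_WINDOW) : ss0]
    downstream = utr[site.seed_end : site.seed_end + CONTEXT_WINDOW]
    seed_seq = utr[ss0 : site.seed_end]

    values: Dict[str, float] = {
        name: 1.0 if name == f"seed_type_{site.seed_type}" else 0.0
        for name in SEED_TYPE_FEATURES
    }
    values.update(
        {
            "duplex_total_score": duplex.total_score,
            "duplex_score_13_16": duplex.score_13_16,
            "au_fraction_upstream": _fraction(upstream, "AU"),
            "au_fraction_downstream": _fraction(downstream, "AU"),
            "dist_from_stop_log": _log1p10(site.seed_start),
            "dist_to_utr_end_log": _log1p10(min(site.seed_start - 1, L - site.seed_end)),
            "relative_position": site.seed_start / L,
            "utr_length_log": _log1p10(L),
            "long_utr_flag": 1.0 if L > LONG_UTR_THRESHOLD else 0.0,
            "seed_au_fraction": _fraction(seed_seq, "AU"),
            "site_gc_fraction": _fraction(site.site_region, "GC"),
        }
    )
    return values


@dataclass(frozen=True)
class Normalizer:
    """Per-feature affine map onto [-1, 1] fitted on training data.

    ``v' = 2 (v - min) / (max - min) - 1``; features that are constant on
    the training set map to 0, and out-of-range values seen at prediction
    time are clamped to [-1, 1].
    """

    feature_names: tuple
    mins: np.ndarray
    maxs: np.ndarray

    def transform(self, table: pd.DataFrame) -> pd.DataFrame:
        if tuple(table.columns) != self.feature_names:
            raise ValueError(
                "feature schema mismatch: expected "
                f"{list(self.feature_names)}, got {list(table.columns)}"
            )
        values = table.to_numpy(dtype=float)
        span = self.maxs - self.mins
        degenerate = span == 0
        safe_span = np.where(degenerate, 1.0, span)
        out = 2.0 * (values - self.mins) / safe_span - 1.0
        out = np.clip(out, -1.0, 1.0)
        out[:, degenerate] = 0.0
        return pd.DataFrame(out, columns=table.columns, index=table.index)

    def to_dict(self) -> dict:
        return {
            "feature_names": list(self.feature_names),
            "mins": self.mins.tolist(),
            "maxs": self.maxs.tolist(),
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "Normalizer":
        return cls(
            feature_names=tuple(d["feature_names"]),
            mins=np.asarray(d["mins"], dtype=float),
            maxs=np.asarray(d["maxs"], dtype=float),
        )


def fit_normalizer(table: pd.DataFrame) -> Normalizer:
    """Fit per-feature min/max on the training feature table (>= 2 rows)."""
    if len(table) < 2:
        raise ValueError("normalizer requires at least two training vectors")
    values = table.to_numpy(dtype=float)
    return Normalizer(
        feature_names=tuple(table.columns),
        mins=values.min(axis=0),
        maxs=values.max(axis=0),
    )


def apply_normalizer(norm: Normalizer, table: pd.DataFrame) -> pd.DataFrame:
    """Functional alias for :meth:`Normalizer.transform`."""
    return norm.transform(table)


def site_feature_table(
    sites: Iterable[TargetSite],
    transcripts: Mapping[str, object],
    mirnas: Mapping[str, object],
) -> pd.DataFrame:
    """Raw feature table (one row per site, columns in fixed schema order)."""
    rows = [
        compute_site_features(s, transcripts[s.transcript_id], mirnas[s.mirna_id])
        for s in sites
    ]
    return pd.DataFrame(rows, columns=SITE_FEATURE_NAMES)
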