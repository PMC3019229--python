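"""Gene-level linear SVM producing the final target-gene scores.

The mRNA-level classifier separates down-regulated genes from unaffected
ones using the discriminant-distribution and site-spacing features.  A
linear kernel with default cost factor (C = 1) performs best at this level;
the gene score is the raw decision value — ROC-based evaluation needs only
the ranking, so no probability calibration is applied.  A fitted mRNA model
is bound to the exact site model that generated its training discriminants
and refuses to score genes prepared with a different one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .mrna_features import DiscriminantBinner
from .site_features import Normalizer
from .site_svm import DEFAULT_MRNA_KERNEL, KernelSpec, _check_two_classes

__all__ = ["MRNAModel", "train_mrna_model", "score_genes"]


@dataclass
class MRNAModel:
    """Fitted gene-level classifier with its normalizer, binner and the id
    of the site model whose discriminants it was trained on."""

    svc: SVC
    kernel: KernelSpec
    normalizer: Normalizer
    binner: DiscriminantBinner
    feature_names: tuple
    site_model_id: str
    schema_version: str


def train_mrna_model(
    features: pd.DataFrame,
    labels,
    normalizer: Normalizer,
    binner: DiscriminantBinner,
    site_model_id: str,
    spec: KernelSpec = DEFAULT_MRNA_KERNEL,
    seed: int = 0,
    schema_version: str = "mrna-svm/1",
) -> MRNAModel:
    """Fit the linear gene-level SVM on normalized mRNA features.

    Deterministic given the data; ``seed`` is accepted for interface
    symmetry.  ``labels`` are 0/1 with 1 = down-regulated.
    """
    y = np.asarray(labels)
    _check_two_classes(y)
    svc = spec.make_svc()
    svc.fit(features.to_numpy(dtype=float), y)
    return MRNAModel(
        svc=svc,
        kernel=spec,
        normalizer=normalizer,
        binner=binner,
        feature_names=tuple(features.columns),
        site_model_id=site_model_id,
        schema_version=schema_version,
    )


def score_genes(model: MRNAModel, features: pd.DataFrame) -> np.ndarray:
    """Gene scores (decision values) for a normalized mRNA feature table."""
    if tuple(features.columns) != model.feature_names:
        raise ValueError(
            "mRNA feature schema mismatch: model expects "
            f"{list(model.feature_names)}, got {list(features.columns)}"
        )
    return model.svc.decision_function(features.to_numpy(dtype=float))
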