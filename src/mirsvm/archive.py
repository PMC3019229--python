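"""Persist a two-step model as a single versioned archive file.

The archive is a joblib dump holding both SVM stages, their normalizers,
the discriminant binner, the feature schemas, and — when only the site
stage has been trained — the cross-validation state the mRNA stage needs.
"""

from __future__ import annotations

from typing import Optional

import joblib
import pandas as pd

from .pipeline import SiteStage, TwoStepModel

__all__ = ["FORMAT_VERSION", "save_model", "load_model", "save_site_stage", "load_site_stage"]

FORMAT_VERSION = 1
_MAGIC = "mirsvm-model"


def save_model(model: TwoStepModel, path, site_stage: Optional[SiteStage] = None) -> None:
    payload = {
        "magic": _MAGIC,
        "format_version": FORMAT_VERSION,
        "site": model.site,
        "mrna": model.mrna,
        "site_stage": site_stage,
    }
    joblib.dump(payload, path, compress=0)


def _load_payload(path) -> dict:
    payload = joblib.load(path)
    if not isinstance(payload, dict) or payload.get("magic") != _MAGIC:
        raise ValueError(f"{path} is not a model archive")
    if payload.get("format_version") != FORMAT_VERSION:
        raise ValueError(
            f"unsupported archive format version {payload.get('format_version')!r}"
        )
    return payload


def load_model(path) -> TwoStepModel:
    payload = _load_payload(path)
    return TwoStepModel(site=payload["site"], mrna=payload["mrna"])


def save_site_stage(stage: SiteStage, path) -> None:
    """Persist a site-only archive (mRNA stage trained later)."""
    save_model(TwoStepModel(site=stage.model, mrna=None), path, site_stage=stage)


def load_site_stage(path) -> SiteStage:
    payload = _load_payload(path)
    stage = payload.get("site_stage")
    if stage is None:
        raise ValueError(f"{path} carries no site-stage training state")
    return stage
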