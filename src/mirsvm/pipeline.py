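"""End-to-end orchestration: scan -> site stage -> mRNA stage -> predictions.

Training proceeds in two stages.  The site stage scans every labelled
(transcript, miRNA) pair, selects the gene-level training set (all positives
plus capped negative samples), builds and normalizes site features for the
selected genes' sites, and fits the site-level SVM; per-site discriminants
come from stratified 10-fold cross-validation so that no discriminant was
produced by a model trained on its own site.  The mRNA stage fits the
discriminant binner on those held-out discriminants, builds gene-level
features, and fits the linear gene-level SVM.

At prediction time candidate genes are scanned and their sites scored with
the final site model; genes with zero candidate sites are not scored and
are reported separately.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .evaluation import EvalResult, roc_curve_auc
from .io import DOWN_REGULATED, LabelRecord, MicroRNA, Transcript
from .mrna_features import (
    MRNA_FEATURE_NAMES,
    MRNA_SCHEMA_VERSION,
    DiscriminantBinner,
    compute_mrna_features,
    fit_binner,
    select_training_genes,
)
from .mrna_svm import MRNAModel, score_genes, train_mrna_model
from .seeds import TargetSite, resolve_overlaps, scan_candidate_sites
from .site_features import (
    SITE_FEATURE_NAMES,
    SITE_SCHEMA_VERSION,
    Normalizer,
    fit_normalizer,
    site_feature_table,
)
from .site_svm import (
    DEFAULT_MRNA_KERNEL,
    DEFAULT_SITE_KERNEL,
    CrossvalResult,
    KernelSpec,
    SiteModel,
    crossval_discriminants,
    score_sites,
    train_site_model,
)

__all__ = [
    "TwoStepModel",
    "SiteStage",
    "TrainResult",
    "scan_pairs",
    "train_site_stage",
    "train_mrna_stage",
    "train_two_step",
    "predict_two_step",
]


@dataclass
class TwoStepModel:
    """The complete two-stage predictor."""

    site: SiteModel
    mrna: Optional[MRNAModel] = None


@dataclass
class SiteStage:
    """Trained site stage plus the state the mRNA stage needs."""

    model: SiteModel
    site_meta: pd.DataFrame  # per training site: ids, coords, label, CV discriminant, fold
    gene_table: pd.DataFrame  # selected training genes: ids, label, n_sites, utr_length
    eval: EvalResult


@dataclass
class TrainResult:
    model: TwoStepModel
    site_stage: SiteStage
    mrna_eval: EvalResult
    #: AUC of ranking genes by their best single-site CV discriminant — the
    #: site-level baseline the mRNA model should improve on.
    baseline_auc: float
    mrna_gene_table: pd.DataFrame


def _index_by_id(items) -> dict:
    return {x.id: x for x in items}


def scan_pairs(
    mirnas: Mapping[str, MicroRNA],
    transcripts: Mapping[str, Transcript],
    pairs: Iterable[Tuple[str, str]],
) -> Tuple[List[TargetSite], pd.DataFrame]:
    """Scan and overlap-resolve each (transcript_id, mirna_id) pair.

    Returns the flat resolved site list and a per-pair summary table with
    the candidate site count (zero-site pairs included).
    """
    sites: List[TargetSite] = []
    rows = []
    for tid, mid in pairs:
        resolved = resolve_overlaps(
            scan_candidate_sites(mirnas[mid], transcripts[tid])
        )
        sites.extend(resolved)
        rows.append(
            {
                "transcript_id": tid,
                "mirna_id": mid,
                "n_sites": len(resolved),
                "utr_length": transcripts[tid].length,
            }
        )
    return sites, pd.DataFrame(rows)


def _labels_frame(labels: Sequence[LabelRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(l.transcript_id, l.mirna_id, l.label) for l in labels],
        columns=["transcript_id", "mirna_id", "label"],
    )


def train_site_stage(
    mirnas: Sequence[MicroRNA],
    transcripts: Sequence[Transcript],
    labels: Sequence[LabelRecord],
    kernel: KernelSpec = DEFAULT_SITE_KERNEL,
    k: int = 10,
    seed: int = 0,
    negative_cap: int = 4000,
    n_high_site_negatives: int = 1000,
) -> SiteStage:
    """Scan labelled pairs, select training genes, and train the site SVM."""
    mirna_map = _index_by_id(mirnas)
    transcript_map = _index_by_id(transcripts)
    label_df = _labels_frame(labels)

    pair_list = list(zip(label_df["transcript_id"], label_df["mirna_id"]))
    all_sites, pair_table = scan_pairs(mirna_map, transcript_map, pair_list)
    gene_table = pair_table.merge(label_df, on=["transcript_id", "mirna_id"])

    selected = select_training_genes(
        gene_table,
        seed=seed,
        negative_cap=negative_cap,
        n_high_site_negatives=n_high_site_negatives,
    )
    selected_pairs = set(zip(selected["transcript_id"], selected["mirna_id"]))
    train_sites = [
        s for s in all_sites if (s.transcript_id, s.mirna_id) in selected_pairs
    ]
    pair_label = dict(
        zip(zip(label_df["transcript_id"], label_df["mirna_id"]), label_df["label"])
    )
    y_site = np.array(
        [
            1 if pair_label[(s.transcript_id, s.mirna_id)] == DOWN_REGULATED else 0
            for s in train_sites
        ],
        dtype=int,
    )

    X_raw = site_feature_table(train_sites, transcript_map, mirna_map)
    normalizer = fit_normalizer(X_raw)
    X_norm = normalizer.transform(X_raw)

    cv = crossval_discriminants(X_norm, y_site, kernel, k=k, seed=seed)
    model = train_site_model(
        X_norm,
        y_site,
        kernel,
        seed=seed,
        normalizer=normalizer,
        schema_version=SITE_SCHEMA_VERSION,
    )

    site_meta = pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in train_sites],
            "mirna_id": [s.mirna_id for s in train_sites],
            "seed_type": [s.seed_type for s in train_sites],
            "seed_start": [s.seed_start for s in train_sites],
            "seed_end": [s.seed_end for s in train_sites],
            "label": y_site,
            "cv_discriminant": cv.discriminants,
            "fold": cv.fold_assignment,
        }
    )
    return SiteStage(
        model=model,
        site_meta=site_meta,
        gene_table=selected.reset_index(drop=True),
        eval=cv.eval,
    )


def _gene_feature_table(
    site_meta: pd.DataFrame,
    gene_table: pd.DataFrame,
    binner: DiscriminantBinner,
    discriminant_column: str,
) -> pd.DataFrame:
    """One raw mRNA feature row per gene in gene_table (>= 1 site each)."""
    grouped = {
        key: grp
        for key, grp in site_meta.groupby(["transcript_id", "mirna_id"], sort=False)
    }
    rows = []
    for row in gene_table.itertuples(index=False):
        grp = grouped[(row.transcript_id, row.mirna_id)]
        rows.append(
            compute_mrna_features(
                grp["seed_start"].tolist(),
                grp[discriminant_column].tolist(),
                int(row.utr_length),
                binner,
            )
        )
    return pd.DataFrame(rows, columns=MRNA_FEATURE_NAMES, index=gene_table.index)


def train_mrna_stage(
    stage: SiteStage,
    spec: KernelSpec = DEFAULT_MRNA_KERNEL,
    k: int = 10,
    seed: int = 0,
) -> TrainResult:
    """Fit the binner and the gene-level linear SVM on the site stage output."""
    binner = fit_binner(stage.site_meta["cv_discriminant"].to_numpy())

    gene_table = stage.gene_table[stage.gene_table["n_sites"] >= 1].reset_index(drop=True)
    X_raw = _gene_feature_table(stage.site_meta, gene_table, binner, "cv_discriminant")
    y = (gene_table["label"] == DOWN_REGULATED).to_numpy(dtype=int)

    normalizer = fit_normalizer(X_raw)
    X_norm = normalizer.transform(X_raw)

    # Gene-level cross-validation for evaluation.
    n = len(y)
    disc = np.empty(n, dtype=float)
    fold_aucs = []
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    Xv = X_norm.to_numpy(dtype=float)
    for train_idx, test_idx in skf.split(Xv, y):
        svc = spec.make_svc()
        svc.fit(Xv[train_idx], y[train_idx])
        d = svc.decision_function(Xv[test_idx])
        disc[test_idx] = d
        fold_aucs.append(roc_curve_auc(d, y[test_idx]).auc)
    mrna_eval = roc_curve_auc(disc, y)
    mrna_eval.fold_aucs = np.asarray(fold_aucs)

    baseline_auc = roc_curve_auc(X_raw["max_discriminant"].to_numpy(), y).auc

    mrna_model = train_mrna_model(
        X_norm,
        y,
        normalizer=normalizer,
        binner=binner,
        site_model_id=stage.model.model_id,
        spec=spec,
        seed=seed,
        schema_version=MRNA_SCHEMA_VERSION,
    )
    gene_table = gene_table.assign(gene_cv_score=disc)
    return TrainResult(
        model=TwoStepModel(site=stage.model, mrna=mrna_model),
        site_stage=stage,
        mrna_eval=mrna_eval,
        baseline_auc=baseline_auc,
        mrna_gene_table=gene_table,
    )


def train_two_step(
    mirnas: Sequence[MicroRNA],
    transcripts: Sequence[Transcript],
    labels: Sequence[LabelRecord],
    site_kernel: KernelSpec = DEFAULT_SITE_KERNEL,
    mrna_kernel: KernelSpec = DEFAULT_MRNA_KERNEL,
    k: int = 10,
    seed: int = 0,
    negative_cap: int = 4000,
    n_high_site_negatives: int = 1000,
) -> TrainResult:
    """Train both stages; see :func:`train_site_stage` / :func:`train_mrna_stage`."""
    stage = train_site_stage(
        mirnas,
        transcripts,
        labels,
        kernel=site_kernel,
        k=k,
        seed=seed,
        negative_cap=negative_cap,
        n_high_site_negatives=n_high_site_negatives,
    )
    return train_mrna_stage(stage, spec=mrna_kernel, k=k, seed=seed)


def predict_two_step(
    model: TwoStepModel,
    mirnas: Sequence[MicroRNA],
    transcripts: Sequence[Transcript],
    pairs: Optional[Iterable[Tuple[str, str]]] = None,
) -> Tuple[pd.DataFrame, pd.DataFrame, List[Tuple[str, str]]]:
    """Score (transcript, miRNA) pairs with the trained two-step model.

    Returns ``(site_table, gene_table, no_site_pairs)``.  The site table has
    one row per resolved site with its discriminant; the gene table one row
    per pair with at least one site.  Zero-site pairs are never scored and
    are returned separately.  Raises when the mRNA stage was trained on a
    different site model than the one provided.
    """
    if model.mrna is None:
        raise ValueError("model has no mRNA stage; train it or use score_sites")
    if model.mrna.site_model_id != model.site.model_id:
        raise ValueError(
            "mRNA stage was trained on a different site model "
            f"({model.mrna.site_model_id} != {model.site.model_id})"
        )
    mirna_map = _index_by_id(mirnas)
    transcript_map = _index_by_id(transcripts)
    if pairs is None:
        pairs = [(t.id, m.id) for t in transcripts for m in mirnas]
    pairs = list(pairs)

    sites, pair_table = scan_pairs(mirna_map, transcript_map, pairs)
    no_site_pairs = [
        (row.transcript_id, row.mirna_id)
        for row in pair_table.itertuples(index=False)
        if row.n_sites == 0
    ]
    if not sites:
        empty_sites = pd.DataFrame(
            columns=[
                "transcript_id", "mirna_id", "seed_type",
                "seed_start", "seed_end", "discriminant",
            ]
        )
        empty_genes = pd.DataFrame(
            columns=["transcript_id", "mirna_id", "n_sites", "gene_score"]
        )
        return empty_sites, empty_genes, no_site_pairs

    X_raw = site_feature_table(sites, transcript_map, mirna_map)
    X_norm = model.site.normalizer.transform(X_raw)
    disc = score_sites(model.site, X_norm)

    site_table = pd.DataFrame(
        {
            "transcript_id": [s.transcript_id for s in sites],
            "mirna_id": [s.mirna_id for s in sites],
            "seed_type": [s.seed_type for s in sites],
            "seed_start": [s.seed_start for s in sites],
            "seed_end": [s.seed_end for s in sites],
            "discriminant": disc,
        }
    )
    gene_rows = pair_table[pair_table["n_sites"] >= 1].reset_index(drop=True)
    X_gene_raw = _gene_feature_table(
        site_table.assign(cv_discriminant=site_table["discriminant"]),
        gene_rows,
        model.mrna.binner,
        "cv_discriminant",
    )
    X_gene = model.mrna.normalizer.transform(X_gene_raw)
    gene_scores = score_genes(model.mrna, X_gene)
    gene_table = pd.DataFrame(
        {
            "transcript_id": gene_rows["transcript_id"],
            "mirna_id": gene_rows["mirna_id"],
            "n_sites": gene_rows["n_sites"],
            "gene_score": gene_scores,
        }
    )
    return site_table, gene_table, no_site_pairs
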