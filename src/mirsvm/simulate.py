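"""Synthetic miRNA/UTR/label datasets with known planted structure.

Real training data for miRNA target prediction comes from transfection
microarrays: a miRNA or siRNA is over-expressed and genes are labelled
down-regulated or unaffected from the expression change.  This module
emulates such datasets at desk scale so every pipeline stage is testable
without downloads: random UTRs receive planted seed-match sites with known
types and positions, a latent repression score is computed from a known
mechanism, and labels are thresholded latent scores with optional noise.

The latent mechanism sums per-site seed-type strengths plus bonuses for
AU-rich site context and for site pairs spaced 17-35 nt apart (cooperative
spacing), so both the site-level determinants and the mRNA-level
multiplicity/spacing features carry real signal.  The ground-truth manifest
records every planted site and latent score.

``plant_site`` is the constructive inverse of the scanner's window
classification: it writes a target window that classifies exactly as the
requested seed type.  The written patch includes the minimal guard bases
without which the type at that anchor would be ambiguous (the base opposite
miRNA position 1, and — for 6-nt windows — the base opposite position 8).
Each plant is verified by re-classification, and each transcript by a full
scan round trip with rejection sampling of the background sequence.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .io import (
    DOWN_REGULATED,
    UNAFFECTED,
    LabelRecord,
    MicroRNA,
    Transcript,
    write_fasta,
    write_label_table,
)
from .seeds import (
    MIN_SEED_START,
    SEED_TYPES,
    _site_from_anchor,
    classify_anchor,
    resolve_overlaps,
    reverse_complement,
    scan_candidate_sites,
)
from .site_features import CONTEXT_WINDOW

__all__ = ["SyntheticConfig", "SyntheticDataset", "plant_site", "generate_dataset", "write_dataset"]

logger = logging.getLogger(__name__)

_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}

#: Relative repression strength of each seed type in the latent mechanism
#: (stringent types strongest, defective matches weakest).
DEFAULT_TYPE_STRENGTH = {
    "8mer": 4.0,
    "7mer-A1": 3.0,
    "7mer-m8": 3.0,
    "6mer": 1.5,
    "GUM": 1.0,
    "GUT": 0.9,
    "LP": 0.7,
    "BM": 0.6,
    "BT": 0.5,
}

#: Seed-type sampling weights for high-efficacy genes (stringent-heavy) and
#: low-efficacy genes (defective-match-heavy); a targeted gene's efficacy
#: interpolates between the two, so site quality is correlated within a gene
#: the way functional target sites cluster on real targets.
DEFAULT_TYPE_WEIGHTS_STRONG = {
    "8mer": 0.44,
    "7mer-A1": 0.22,
    "7mer-m8": 0.22,
    "6mer": 0.02,
    "GUM": 0.02,
    "GUT": 0.02,
    "LP": 0.02,
    "BM": 0.02,
    "BT": 0.02,
}
DEFAULT_TYPE_WEIGHTS_WEAK = {
    "8mer": 0.02,
    "7mer-A1": 0.03,
    "7mer-m8": 0.03,
    "6mer": 0.14,
    "GUM": 0.20,
    "GUT": 0.18,
    "LP": 0.16,
    "BM": 0.13,
    "BT": 0.11,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic transfection-style dataset."""

    n_mirnas: int = 5
    n_transcripts: int = 2000
    mirna_length: int = 22
    #: 3' UTR lengths are log-normal (median ~250 nt at these defaults),
    #: clipped to [utr_min, utr_max].
    utr_log_mean: float = math.log(200.0)
    utr_log_sigma: float = 0.5
    utr_min: int = 60
    utr_max: int = 3000
    #: Background A+U fraction; 0.5 = uniform base composition.
    au_fraction: float = 0.5
    #: Probability that a transcript is targeted by (exactly one) miRNA.
    p_target: float = 0.35
    #: Planted site count for a targeted transcript is
    #: 1 + Binomial(n_sites_max - 1, p) with p interpolated between
    #: p_sites_min and p_sites_max by efficacy: functional targets carry
    #: several sites, marginal targets mostly one or two.
    n_sites_max: int = 5
    p_sites_min: float = 0.05
    p_sites_max: float = 0.9
    #: Probability that a consecutive planted site pair is placed at a
    #: cooperative 17-35 nt seed-start spacing.
    p_synergy_pair: float = 0.35
    #: A planted site receives 3' supplementary pairing (a flank
    #: complementary to miRNA positions 13-16) with probability
    #: p_supplementary_min + (max - min) * efficacy.
    p_supplementary_min: float = 0.05
    p_supplementary_max: float = 0.95
    type_weights_strong: tuple = tuple(DEFAULT_TYPE_WEIGHTS_STRONG.items())
    type_weights_weak: tuple = tuple(DEFAULT_TYPE_WEIGHTS_WEAK.items())
    type_strength: tuple = tuple(DEFAULT_TYPE_STRENGTH.items())
    #: Latent-score weight of one cooperative site pair.
    w_pairs: float = 0.6
    #: Latent-score weight of the mean AU context of the planted sites.
    w_au: float = 1.0
    #: A+U fraction used to enrich the context around planted sites of
    #: AU-rich genes (functional sites sit in AU-rich context); a gene is
    #: AU-rich with probability equal to its efficacy.
    au_rich_level: float = 0.85
    #: Latent-score weight of 3' supplementary pairing, per site (added to
    #: the site's quality term).
    w_supplementary: float = 2.0
    #: Beta(a, a) shape of the gene-efficacy distribution; a < 1 makes
    #: efficacy bimodal (targets are mostly clearly functional or clearly
    #: non-functional, with few borderline genes).
    efficacy_beta: float = 0.2
    #: Latent-score weight of each site beyond the first.
    w_count: float = 0.6
    #: Fraction of targeted (planted) pairs labelled down-regulated;
    #: matches the mass of the high-efficacy mode so the label threshold
    #: falls in the trough between functional and non-functional targets.
    positive_fraction: float = 0.5
    #: Probability that a label is flipped.
    label_noise: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.label_noise < 0.5:
            raise ValueError("label_noise must be in [0, 0.5)")
        for _, w in tuple(self.type_weights_strong) + tuple(self.type_weights_weak):
            if w < 0:
                raise ValueError("type weights must be >= 0")

    @property
    def type_weights(self) -> dict:
        """Marginal seed-type sampling weights (efficacy is uniform, so the
        marginal is the mean of the strong and weak weight vectors)."""
        strong, weak = dict(self.type_weights_strong), dict(self.type_weights_weak)
        return {t: (strong[t] + weak[t]) / 2.0 for t in strong}


@dataclass
class SyntheticDataset:
    """Generated sequences, labels and ground truth."""

    mirnas: List[MicroRNA]
    transcripts: List[Transcript]
    labels: List[LabelRecord]
    #: One row per planted site: transcript_id, mirna_id, seed_type,
    #: seed_start, seed_end.
    manifest: pd.DataFrame
    #: One row per labelled pair: latent score and pre-noise label.
    genes_truth: pd.DataFrame
    config: SyntheticConfig


def _random_sequence(rng, length: int, au_fraction: float) -> str:
    p = np.array([au_fraction / 2, (1 - au_fraction) / 2, (1 - au_fraction) / 2, au_fraction / 2])
    return "".join(rng.choice(np.array(list("ACGU")), size=length, p=p))


def _random_mirna(rng, length: int, mirna_id: str) -> MicroRNA:
    # Require a U and a G in the seed region so every seed type is plantable.
    while True:
        seq = _random_sequence(rng, length, 0.5)
        seed28 = seq[1:8]
        if "U" in seed28 and "G" in seed28:
            return MicroRNA(id=mirna_id, sequence=seq)


def _non_a(rng) -> str:
    return str(rng.choice(np.array(list("CGU"))))


def _patch(utr: str, start0: int, text: str) -> str:
    return utr[:start0] + text + utr[start0 + len(text) :]


def _window_variants(mirna: MicroRNA, seed_type: str, rng) -> List[Tuple[str, Optional[str], bool]]:
    """Candidate (window, a1_base, need_guard5p) patches for a seed type.

    ``a1_base`` is the required base 3' of the window (None = leave the
    existing base); ``need_guard5p`` marks 6-nt windows whose 5' neighbour
    (opposite miRNA position 8) must not Watson-Crick pair with position 8.
    """
    seed28 = mirna.sequence[1:8]
    rc28 = reverse_complement(seed28)
    rc27 = reverse_complement(seed28[:6])
    out: List[Tuple[str, Optional[str], bool]] = []
    if seed_type == "8mer":
        out.append((rc28, "A", False))
    elif seed_type == "7mer-m8":
        out.append((rc28, _non_a(rng), False))
    elif seed_type == "7mer-A1":
        out.append((rc27, "A", True))
    elif seed_type == "6mer":
        out.append((rc27, _non_a(rng), True))
    elif seed_type in ("GUM", "GUT"):
        wanted = "U" if seed_type == "GUM" else "G"
        target = "G" if seed_type == "GUM" else "U"
        idxs = [i for i, m in enumerate(seed28) if m == wanted]
        for i in idxs:
            w = list(rc28)
            w[6 - i] = target
            out.append(("".join(w), _non_a(rng), False))
    elif seed_type == "LP":
        for i in range(1, 6):
            m = seed28[i]
            for b in "ACGU":
                if b == _WC_PARTNER[m] or {m, b} == {"G", "U"}:
                    continue
                w = list(rc28)
                w[6 - i] = b
                out.append(("".join(w), _non_a(rng), False))
    elif seed_type == "BM":
        for i in range(1, 6):
            w = reverse_complement(seed28[:i] + seed28[i + 1 :])
            if w != rc27:
                out.append((w, _non_a(rng), True))
    elif seed_type == "BT":
        for k in range(1, 7):
            for b in "ACGU":
                out.append((rc28[:k] + b + rc28[k:], _non_a(rng), False))
    else:
        raise ValueError(f"unknown seed type {seed_type!r}")
    rng.shuffle(out)
    return out


def plant_site(utr: str, mirna: MicroRNA, seed_type: str, position: int, rng=None) -> Tuple[str, int, int]:
    """Write a site of ``seed_type`` with its seed match starting at
    ``position`` (1-based); returns ``(new_utr, seed_start, seed_end)``.

    The patch is verified by re-classification at the anchor; candidate
    windows are tried until one classifies exactly as requested.  Raises
    ``ValueError`` when the type is impossible at that position (boundary,
    or a seed composition without the needed U/G).
    """
    if seed_type not in SEED_TYPES:
        raise ValueError(f"unknown seed type {seed_type!r}")
    if position < MIN_SEED_START:
        raise ValueError(f"seed match may not start before UTR position {MIN_SEED_START}")
    rng = rng if rng is not None else np.random.default_rng(0)
    start0 = position - 1
    needs_a1 = seed_type in ("8mer", "7mer-A1")
    last_error = "no candidate window classified and survived resolution"
    for _attempt in range(3):  # fresh random base draws per attempt
        variants = _window_variants(mirna, seed_type, rng)
        if not variants:
            raise ValueError(f"seed type {seed_type!r} impossible for miRNA {mirna.id}")
        for window, a1_base, guard5p in variants:
            wlen = len(window)
            end0 = start0 + wlen - 1  # anchor (0-based)
            if end0 >= len(utr):
                raise ValueError(f"window does not fit at position {position}")
            if needs_a1 and end0 + 1 >= len(utr):
                raise ValueError(
                    f"{seed_type} requires a base 3' of the window at position {position}"
                )
            new = _patch(utr, start0, window)
            if a1_base is not None and end0 + 1 < len(new):
                new = _patch(new, end0 + 1, a1_base)
            if guard5p and start0 >= 1:
                m8 = mirna.sequence[7]
                if new[start0 - 1] == _WC_PARTNER[m8]:
                    choices = [b for b in "ACGU" if b != _WC_PARTNER[m8]]
                    new = _patch(new, start0 - 1, str(rng.choice(np.array(choices))))
            hit = classify_anchor(mirna, new, end0)
            if hit is None or hit[0] != seed_type or hit[1] != start0:
                last_error = f"window classified as {hit[0] if hit else None}"
                continue
            # The surrounding context (or our own guard bases) can host an
            # overlapping higher-precedence match at a nearby anchor that
            # would mask this site during overlap resolution; verify with a
            # local scan before accepting the patch.
            seed_end = end0 + 1 + (1 if needs_a1 else 0)
            lo = max(MIN_SEED_START + 4, start0 - 3)
            hi = min(len(new) - 1, end0 + 9)
            local = []
            for anchor in range(lo, hi + 1):
                h = classify_anchor(mirna, new, anchor)
                if h is not None:
                    local.append(
                        _site_from_anchor(mirna.id, "_", new, anchor, h[0], h[1])
                    )
            surviving = {
                (s.seed_start, s.seed_type) for s in resolve_overlaps(local)
            }
            if (position, seed_type) in surviving:
                return new, position, seed_end
            last_error = "masked by an overlapping higher-precedence site"
    raise ValueError(
        f"could not plant {seed_type} for miRNA {mirna.id} at position {position}: {last_error}"
    )


def _au_context(utr: str, seed_start: int, seed_end: int) -> float:
    ss0 = seed_start - 1
    up = utr[max(0, ss0 - CONTEXT_WINDOW) : ss0]
    down = utr[seed_end : seed_end + CONTEXT_WINDOW]
    window = up + down
    if not window:
        return 0.0
    return sum(window.count(b) for b in "AU") / len(window)


def _plan_positions(rng, utr_len: int, k: int, p_synergy: float) -> List[int]:
    """Seed-start positions for k sites, some at 17-35 nt spacing; minimum
    separation 17 nt keeps windows and supplementary flanks disjoint; empty
    list when the UTR is too short."""
    lo, hi = MIN_SEED_START, utr_len - 9  # leave room for the window + A1 base
    if hi < lo:
        return []
    positions: List[int] = []
    for _ in range(200):
        if len(positions) == k:
            break
        if positions and rng.random() < p_synergy:
            base = positions[-1]
            cand = base + int(rng.integers(17, 36))
        else:
            cand = int(rng.integers(lo, hi + 1))
        if cand < lo or cand > hi:
            continue
        if all(abs(cand - p) >= 17 for p in positions):
            positions.append(cand)
    return sorted(positions)


def _plant_supplementary(utr: str, mirna: MicroRNA, seed_start: int, seed_type: str) -> str:
    """Make the flank opposite miRNA positions 13-16 perfectly complementary
    (3' supplementary pairing of a functional site)."""
    flank_end0 = seed_start - 1
    if seed_type in ("6mer", "7mer-A1"):  # match pairs positions 2-7 only
        flank_end0 -= 1
    # Base opposite miRNA position p sits at index flank_end0 + 8 - p.
    patch = "".join(_WC_PARTNER[mirna.sequence[p - 1]] for p in (16, 15, 14, 13))
    return _patch(utr, flank_end0 - 8, patch)


def _pairs_in_window(starts: Sequence[int]) -> int:
    n = 0
    for i in range(len(starts)):
        for j in range(i + 1, len(starts)):
            if 17 <= abs(starts[i] - starts[j]) <= 35:
                n += 1
    return n


def generate_dataset(cfg: SyntheticConfig) -> SyntheticDataset:
    """Generate one dataset; byte-identical for identical configs."""
    rng = np.random.default_rng(cfg.seed)
    strong = dict(cfg.type_weights_strong)
    weak = dict(cfg.type_weights_weak)
    type_names = list(strong)
    w_strong = np.array([strong[t] for t in type_names], dtype=float)
    w_weak = np.array([weak[t] for t in type_names], dtype=float)
    w_strong /= w_strong.sum()
    w_weak /= w_weak.sum()
    strength = dict(cfg.type_strength)

    mirnas = [_random_mirna(rng, cfg.mirna_length, f"mir{i+1:02d}") for i in range(cfg.n_mirnas)]

    transcripts: List[Transcript] = []
    manifest_rows: List[dict] = []
    targeted: Dict[str, Tuple[str, List[dict]]] = {}  # transcript -> (mirna, sites)

    lengths = np.clip(
        rng.lognormal(cfg.utr_log_mean, cfg.utr_log_sigma, size=cfg.n_transcripts),
        cfg.utr_min,
        cfg.utr_max,
    ).astype(int)
    is_targeted = rng.random(cfg.n_transcripts) < cfg.p_target
    mirna_choice = rng.integers(0, cfg.n_mirnas, size=cfg.n_transcripts)

    for t in range(cfg.n_transcripts):
        tid = f"tx{t+1:05d}"
        L = int(lengths[t])
        planted: List[dict] = []
        mirna = mirnas[int(mirna_choice[t])]  # the transcript's measured miRNA
        utr = _random_sequence(rng, L, cfg.au_fraction)
        efficacy = 0.0
        if is_targeted[t]:
            # The gene-level efficacy makes site quality correlated within a
            # gene: high-efficacy targets carry stringent, supplementary-
            # paired sites; low-efficacy targets carry defective matches.
            efficacy = float(rng.beta(cfg.efficacy_beta, cfg.efficacy_beta))
            type_p = (1.0 - efficacy) * w_weak + efficacy * w_strong
            type_p /= type_p.sum()
            p_sup = cfg.p_supplementary_min + (
                cfg.p_supplementary_max - cfg.p_supplementary_min
            ) * efficacy
            p_sites = cfg.p_sites_min + (cfg.p_sites_max - cfg.p_sites_min) * efficacy
            n_sites = 1 + int(rng.binomial(cfg.n_sites_max - 1, p_sites))
            au_rich = bool(rng.random() < efficacy)
            # Rejection-sample the background so the scan round trip recovers
            # every planted site (a random context can create an overlapping
            # higher-precedence site that would mask a planted one).
            for attempt in range(5):
                utr_try = utr if attempt == 0 else _random_sequence(rng, L, cfg.au_fraction)
                positions = _plan_positions(rng, L, n_sites, cfg.p_synergy_pair)
                trial: List[dict] = []
                ok = len(positions) > 0
                cur = utr_try
                if au_rich:
                    # Enrich the AU content around every planned site before
                    # planting; the windows themselves are written after.
                    for pos in positions:
                        lo = max(0, pos - 1 - 31)
                        hi = min(L, pos - 1 + 38)
                        cur = _patch(
                            cur, lo, _random_sequence(rng, hi - lo, cfg.au_rich_level)
                        )
                for pos in positions:
                    stype = str(rng.choice(np.array(type_names), p=type_p))
                    supplementary = bool(rng.random() < p_sup)
                    try:
                        cur, ss, se = plant_site(cur, mirna, stype, pos, rng)
                    except ValueError:
                        ok = False
                        break
                    if supplementary:
                        cur = _plant_supplementary(cur, mirna, ss, stype)
                    trial.append(
                        {
                            "transcript_id": tid,
                            "mirna_id": mirna.id,
                            "seed_type": stype,
                            "seed_start": ss,
                            "seed_end": se,
                            "supplementary": int(supplementary),
                        }
                    )
                if not ok:
                    continue
                resolved = resolve_overlaps(
                    scan_candidate_sites(mirna, Transcript(id=tid, utr=cur))
                )
                found = {(s.seed_start, s.seed_type) for s in resolved}
                if all((row["seed_start"], row["seed_type"]) in found for row in trial):
                    utr, planted = cur, trial
                    break
            if not planted:
                logger.info("skipped planting on %s (no feasible placement)", tid)
        transcripts.append(Transcript(id=tid, utr=utr))
        targeted[tid] = (mirna.id, planted, efficacy)
        manifest_rows.extend(planted)

    # Latent repression scores; one measured (transcript, miRNA) pair per
    # transcript, emulating one transfection measurement per gene.  The
    # latent is the mean site quality (seed-type strength + supplementary
    # pairing) plus bonuses for site multiplicity, cooperative spacing and
    # AU context, so both site-level and gene-level determinants matter.
    truth_rows: List[dict] = []
    for tr in transcripts:
        mirna_id, sites, efficacy = targeted[tr.id]
        latent = 0.0
        if sites:
            starts = [s["seed_start"] for s in sites]
            au = float(
                np.mean([_au_context(tr.utr, s["seed_start"], s["seed_end"]) for s in sites])
            )
            qualities = [
                strength[s["seed_type"]] + cfg.w_supplementary * s["supplementary"]
                for s in sites
            ]
            latent = (
                float(np.mean(qualities))
                + cfg.w_count * (len(sites) - 1)
                + cfg.w_pairs * _pairs_in_window(starts)
                + cfg.w_au * au
            )
        truth_rows.append(
            {
                "transcript_id": tr.id,
                "mirna_id": mirna_id,
                "latent": latent,
                "efficacy": efficacy,
            }
        )
    truth = pd.DataFrame(
        truth_rows, columns=["transcript_id", "mirna_id", "latent", "efficacy"]
    )

    planted_latents = truth.loc[truth["latent"] > 0, "latent"]
    if len(planted_latents):
        threshold = float(np.quantile(planted_latents, 1.0 - cfg.positive_fraction))
    else:
        threshold = float("inf")
    truth["label_true"] = np.where(
        truth["latent"] >= threshold, DOWN_REGULATED, UNAFFECTED
    )
    flip = rng.random(len(truth)) < cfg.label_noise
    flipped = np.where(
        truth["label_true"] == DOWN_REGULATED, UNAFFECTED, DOWN_REGULATED
    )
    truth["label"] = np.where(flip, flipped, truth["label_true"])

    labels = [
        LabelRecord(row.transcript_id, row.mirna_id, row.label)
        for row in truth.itertuples(index=False)
    ]
    manifest = pd.DataFrame(
        manifest_rows,
        columns=[
            "transcript_id", "mirna_id", "seed_type",
            "seed_start", "seed_end", "supplementary",
        ],
    )
    return SyntheticDataset(
        mirnas=mirnas,
        transcripts=transcripts,
        labels=labels,
        manifest=manifest,
        genes_truth=truth,
        config=cfg,
    )


def write_dataset(dataset: SyntheticDataset, out_dir) -> dict:
    """Write FASTA files, label table, manifest and ground truth; returns
    the path of each artefact."""
    import os

    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "mirnas": os.path.join(out_dir, "mirnas.fasta"),
        "utrs": os.path.join(out_dir, "utrs.fasta"),
        "labels": os.path.join(out_dir, "labels.tsv"),
        "manifest": os.path.join(out_dir, "manifest.tsv"),
        "genes_truth": os.path.join(out_dir, "genes_truth.tsv"),
    }
    write_fasta(dataset.mirnas, paths["mirnas"])
    write_fasta(dataset.transcripts, paths["utrs"])
    write_label_table(dataset.labels, paths["labels"])
    dataset.manifest.to_csv(paths["manifest"], sep="\t", index=False)
    dataset.genes_truth.to_csv(paths["genes_truth"], sep="\t", index=False)
    return paths
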