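# Methods

## Seed-match model

A candidate site is anchored at the UTR base that pairs miRNA position 2.
At each anchor the 7-, 6- and 8-nt windows ending there are classified
against the seed (miRNA positions 2–8, with positions 2–7 as the 6-mer
core):

| class | window | definition |
|---|---|---|
| 8mer | 7 nt | Watson–Crick (WC) complement of positions 2–8, A opposite position 1 |
| 7mer-A1 | 6 nt | WC complement of 2–7, A opposite position 1 |
| 7mer-m8 | 7 nt | WC complement of 2–8 |
| 6mer | 6 nt | WC complement of 2–7 |
| GUM / GUT | 7 nt | 2–8 with exactly one G:U wobble, U on the miRNA / target |
| LP | 7 nt | 2–8 with exactly one internal 1×1 mismatch loop |
| BM | 6 nt | 2–8 with exactly one internal miRNA base unpaired |
| BT | 8 nt | 2–8 with exactly one internal extra target base |

Only the highest-precedence class at an anchor is reported (an 8mer is not
additionally reported as the 7mer or 6mer it contains).  Defects (loops and
bulges) may not occupy seed-terminal positions: a terminal defect is
indistinguishable from a shorter exact match.  Sites whose match begins in
the first 15 nt after the stop codon are discarded; reported coordinates
are 1-based inclusive and span the full match (the A1 adenosine extends
`seed_end` for 8mer/7mer-A1).  Overlap resolution is greedy by
(precedence rank, seed start, class order); two surviving sites may overlap
only if both are stringent or 6mer.  Classification is implemented by
precomputed pattern sets per miRNA (at most ~50 strings), making a scan a
few set lookups per anchor; the test suite checks exact equivalence with a
naive per-column enumeration on hundreds of random miRNA/UTR pairs.

## 3' supplementary pairing score

miRNA positions 9..min(L, 20) are aligned to the UTR flank immediately 5'
of the seed match (for 6mer/7mer-A1 matches the flank is shifted one base
further 5', since their match only reaches position 7).  The alignment is
a Gotoh dynamic program over *pairing* scores — WC +5, G:U +1, otherwise
−4; a gap of length k costs 10 + 0.5·k; end gaps are free — with
deterministic traceback (diagonal over gap-in-target over gap-in-miRNA).
Free end gaps make a short or empty flank score low or zero rather than
being an error, and keep the score symmetric in its two sequences.  The
13–16 sub-score sums the columns whose miRNA base comes from positions
13–16, the canonical supplementary-pairing region.  These parameters are a
design choice exposed in `mirsvm.duplex`; they reward 3' pairing without
modelling hybridisation thermodynamics.

## Site features and normalization

20 scalars per site: the 9-way seed-type one-hot; duplex total and 13–16
scores; AU fraction in the 30 nt upstream and downstream of the match
(truncated at UTR boundaries; an empty window scores 0); distance from the
stop codon (= seed start) and distance to the nearest UTR end, both
log10(1 + x); relative position (seed start / UTR length); log UTR length
and a binary flag for UTRs over 2000 nt (long UTRs are targeted mostly near
their ends); AU fraction of the match; GC fraction of the 20-nt site
region.  Features are mapped to [−1, 1] by a per-feature min–max affine
transform fitted on training sites only; constant features map to 0 and
out-of-range values at prediction time are clamped.

## Two-stage classification

**Site stage.** Sites inherit their gene's label (positive = site on a
down-regulated gene).  The classifier is a soft-margin SVM with the
homogeneous polynomial kernel K(x, y) = (γ x·y)^d, d = 5, C = 2
("homogeneous" = zero constant term).  γ = 2⁻⁵ by default: with ~20
features in [−1, 1] this keeps kernel values of order one; γ = 1 drives
(x·y)⁵ to ~10⁶, where the fixed C both underfits and slows libsvm by two
orders of magnitude.  Discriminants for training genes come from stratified
10-fold cross-validation, so no discriminant was produced by a model that
saw its own site; folds stratify on the site label and do not group sites
by gene (a `group_by_gene`-style extension would be straightforward but is
not the default).  A kernel/parameter grid search
(C = 2^(2n−5), n = 0..11; γ = 2^(2n−13), n = 0..10; d = 2..8; linear,
Gaussian, homogeneous and inhomogeneous polynomial) is available, with ties
broken toward simpler kernels.

**Gene-level training set.** Positives are all down-regulated genes with at
least one site.  Negatives are sampled in two pools: unaffected genes with
1–7 sites up to a cap (default 4000), plus exactly min(1000, available)
unaffected genes with more than 7 sites — added explicitly because random
sampling would underrepresent long-UTR, many-site genes, which are
empirically depleted of true targets.  Selection happens once, before the
site stage, and the site SVM trains only on selected genes' sites, so every
training gene's sites carry held-out discriminants.

**mRNA stage.** Each gene's discriminants are binned into 16 counts: below
mean − 2 sd, above mean + 2 sd, and 14 bins bounded by the 25.00, 43.75,
57.81, 68.36, 76.27, 82.20, 86.65, 89.99, 92.49, 94.37, 95.78, 97.19, 98.6
and 100 percentiles of the training distribution with extremes removed —
an uneven grid with high resolution on the upper tail, where strong sites
concentrate.  Percentiles use linear interpolation; a value exactly at a
cut point falls in the lower bin; unseen values beyond the last cut but
within the extreme thresholds fall in the last interior bin; a degenerate
(sd = 0) distribution puts all mass in the first interior bin.  Seven more
scalars complete the 23-feature vector: site count, log UTR length, site
density, a binary "fewer than 7 sites" flag, the number of site pairs with
seed-start spacing in the cooperative 17–35 nt window, the log minimum
pairwise spacing (capped at 10⁴; single-site genes take the cap), and the
maximum discriminant.  The gene classifier is a linear SVM with C = 1 (the
conventional default; the gene score is the raw decision value, since ROC
evaluation needs only a ranking).  Genes with zero candidate sites are
never scored and are reported separately.

## Evaluation

ROC curves come from a full threshold sweep; the AUC (trapezoidal, so equal
to the pairwise rank statistic with ties counted ½) is verified against an
independent pairwise computation in the tests to 1e−12.  ROC_10·n truncates
the curve at 10·n false positives (n = number of miRNAs in the set) while
keeping the FPR axis over all negatives, so its maximum is 10·n/#negatives
— of order 10⁻² on gene-scale sets.  The leave-one-feature-group-out
ablation reruns cross-validation with the identical fold partition per
omitted group and reports ΔAUC against the full model.

## Synthetic data generator

The generator emulates a transfection microarray study: random miRNAs
(22 nt, seed required to contain a U and a G so all nine classes are
plantable), log-normal UTR lengths (median 200 nt, clipped to 60–3000),
uniform background composition with a configurable AU knob, and one
measured (transcript, miRNA) pair per transcript — the targeting miRNA for
targeted transcripts (35%), a random one otherwise.

Each targeted gene draws a latent **efficacy** u ~ Beta(0.2, 0.2).  The
bimodal shape encodes that candidate targets are mostly either clearly
functional or clearly not; u controls everything that makes a target
functional: the seed-type mix (stringent-heavy at high u, defective-heavy
at low u), the per-site probability of 3' supplementary pairing
(0.05 + 0.9·u; planted as a perfectly complementary 13–16 flank), the
planted site count (1 + Binomial(4, 0.05 + 0.85·u)) and AU-rich context
around sites (probability u of resampling the ±30 nt windows at 85% A+U).
The latent repression score is the mean site quality (seed-type strength:
8mer 4.0, 7mer-A1/7mer-m8 3.0, 6mer 1.5, GUM 1.0, GUT 0.9, LP 0.7, BM 0.6,
BT 0.5; plus 2.0 per supplementary-paired site) plus 0.6 per site beyond
the first, 0.6 per site pair at 17–35 nt spacing, and 1.0 times the mean AU
context.  Genes above the median latent of targeted genes are labelled
down-regulated, and every label flips with probability 0.05.  Mid-efficacy
genes are exactly where site count and spacing decide the label — that is
what a gene-level model can exploit and a best-single-site ranking cannot.

`plant_site` is the constructive inverse of window classification: it
writes the window plus the minimal guard bases (the A1 base; for 6-nt
windows also the base opposite position 8) without which the class at the
anchor would be ambiguous, verifies by re-classification and a local
scan+resolve, and fails (for the caller to re-place) when the surrounding
context would mask the site with an overlapping higher-precedence match.
`generate_dataset` additionally verifies each transcript by a full scan
round trip, re-rolling the background on failure, so every manifest site is
recoverable by construction.

**What the generator does not emulate:** real expression-derived labels
(p-value/log-ratio thresholds over probe intensities), conservation,
site accessibility and secondary structure, realistic transcriptome length
and composition distributions, competition with endogenous miRNAs, and
3'-compensatory (seedless) sites.  Tests passing on this generator show the
pipeline recovers a planted signal of the kind the features encode; they do
not certify accuracy on biological data.

## Problem sizes and numerical choices

The test suite and the acceptance script run the study at 2000 transcripts
× 5 miRNAs (≈ 2900 training sites, ≈ 1200 scored genes), where a full
two-stage training with 10-fold cross-validation takes seconds on one core.
Scanner/oracle equivalence uses 250 random 1-kb UTRs; plant/scan round
trips 500 sites.  All randomness flows through explicit integer seeds;
training itself (libsvm) is deterministic given the data, so repeated runs
are byte-identical.  Percentile interpolation, bin edge conventions, the
min–max degenerate-feature rule and clamping are as stated above; sample
standard deviation (ddof = 1) is used for the binner's extreme thresholds.

## Known limitations

- The 20-feature site vector covers the determinants named above;
  accessibility (ΔΔG) and conservation (phastCons/phyloP) features are
  deliberately excluded — they are computationally heavy and contributed
  little in the underlying model — so predictions are conservation-free.
- The homogeneous-polynomial γ default was chosen for numerical sanity on
  this feature schema; other feature sets may prefer a different grid
  point.
- The mRNA stage requires the exact site model that produced its training
  discriminants (enforced by a model fingerprint); mixing stages from
  different runs is an error, not a warning.
- Site-level folds are not grouped by gene; sites of one gene can appear in
  different folds.  The held-out-discriminant guarantee is per site, not
  per gene.
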