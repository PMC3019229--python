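"""ROC evaluation: full AUC and the truncated ROC_10*n score.

Builds a toy ranking of 1000 genes for a 9-miRNA evaluation set and prints
both scores.  ROC_10*n looks only at the curve up to 10*n false positives
(90 here), so it rewards methods whose top-ranked predictions are right;
its ceiling is 10*n divided by the number of negatives.
"""

import numpy as np

from mirsvm import roc_curve_auc, roc_truncated

rng = np.random.default_rng(4)
n_genes, n_mirnas = 1000, 9
labels = (rng.random(n_genes) < 0.1).astype(int)
# Scores: informative but noisy, so some negatives rank high.
scores = labels * 1.5 + rng.normal(size=n_genes)

result = roc_curve_auc(scores, labels)
truncated = roc_truncated(scores, labels, n_mirnas)
n_neg = int((labels == 0).sum())

print(f"genes: {n_genes} ({int(labels.sum())} down-regulated)")
print(f"full AUC: {result.auc:.3f}")
print(f"ROC_10*n (n={n_mirnas}, cutoff {10 * n_mirnas} false positives): {truncated:.4f}")
print(f"ROC_10*n ceiling: {10 * n_mirnas / n_neg:.4f}")
# A full AUC near 0.9 with a ROC_10*n well below its ceiling means the
# ranking is good overall but the very top of the list still mixes in
# false positives.
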