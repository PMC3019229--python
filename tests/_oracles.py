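"""Independent brute-force oracles used only by the tests.

These deliberately avoid the package's pattern-set machinery: window
classification is done by explicit per-column pairing loops, site
enumeration by scanning every window, and overlap resolution by a naive
repeated-selection loop, so agreement with the library is a genuine
cross-check.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}

ORACLE_TYPE_ORDER = ["8mer", "7mer-A1", "7mer-m8", "6mer", "GUM", "GUT", "LP", "BM", "BT"]
ORACLE_RANK = {"8mer": 0, "7mer-A1": 0, "7mer-m8": 0, "6mer": 0,
               "GUM": 1, "GUT": 2, "LP": 3, "BM": 4, "BT": 5}
ORACLE_EXEMPT = {"8mer", "7mer-A1", "7mer-m8", "6mer"}


def _is_wc(m: str, t: str) -> bool:
    return (m, t) in _WC


def _pair_states(seed: str, window: str) -> List[str]:
    """Pairing state per seed position (5'->3' on the miRNA); window base at
    index len-1-k pairs seed index k (antiparallel)."""
    n = len(seed)
    states = []
    for k in range(n):
        m = seed[k]
        t = window[n - 1 - k]
        if _is_wc(m, t):
            states.append("wc")
        elif m == "U" and t == "G":
            states.append("gum")
        elif m == "G" and t == "U":
            states.append("gut")
        else:
            states.append("mm")
    return states


def oracle_window_types(mirna_seq: str, window: str, next_base: Optional[str]) -> List[str]:
    """All seed types the window satisfies, by explicit enumeration."""
    seed28 = mirna_seq[1:8]
    seed27 = seed28[:6]
    found = []
    n = len(window)
    if n == 7:
        st = _pair_states(seed28, window)
        if all(s == "wc" for s in st):
            found.append("8mer" if next_base == "A" else "7mer-m8")
        if st.count("gum") == 1 and st.count("wc") == 6:
            found.append("GUM")
        if st.count("gut") == 1 and st.count("wc") == 6:
            found.append("GUT")
        if st.count("mm") == 1 and st.count("wc") == 6 and st.index("mm") in (1, 2, 3, 4, 5):
            found.append("LP")
    elif n == 6:
        st = _pair_states(seed27, window)
        if all(s == "wc" for s in st):
            found.append("7mer-A1" if next_base == "A" else "6mer")
        for i in (1, 2, 3, 4, 5):  # bulged miRNA base, internal only
            reduced = seed28[:i] + seed28[i + 1 :]
            st_b = _pair_states(reduced, window)
            if all(s == "wc" for s in st_b) and reduced != seed27:
                found.append("BM")
                break
    elif n == 8:
        for i in (1, 2, 3, 4, 5, 6):  # inserted target base, internal only
            reduced = window[:i] + window[i + 1 :]
            st_b = _pair_states(seed28, reduced)
            if all(s == "wc" for s in st_b):
                found.append("BT")
                break
    return found


def oracle_scan(mirna_seq: str, utr: str) -> List[Tuple[str, int, int]]:
    """All candidate sites as (seed_type, seed_start, seed_end), one per
    anchor, highest-precedence type; 1-based coordinates."""
    L = len(utr)
    sites = []
    for anchor in range(L):  # anchor = 0-based index of the window's 3' end
        next_base = utr[anchor + 1] if anchor + 1 < L else None
        best = None
        for wlen in (6, 7, 8):
            start = anchor - wlen + 1
            if start < 15:  # seed match must start at UTR position >= 16
                continue
            window = utr[start : anchor + 1]
            for t in oracle_window_types(mirna_seq, window, next_base):
                cand = (ORACLE_TYPE_ORDER.index(t), t, start)
                if best is None or cand[0] < best[0]:
                    best = cand
        if best is None:
            continue
        _, t, start = best
        seed_start = start + 1
        seed_end = anchor + 1 + (1 if t in ("8mer", "7mer-A1") else 0)
        sites.append((t, seed_start, seed_end))
    return sites


def oracle_resolve(sites: List[Tuple[str, int, int]]) -> List[Tuple[str, int, int]]:
    """Naive repeated-selection overlap resolution."""
    remaining = list(sites)
    kept: List[Tuple[str, int, int]] = []

    def overlaps(a, b):
        return a[1] <= b[2] and b[1] <= a[2]

    def conflicts(a, b):
        return overlaps(a, b) and not (a[0] in ORACLE_EXEMPT and b[0] in ORACLE_EXEMPT)

    while remaining:
        remaining.sort(key=lambda s: (ORACLE_RANK[s[0]], s[1], ORACLE_TYPE_ORDER.index(s[0]), s[2]))
        best = remaining.pop(0)
        kept.append(best)
        remaining = [s for s in remaining if not conflicts(s, best)]
    kept.sort(key=lambda s: (s[1], s[2], ORACLE_TYPE_ORDER.index(s[0])))
    return kept


def oracle_auc_pairwise(scores, labels) -> float:
    """AUC as the pairwise rank statistic, ties counted 1/2."""
    pos = [s for s, l in zip(scores, labels) if l == 1]
    neg = [s for s, l in zip(scores, labels) if l == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def oracle_roc_truncated(scores, labels, max_fp: int) -> float:
    """Truncated ROC area by direct threshold enumeration.

    Walks distinct score thresholds from high to low, accumulating
    trapezoids on the (FPR, TPR) curve, clipping the final segment at
    ``max_fp`` false positives; FPR is measured against all negatives.
    """
    import numpy as np

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    fp_max = min(max_fp, n_neg)
    order = np.argsort(-scores, kind="mergesort")
    s_sorted = scores[order]
    l_sorted = labels[order]
    area = 0.0
    tp = fp = 0
    i = 0
    n = len(scores)
    while i < n and fp < fp_max:
        j = i
        d_tp = d_fp = 0
        while j < n and s_sorted[j] == s_sorted[i]:  # tie block
            if l_sorted[j] == 1:
                d_tp += 1
            else:
                d_fp += 1
            j += 1
        tp2, fp2 = tp + d_tp, fp + d_fp
        if fp2 > fp_max:  # clip the tie block's segment at fp_max
            frac = (fp_max - fp) / d_fp
            tp2 = tp + d_tp * frac
            fp2 = fp_max
        area += (fp2 - fp) / n_neg * ((tp + tp2) / 2.0) / n_pos
        tp, fp = tp2, fp2
        i = j
    return area
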