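"""Global alignment of the miRNA 3' region against the target site flank.

Beyond the seed, pairing between the miRNA 3' half — especially positions
13-16 — and the target supplements site recognition.  The miRNA region at
positions 9..min(L, 20) is aligned to the UTR flank immediately 5' of the
seed match (the bases lying opposite those miRNA positions in the duplex).

Scoring quantifies base *pairing* rather than identity: a Watson-Crick pair
scores +5, a G:U wobble +1, any other juxtaposition -4; a gap of length k
costs 10 + 0.5k.  End gaps are free, so a short or empty flank simply
yields a low or zero score.  The alignment is a Needleman-Wunsch/Gotoh
dynamic program with deterministic traceback (diagonal preferred over a gap
in the target, over a gap in the miRNA).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

__all__ = [
    "DuplexAlignment",
    "MATCH_SCORE",
    "WOBBLE_SCORE",
    "MISMATCH_SCORE",
    "GAP_OPEN",
    "GAP_EXTEND",
    "pair_score",
    "align_pairing",
    "align_duplex",
]

MATCH_SCORE = 5.0
WOBBLE_SCORE = 1.0
MISMATCH_SCORE = -4.0
GAP_OPEN = 10.0  # charged once per interior gap, in addition to the extension
GAP_EXTEND = 0.5  # charged per gap column

#: miRNA positions whose pairing is summarised separately.
SUPPLEMENTARY_RANGE = (13, 16)

#: Last miRNA position considered for 3' supplementary pairing.
MAX_MIRNA_POSITION = 20

_WC = {("A", "U"), ("U", "A"), ("G", "C"), ("C", "G")}
_WOBBLE = {("G", "U"), ("U", "G")}


def pair_score(a: str, b: str) -> float:
    """Score of juxtaposing miRNA base ``a`` with target base ``b``."""
    if (a, b) in _WC:
        return MATCH_SCORE
    if (a, b) in _WOBBLE:
        return WOBBLE_SCORE
    return MISMATCH_SCORE


@dataclass(frozen=True)
class DuplexAlignment:
    """Alignment of the miRNA 3' region with the site flank.

    ``aligned_mirna`` is the miRNA region 5'->3'; ``aligned_target`` is the
    flank written 3'->5' (so paired bases sit in the same column), both with
    ``-`` for gaps.  ``score_13_16`` sums the columns whose miRNA character
    originates from miRNA positions 13-16 (including gap costs charged in
    those columns).
    """

    aligned_mirna: str
    aligned_target: str
    total_score: float
    score_13_16: float
    mirna_offset: int = 9  # miRNA position of the first aligned_mirna base


_NEG = float("-inf")
_M, _X, _Y = 0, 1, 2  # pair / gap-in-target ("up") / gap-in-miRNA ("left")


def _best3(m: float, x: float, y: float) -> Tuple[float, int]:
    # Preference order M > X > Y realises diagonal > up > left tie-breaking.
    best, st = m, _M
    if x > best:
        best, st = x, _X
    if y > best:
        best, st = y, _Y
    return best, st


def align_pairing(a: str, b: str, mirna_offset: int = 9) -> DuplexAlignment:
    """Align miRNA fragment ``a`` (5'->3') to target fragment ``b`` (3'->5')
    with the duplex pairing scores and free end gaps."""
    n, m = len(a), len(b)
    open_total = GAP_OPEN + GAP_EXTEND

    M = [[_NEG] * (m + 1) for _ in range(n + 1)]
    X = [[_NEG] * (m + 1) for _ in range(n + 1)]
    Y = [[_NEG] * (m + 1) for _ in range(n + 1)]
    pM = [[-1] * (m + 1) for _ in range(n + 1)]
    pX = [[-1] * (m + 1) for _ in range(n + 1)]
    pY = [[-1] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = 0.0  # free leading gap in the target
        pX[i][0] = _M if i == 1 else _X
    for j in range(1, m + 1):
        Y[0][j] = 0.0  # free leading gap in the miRNA
        pY[0][j] = _M if j == 1 else _Y

    for i in range(1, n + 1):
        ai = a[i - 1]
        for j in range(1, m + 1):
            s = pair_score(ai, b[j - 1])
            best, st = _best3(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            M[i][j] = s + best
            pM[i][j] = st
            best, st = _best3(
                M[i - 1][j] - open_total,
                X[i - 1][j] - GAP_EXTEND,
                Y[i - 1][j] - open_total,
            )
            X[i][j] = best
            pX[i][j] = st
            best, st = _best3(
                M[i][j - 1] - open_total,
                X[i][j - 1] - open_total,
                Y[i][j - 1] - GAP_EXTEND,
            )
            Y[i][j] = best
            pY[i][j] = st

    # Free trailing gaps: the alignment may end anywhere on the last row or
    # column; remaining characters are appended opposite cost-free gaps.
    candidates = [(n, m)]
    candidates += [(i, m) for i in range(n - 1, -1, -1)]
    candidates += [(n, j) for j in range(m - 1, -1, -1)]
    total = _NEG
    for (i, j) in candidates:
        for st, mat in ((_M, M), (_X, X), (_Y, Y)):
            if mat[i][j] > total:
                total = mat[i][j]
    start = None
    for (i, j) in candidates:
        for st, mat in ((_M, M), (_X, X), (_Y, Y)):
            if mat[i][j] == total:
                start = (i, j, st)
                break
        if start:
            break
    if start is None or total == _NEG:  # only possible for n == 0 or m == 0
        cols = [(a[k], "-", 0.0) for k in range(n)]
        cols += [("-", b[k], 0.0) for k in range(m)]
        return _finish(cols, 0.0, mirna_offset)

    i, j, st = start
    cols = []  # built back-to-front: (mirna char, target char, column cost)
    for k in range(n - 1, i - 1, -1):
        cols.append((a[k], "-", 0.0))  # free trailing gap
    for k in range(m - 1, j - 1, -1):
        cols.append(("-", b[k], 0.0))

    while (i, j) != (0, 0):
        if st == _M:
            cols.append((a[i - 1], b[j - 1], pair_score(a[i - 1], b[j - 1])))
            st = pM[i][j]
            i, j = i - 1, j - 1
        elif st == _X:
            if j == 0:
                cost = 0.0  # free leading gap run
            else:
                prev = pX[i][j]
                cost = -GAP_EXTEND if prev == _X else -open_total
            cols.append((a[i - 1], "-", cost))
            st = pX[i][j]
            i -= 1
        else:
            if i == 0:
                cost = 0.0
            else:
                prev = pY[i][j]
                cost = -GAP_EXTEND if prev == _Y else -open_total
            cols.append(("-", b[j - 1], cost))
            st = pY[i][j]
            j -= 1

    cols.reverse()
    return _finish(cols, total, mirna_offset)


def _finish(cols, total: float, mirna_offset: int) -> DuplexAlignment:
    lo, hi = SUPPLEMENTARY_RANGE
    aligned_a = "".join(c[0] for c in cols)
    aligned_b = "".join(c[1] for c in cols)
    pos = mirna_offset
    score_sup = 0.0
    for ca, _cb, cost in cols:
        if ca != "-":
            if lo <= pos <= hi:
                score_sup += cost
            pos += 1
    return DuplexAlignment(
        aligned_mirna=aligned_a,
        aligned_target=aligned_b,
        total_score=float(total),
        score_13_16=float(score_sup),
        mirna_offset=mirna_offset,
    )


#: Seed types whose match pairs miRNA positions 2-7 only; their duplex
#: register sits one base further 5' on the UTR (the base immediately 5' of
#: the match lies opposite position 8, not 9).
_SHORT_REGISTER_TYPES = ("6mer", "7mer-A1")


def align_duplex(mirna, site, transcript) -> DuplexAlignment:
    """Align miRNA positions 9..min(L, 20) to the flank 5' of a site's seed
    match; the flank is truncated at the UTR 5' boundary and may be empty."""
    seq = mirna.sequence
    three_prime = seq[8 : min(len(seq), MAX_MIRNA_POSITION)]
    n_flank = len(three_prime)
    flank_end = site.seed_start - 1
    if site.seed_type in _SHORT_REGISTER_TYPES:
        flank_end -= 1
    flank = transcript.utr[max(0, flank_end - n_flank) : max(0, flank_end)]
    # The flank base adjacent to the match register lies opposite miRNA
    # position 9; reversing the flank puts paired bases in matching columns.
    return align_pairing(three_prime, flank[::-1])
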