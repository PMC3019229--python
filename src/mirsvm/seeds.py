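"""Seed-match scanning of 3' UTRs under nine seed-type definitions.

Animal miRNAs recognise targets mainly through the "seed" — miRNA positions
2-7 at the 5' end, extendable to position 8 — pairing antiparallel to the
3' UTR.  Nine match classes are recognised here, in two groups:

* stringent: ``8mer``, ``7mer-A1``, ``7mer-m8`` — perfect Watson-Crick (WC)
  pairing of the seed, with an adenosine opposite miRNA position 1 (the "A1"
  base) for ``8mer``/``7mer-A1``;
* non-stringent: ``6mer`` (WC pairing of positions 2-7 only) and five
  single-defect variants of the 2-8 match — ``GUM``/``GUT`` (one G:U wobble,
  with the U on the miRNA or the target respectively), ``LP`` (one internal
  1x1 mismatch loop), ``BM`` (one unpaired miRNA base) and ``BT`` (one
  unpaired target base).

All non-stringent defect types are defined over the miRNA 2-8 span with
exactly one defect; the defect may not sit at a seed-terminal position for
LP/BM/BT (a terminal bulge or loop is indistinguishable from a shorter exact
match).

Coordinates are 1-based inclusive on the UTR, whose first base is the first
nucleotide after the stop codon.  Sites whose match would begin within the
first 15 nt of the UTR are not reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Iterable, Optional, Sequence

__all__ = [
    "SEED_TYPES",
    "STRINGENT_TYPES",
    "OVERLAP_EXEMPT_TYPES",
    "PRECEDENCE_RANK",
    "MIN_SEED_START",
    "TargetSite",
    "reverse_complement",
    "classify_window",
    "classify_anchor",
    "scan_candidate_sites",
    "resolve_overlaps",
]

_COMPLEMENT = str.maketrans("ACGU", "UGCA")

#: Fixed type order; doubles as the within-rank tie-break order.
SEED_TYPES = ("8mer", "7mer-A1", "7mer-m8", "6mer", "GUM", "GUT", "LP", "BM", "BT")

STRINGENT_TYPES = frozenset({"8mer", "7mer-A1", "7mer-m8"})

#: Types allowed to partially overlap each other on the UTR.
OVERLAP_EXEMPT_TYPES = frozenset({"8mer", "7mer-A1", "7mer-m8", "6mer"})

#: Overlap precedence: 8mer = 7mer-A1 = 7mer-m8 = 6mer > GUM > GUT > LP > BM > BT.
PRECEDENCE_RANK = {
    "8mer": 0,
    "7mer-A1": 0,
    "7mer-m8": 0,
    "6mer": 0,
    "GUM": 1,
    "GUT": 2,
    "LP": 3,
    "BM": 4,
    "BT": 5,
}

_TYPE_INDEX = {t: i for i, t in enumerate(SEED_TYPES)}

#: 1-based minimum UTR coordinate for the 5' end of a seed match.
MIN_SEED_START = 16

#: Length of the site region reported for each site (opposite miRNA 1..20).
SITE_REGION_LENGTH = 20


def reverse_complement(seq: str) -> str:
    """Reverse complement of an RNA string (ACGU alphabet)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class TargetSite:
    """One candidate miRNA target site on a 3' UTR.

    ``seed_start``/``seed_end`` are 1-based inclusive UTR coordinates of the
    full extent of the seed match, including the A1 adenosine for
    8mer/7mer-A1 sites.  ``site_region`` is the up-to-20-nt UTR substring
    whose 3'-most base lies opposite miRNA position 1.
    """

    transcript_id: str
    mirna_id: str
    seed_type: str
    seed_start: int
    seed_end: int
    site_region: str
    duplex: Optional[object] = None

    @property
    def span(self) -> int:
        return self.seed_end - self.seed_start + 1


@dataclass(frozen=True)
class _SeedPatterns:
    """Pre-computed target-window strings for one miRNA seed region."""

    rc27: str
    rc28: str
    gum: frozenset
    gut: frozenset
    lp: frozenset
    bm: frozenset
    bt: frozenset


_WC_PARTNER = {"A": "U", "U": "A", "G": "C", "C": "G"}


@lru_cache(maxsize=4096)
def _seed_patterns(seed28: str) -> _SeedPatterns:
    """Enumerate all target windows matching miRNA seed ``seed28`` (positions 2-8).

    The target window is read 5'->3'; window base at index ``6 - i`` pairs
    seed28 index ``i`` (antiparallel duplex).
    """
    if len(seed28) != 7 or any(c not in "ACGU" for c in seed28):
        raise ValueError(f"seed region must be 7 nt of ACGU, got {seed28!r}")
    rc28 = reverse_complement(seed28)
    rc27 = reverse_complement(seed28[:6])

    gum, gut, lp = set(), set(), set()
    for i, m in enumerate(seed28):  # i=0 is miRNA position 2
        k = 6 - i  # window index pairing seed28[i]
        if m == "U":
            w = list(rc28)
            w[k] = "G"  # U(miRNA):G(target) wobble
            gum.add("".join(w))
        if m == "G":
            w = list(rc28)
            w[k] = "U"  # G(miRNA):U(target) wobble
            gut.add("".join(w))
        if 1 <= i <= 5:  # internal positions 3-7 only
            for b in "ACGU":
                if b == _WC_PARTNER[m]:
                    continue
                if {m, b} == {"G", "U"}:
                    continue  # wobble, not a loop
                w = list(rc28)
                w[k] = b
                lp.add("".join(w))

    bm = set()
    for i in range(1, 6):  # bulged miRNA base at positions 3-7
        reduced = seed28[:i] + seed28[i + 1 :]
        w = reverse_complement(reduced)
        if w != rc27:  # degenerate: identical to an exact 6mer window
            bm.add(w)

    bt = set()
    for k in range(1, 7):  # inserted target base strictly inside the 8-nt window
        for b in "ACGU":
            bt.add(rc28[:k] + b + rc28[k:])
    bt.discard(rc28)  # cannot happen (lengths differ) but keep the intent explicit

    return _SeedPatterns(
        rc27=rc27,
        rc28=rc28,
        gum=frozenset(gum),
        gut=frozenset(gut),
        lp=frozenset(lp),
        bm=frozenset(bm),
        bt=frozenset(bt),
    )


def _seed_region(mirna) -> str:
    seq = mirna if isinstance(mirna, str) else mirna.sequence
    if len(seq) < 8:
        raise ValueError("miRNA shorter than 8 nt has no seed region")
    return seq[1:8]


def classify_window(mirna, window: str, next_base: Optional[str] = None) -> Optional[str]:
    """Classify a UTR window (read 5'->3') against a miRNA seed.

    ``next_base`` is the UTR base immediately 3' of the window — the base
    opposite miRNA position 1 — or ``None`` at the UTR boundary.  Returns the
    highest-precedence seed type the window satisfies, or ``None``.  Windows
    shorter than 6 nt never match.
    """
    pats = _seed_patterns(_seed_region(mirna))
    n = len(window)
    if n == 7:
        if window == pats.rc28:
            return "8mer" if next_base == "A" else "7mer-m8"
        if window in pats.gum:
            return "GUM"
        if window in pats.gut:
            return "GUT"
        if window in pats.lp:
            return "LP"
    elif n == 6:
        if window == pats.rc27:
            return "7mer-A1" if next_base == "A" else "6mer"
        if window in pats.bm:
            return "BM"
    elif n == 8:
        if window in pats.bt:
            return "BT"
    return None


# Window length per type (full window written on the UTR, excluding the A1 base).
_WINDOW_LENGTH = {
    "8mer": 7,
    "7mer-m8": 7,
    "GUM": 7,
    "GUT": 7,
    "LP": 7,
    "7mer-A1": 6,
    "6mer": 6,
    "BM": 6,
    "BT": 8,
}


def classify_anchor(mirna, utr: str, anchor: int) -> Optional[tuple]:
    """Best seed type at an anchor (0-based UTR index pairing miRNA position 2).

    The 7-, 6- and 8-nt windows ending at ``anchor`` are classified and the
    single highest-precedence type is returned as ``(seed_type, start0)``
    with ``start0`` the 0-based window start, or ``None``.  Windows starting
    before UTR position 16 (1-based) are not considered.
    """
    pats = _seed_patterns(_seed_region(mirna))
    L = len(utr)
    if anchor >= L:
        return None
    next_base = utr[anchor + 1] if anchor + 1 < L else None
    best = None
    for wlen in (7, 6, 8):
        start0 = anchor - wlen + 1
        if start0 < MIN_SEED_START - 1:
            continue
        w = utr[start0 : anchor + 1]
        t = None
        if wlen == 7:
            if w == pats.rc28:
                t = "8mer" if next_base == "A" else "7mer-m8"
            elif w in pats.gum:
                t = "GUM"
            elif w in pats.gut:
                t = "GUT"
            elif w in pats.lp:
                t = "LP"
        elif wlen == 6:
            if w == pats.rc27:
                t = "7mer-A1" if next_base == "A" else "6mer"
            elif w in pats.bm:
                t = "BM"
        else:
            if w in pats.bt:
                t = "BT"
        if t is not None and (best is None or _TYPE_INDEX[t] < _TYPE_INDEX[best[0]]):
            best = (t, start0)
    return best


def _site_from_anchor(mirna_id: str, transcript_id: str, utr: str, anchor: int,
                      seed_type: str, start0: int) -> TargetSite:
    L = len(utr)
    seed_start = start0 + 1
    seed_end = anchor + 1
    if seed_type in ("8mer", "7mer-A1"):
        seed_end += 1  # A1 adenosine is part of the match
    region_end = min(anchor + 2, L)  # 1-based coordinate opposite miRNA position 1
    region_start = max(1, region_end - SITE_REGION_LENGTH + 1)
    return TargetSite(
        transcript_id=transcript_id,
        mirna_id=mirna_id,
        seed_type=seed_type,
        seed_start=seed_start,
        seed_end=seed_end,
        site_region=utr[region_start - 1 : region_end],
    )


def scan_candidate_sites(mirna, transcript) -> list:
    """Enumerate candidate sites for one miRNA on one transcript (pre-resolution).

    One site per anchor, labelled with the highest-precedence type at that
    anchor; deterministic left-to-right order.  UTRs shorter than 21 nt yield
    no sites (no 6-nt window fits past the 15-nt exclusion zone).
    """
    utr = transcript.utr
    L = len(utr)
    if L < MIN_SEED_START + 5:
        return []
    sites = []
    # Smallest window (6 nt) starting at index 15 ends at index 20.
    for anchor in range(MIN_SEED_START + 4, L):
        hit = classify_anchor(mirna, utr, anchor)
        if hit is None:
            continue
        seed_type, start0 = hit
        sites.append(
            _site_from_anchor(mirna.id, transcript.id, utr, anchor, seed_type, start0)
        )
    return sites


def _overlap(a: TargetSite, b: TargetSite) -> bool:
    return a.seed_start <= b.seed_end and b.seed_start <= a.seed_end


def _conflict(a: TargetSite, b: TargetSite) -> bool:
    if not _overlap(a, b):
        return False
    return not (
        a.seed_type in OVERLAP_EXEMPT_TYPES and b.seed_type in OVERLAP_EXEMPT_TYPES
    )


def resolve_overlaps(sites: Iterable[TargetSite]) -> list:
    """Resolve overlapping sites of one (miRNA, transcript) pair by precedence.

    Partial overlaps are allowed only among {8mer, 7mer-A1, 7mer-m8, 6mer}.
    Conflicts are resolved greedily by (precedence rank, seed_start, type
    order): e.g. an overlapping GUM/GUT pair keeps the GUM site.  Idempotent
    and independent of input order.
    """
    order = sorted(
        sites,
        key=lambda s: (
            PRECEDENCE_RANK[s.seed_type],
            s.seed_start,
            _TYPE_INDEX[s.seed_type],
            s.seed_end,
            s.transcript_id,
            s.mirna_id,
        ),
    )
    kept: list = []
    for s in order:
        if any(_conflict(s, k) for k in kept):
            continue
        kept.append(s)
    kept.sort(key=lambda s: (s.seed_start, s.seed_end, _TYPE_INDEX[s.seed_type]))
    return kept
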