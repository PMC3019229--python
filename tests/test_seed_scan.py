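"""Seed-type classification, scanning and overlap resolution."""

import numpy as np
import pytest

from mirsvm import (
    MIN_SEED_START,
    SEED_TYPES,
    MicroRNA,
    TargetSite,
    Transcript,
    classify_window,
    resolve_overlaps,
    reverse_complement,
    scan_candidate_sites,
)

from _oracles import oracle_resolve, oracle_scan, oracle_window_types
from conftest import random_mirna, random_rna


@pytest.mark.parametrize(
    "window,next_base,expected",
    [
        ("AUAAGCU", "A", "8mer"),      # WC 2-8 + A1 adenosine
        ("AUAAGCU", "C", "7mer-m8"),   # WC 2-8, no A1
        ("UAAGCU", "A", "7mer-A1"),    # WC 2-7 + A1
        ("UAAGCU", "G", "6mer"),       # WC 2-7 only
        ("AUAGGCU", "C", "GUM"),       # G opposite miRNA U at position 5
        ("AUAAGUU", "C", "GUT"),       # U opposite miRNA G at position 3
        ("AUACGCU", "C", "LP"),        # C opposite miRNA U at position 5: 1x1 loop
        ("AUAGCU", "C", "BM"),         # miRNA position 5 bulged out
        ("AUAAGGCU", "C", "BT"),       # extra target base inside the match
        ("AUAAG", "A", None),          # shorter than 6 nt never matches
        ("AUAAGCG", "C", None),        # terminal mismatch is not a loop
    ],
)
def test_classify_window_examples(mir21, window, next_base, expected):
    # mir21 seed 2-8 = AGCUUAU; WC window for 2-8 is AUAAGCU.
    assert classify_window(mir21, window, next_base) == expected


def test_classify_window_agrees_with_enumeration_oracle(mir21):
    """Exhaustive cross-check on random windows of lengths 5-9."""
    rng = np.random.default_rng(42)
    order = list(SEED_TYPES)
    rc28 = reverse_complement(mir21.sequence[1:8])
    n_hits = 0
    for _ in range(4000):
        # Mutate the perfect window: substitutions, one insertion or one
        # deletion, so both matching and near-matching windows are covered.
        w = list(rc28)
        for _ in range(int(rng.integers(0, 3))):
            w[int(rng.integers(0, len(w)))] = str(rng.choice(list("ACGU")))
        action = rng.random()
        if action < 0.25:
            w.insert(int(rng.integers(0, len(w) + 1)), str(rng.choice(list("ACGU"))))
        elif action < 0.5:
            del w[int(rng.integers(0, len(w)))]
        window = "".join(w)
        next_base = str(rng.choice(list("ACGU")))
        got = classify_window(mir21, window, next_base)
        expected = oracle_window_types(mir21.sequence, window, next_base)
        if expected:
            assert got == min(expected, key=order.index), (window, next_base)
            n_hits += 1
        else:
            assert got is None, (window, next_base)
    assert n_hits > 200  # the fuzz actually exercised matching windows


def test_scan_finds_planted_8mer_after_exclusion_zone(mir21):
    utr = "A" * 15 + "AUAAGCUA"
    sites = scan_candidate_sites(mir21, Transcript(id="t", utr=utr))
    assert len(sites) == 1
    (site,) = sites
    assert site.seed_type == "8mer"
    assert (site.seed_start, site.seed_end) == (16, 23)
    assert site.span == 8


def test_scan_ignores_sites_within_first_15_nt(mir21):
    utr = "AUAAGCUA" + "A" * 20
    assert scan_candidate_sites(mir21, Transcript(id="t", utr=utr)) == []


def test_scan_short_utr_yields_no_sites(mir21):
    assert scan_candidate_sites(mir21, Transcript(id="t", utr="A" * 20)) == []


def test_scan_matches_brute_force_oracle_on_random_pairs(mir21):
    rng = np.random.default_rng(100)
    for i in range(40):
        mirna = random_mirna(rng, f"m{i}")
        utr = random_rna(rng, 500)
        got = [
            (s.seed_type, s.seed_start, s.seed_end)
            for s in scan_candidate_sites(mirna, Transcript(id="t", utr=utr))
        ]
        assert got == oracle_scan(mirna.sequence, utr)


def _site(seed_type, start, end):
    return TargetSite(
        transcript_id="t", mirna_id="m", seed_type=seed_type,
        seed_start=start, seed_end=end, site_region="",
    )


def test_resolve_overlaps_precedence_cases():
    gum, gut = _site("GUM", 30, 36), _site("GUT", 33, 39)
    assert resolve_overlaps([gut, gum]) == [gum]  # GUM outranks GUT

    lp, bt = _site("LP", 30, 36), _site("BT", 32, 39)
    assert resolve_overlaps([bt, lp]) == [lp]

    m8, m6 = _site("7mer-m8", 30, 36), _site("6mer", 33, 38)
    assert resolve_overlaps([m8, m6]) == [m8, m6]  # stringent + 6mer may overlap

    m8b, gum2 = _site("7mer-m8", 30, 36), _site("GUM", 33, 39)
    assert resolve_overlaps([gum2, m8b]) == [m8b]


def test_resolve_overlaps_idempotent_and_order_independent():
    rng = np.random.default_rng(3)
    sites = []
    pos = 20
    for seed_type in ("8mer", "GUM", "LP", "6mer", "BT", "GUT", "BM"):
        span = {"8mer": 8, "BT": 8, "BM": 6, "6mer": 6}.get(seed_type, 7)
        sites.append(_site(seed_type, pos, pos + span - 1))
        pos += int(rng.integers(3, 10))  # overlapping chain
    resolved = resolve_overlaps(sites)
    assert resolve_overlaps(resolved) == resolved
    for _ in range(10):
        perm = list(sites)
        rng.shuffle(perm)
        assert resolve_overlaps(perm) == resolved


def test_no_resolved_site_starts_before_position_16(mir21):
    rng = np.random.default_rng(8)
    for _ in range(20):
        utr = random_rna(rng, 300)
        for s in resolve_overlaps(scan_candidate_sites(mir21, Transcript(id="t", utr=utr))):
            assert s.seed_start >= MIN_SEED_START


def test_resolution_matches_oracle_resolution(mir21):
    rng = np.random.default_rng(200)
    for i in range(30):
        mirna = random_mirna(rng, f"m{i}")
        utr = random_rna(rng, 600)
        got = [
            (s.seed_type, s.seed_start, s.seed_end)
            for s in resolve_overlaps(scan_candidate_sites(mirna, Transcript(id="t", utr=utr)))
        ]
        assert got == oracle_resolve(oracle_scan(mirna.sequence, utr))


def test_reverse_complement():
    assert reverse_complement("AGCUUAU") == "AUAAGCU"
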