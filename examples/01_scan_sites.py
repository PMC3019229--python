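"""Scan a 3' UTR for candidate miRNA target sites.

Builds a small UTR containing an 8mer match for miR-21 plus a G:U-wobble
site, scans it under the nine seed-type definitions, and prints the
resolved sites.  Coordinates are 1-based on the UTR; the first 15 nt after
the stop codon are never reported.
"""

from mirsvm import MicroRNA, Transcript, resolve_overlaps, reverse_complement, scan_candidate_sites

mir21 = MicroRNA(id="hsa-miR-21", sequence="UAGCUUAUCAGACUGAUGUUGA")
seed_2_8 = mir21.sequence[1:8]

# An 8mer site (perfect match to positions 2-8 plus an A opposite position
# 1) and a GUM site (one G:U wobble, U on the miRNA) 40 nt apart.
eight_mer = reverse_complement(seed_2_8) + "A"
gum = "AUAGGCU" + "C"  # G opposite the miRNA U at position 5
utr = "C" * 20 + eight_mer + "G" * 32 + gum + "C" * 20

transcript = Transcript(id="NM_000000", utr=utr)
sites = resolve_overlaps(scan_candidate_sites(mir21, transcript))

print(f"{'type':>8} {'start':>6} {'end':>4}  site region (5'->3')")
for site in sites:
    print(f"{site.seed_type:>8} {site.seed_start:>6} {site.seed_end:>4}  {site.site_region}")
# Each row is one candidate site: its seed-match class, its 1-based UTR
# coordinates, and the ~20-nt region lying opposite miRNA positions 1-20.
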