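"""Score 3' supplementary pairing between a miRNA and a target site.

Functional sites often pair the miRNA 3' region — especially positions
13-16 — with the UTR just upstream of the seed match.  This aligns miR-21
positions 9-20 against such a flank and prints the alignment and scores
(+5 per Watson-Crick pair, +1 per G:U wobble, -4 per mismatch, gaps
10 + 0.5/nt, end gaps free).
"""

from mirsvm import MicroRNA, Transcript, reverse_complement, scan_candidate_sites
from mirsvm.duplex import align_duplex

mir21 = MicroRNA(id="hsa-miR-21", sequence="UAGCUUAUCAGACUGAUGUUGA")
three_prime = mir21.sequence[8:20]  # positions 9..20

# A flank complementary to positions 9-20 except for two mismatches at
# positions 10 and 19 (outside the 13-16 supplementary core).
flank = list(reverse_complement(three_prime))
flank[1] = "A" if flank[1] != "A" else "C"   # opposite position 19
flank[10] = "A" if flank[10] != "A" else "C"  # opposite position 10
flank = "".join(flank)
utr = "G" * 20 + flank + reverse_complement(mir21.sequence[1:8]) + "C" + "G" * 20
transcript = Transcript(id="tx1", utr=utr)

(site,) = scan_candidate_sites(mir21, transcript)
duplex = align_duplex(mir21, site, transcript)

print("miRNA 3' region (5'->3'):", duplex.aligned_mirna)
print("target flank    (3'->5'):", duplex.aligned_target)
print(f"total score: {duplex.total_score:+.1f}")
print(f"score at miRNA positions 13-16: {duplex.score_13_16:+.1f}")
# The 13-16 sub-score isolates the canonical supplementary-pairing region:
# the four planted Watson-Crick pairs contribute +20 there, while the two
# mismatches only reduce the total score.
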