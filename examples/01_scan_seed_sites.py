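"""Scan a 3'UTR for canonical microRNA seed-match sites.

A mature microRNA binds targets through its seed (nucleotides 2-8).  We
build let-7a-5p, derive its seed and the four site-class motifs, and scan
a short UTR carrying one planted 8mer site.
"""

from mirvar import MatureMiRNA, UTRSequence, find_seed_sites, site_motifs
from mirvar.seed_match import SITE_TYPES, sites_to_bed

let7 = MatureMiRNA(name="let-7a-5p", mature_seq="UGAGGUAGUAGGUUGUAUAGUU")
print(f"mature: {let7.mature_seq}")
print(f"seed (positions 2-8): {let7.seed}")
print("site motifs:", site_motifs(let7.seed))

utr = UTRSequence(utr_id="DEMO1", gene="GENE1", seq="AAACTACCTCAAAAGGTACCTCAGG")
sites = find_seed_sites(utr, let7, SITE_TYPES)
print("\nBED6 sites found:")
print(sites_to_bed(sites), end="")
# The 8mer at 3..11 subsumes the contained 7mer-m8 (per-anchor precedence);
# the second locus is a separate 7mer-A1 match.
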