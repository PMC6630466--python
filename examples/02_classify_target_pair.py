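"""Classify a biallelic SNP into a target/near-target pair and polarize it.

One allele of the SNP completes a let-7 8mer site, the other abolishes
it.  Polarization compares the target allele with the ancestral allele
and with the reference genome: here the ancestral target allele is
missing from the reference — the class of site that reference-based
target prediction cannot see.
"""

from mirvar import BiallelicSNP, MatureMiRNA, UTRSequence, classify_pair

let7 = MatureMiRNA(name="let-7a-5p", mature_seq="UGAGGUAGUAGGUUGUAUAGUU")
# reference carries the broken site (G at offset 6); the alternative
# allele C restores the 8mer CTACCTCA, and C is the ancestral state
utr = UTRSequence(utr_id="DEMO1", gene="GENE1", seq="AAACTAGCTCAAAA")
snp = BiallelicSNP(
    snp_id="rs0000001", utr_id="DEMO1", pos=6,
    ref_allele="G", alt_allele="C", ancestral_allele="C",
)

pair = classify_pair(utr, snp, let7)
print(f"target allele     : {pair.target_allele}")
print(f"site              : {pair.site_start}..{pair.site_end} ({pair.site_type})")
print(f"target in reference: {pair.target_in_reference}")
print(f"polarization      : {pair.polarization}")
# 'ancestral_target_lost' marks an ancestral site absent from the
# reference sequence, typically still segregating in African populations.
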