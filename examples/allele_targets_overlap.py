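"""Allele-dependent target prediction and the cosine percent overlap.

A seed SNP replaces one base of the 7 nt seed; the reference and derived
seeds therefore recognise different complementary sites in 3'UTRs.  The
functional effect of the substitution is summarised by the cosine percent
overlap |R ∩ D| / sqrt(|R|·|D|) of the two target sets: 1 means the allele
swap leaves the target spectrum intact, 0 means it rewires it completely.
"""

from mirseedsnp import Rarity, SeedSnp
from mirseedsnp.overlap import percent_overlap
from mirseedsnp.target_prediction import allele_dependent_targets, seed_match_patterns

snp = SeedSnp(
    rsid="rs_demo", mature_id="let-7a-5p", genomic_pos=1_000, seed_offset=4,
    ref_seed="GAGGUAG", derived_seeds=(("T", "GAGAUAG"),), rarity=Rarity.RARE,
)
print("reference seed", snp.ref_seed, "-> site patterns",
      {t.value: p for t, p in seed_match_patterns(snp.ref_seed).items()})
print("derived   seed", snp.derived_seeds[0][1], "-> site patterns",
      {t.value: p for t, p in seed_match_patterns(snp.derived_seeds[0][1]).items()})

utrs = {
    "shared_target": "TTTCTACCTCATTTTTCTATCTCATT",   # sites for both alleles
    "ref_only":      "AAAACTACCTCAAAAA",             # 8mer for the reference
    "der_only_1":    "GGGGCTATCTCGGG",               # 7mer-m8 for the derived
    "der_only_2":    "CCCTATCTCACCC",                # 7mer-A1 for the derived
    "no_site":       "ACACACACACACACAC",
}
ref, (der,) = allele_dependent_targets(snp, utrs)
print(f"\nreference targets R = {sorted(ref.genes)}")
print(f"derived   targets D = {sorted(der.genes)}")
score = percent_overlap(ref.genes, der.genes)
print(f"percent overlap = |R∩D| / sqrt(|R||D|) = "
      f"{len(ref.genes & der.genes)}/sqrt({len(ref.genes)}*{len(der.genes)}) "
      f"= {score:.3f}")
print("\nA low score means this single seed substitution both loses control "
      "of previous targets and gains novel ones - a high functional cost.")
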