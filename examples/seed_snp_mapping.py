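"""Map a SNP into a miRNA seed region, strand-aware.

Builds a let-7-style mature miRNA on the + strand, places one SNP inside
its seed (mature positions 2-8) and one outside, and shows how the seed
interval, the in-seed offset and the derived seed sequence are derived.
"""

from mirseedsnp import MatureMirna, SnpRecord
from mirseedsnp.seed_mapping import compute_seed_interval, map_snps_to_seeds

mature = MatureMirna(
    id="MIMAT0000062", name="let-7a-5p", precursor_id="MI0000060",
    chrom="chr9", start=94_175_962, end=94_175_983, strand="+",
    sequence="UGAGGUAGUAGGUUGUAUAGUU",
)
seed = compute_seed_interval(mature)
print(f"mature {mature.name} spans {mature.chrom}:{mature.start}-{mature.end} ({mature.strand})")
print(f"seed (positions 2-8): {seed.chrom}:{seed.start}-{seed.end}  sequence {seed.seed_sequence}")

snps = [
    # inside the seed: forward-strand REF G matches the seed base
    SnpRecord(rsid="rs_in_seed", chrom="chr9", pos=94_175_965,
              ref_allele="G", alt_alleles=("A",), maf=0.004),
    # outside the seed: ignored by the mapper
    SnpRecord(rsid="rs_outside", chrom="chr9", pos=94_175_980,
              ref_allele="A", alt_alleles=("C",), maf=0.21),
]
hits, meta = map_snps_to_seeds([seed], snps)
print(f"\n{meta['n_seed_snps']} of {len(snps)} SNPs fall in the seed:")
for h in hits:
    alt, derived = h.derived_seeds[0]
    print(f"  {h.rsid}: seed offset {h.seed_offset} (mature position "
          f"{h.seed_offset + 1}), {h.rarity.value} variant")
    print(f"    reference seed {h.ref_seed} -> derived seed {derived} "
          f"(forward-strand ALT {alt})")
print("\nThe derived seed is the allele the target predictor uses to ask "
      "which mRNAs gain or lose this miRNA's regulation.")
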