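# mirseedsnp

Analysis of single-nucleotide polymorphisms (SNPs) in microRNA **seed
regions** — the 7 nt stretch at mature positions 2–8 that drives target
recognition — and of how their distribution and functional impact relate to
**miRNA genomic clustering**. The package is aimed at regulatory-genomics
researchers who want to reproduce or extend this style of analysis on their
own annotation/variant sets, entirely from standard files (miRBase-dialect
GFF3, FASTA, VCF).

## What it computes

Given miRNA gene annotations, mature sequences, SNVs and (optionally) a
3′UTR collection and miRNA pathway sets, the pipeline:

1. **Maps SNPs into seeds, strand-aware.** The seed of a mature miRNA
   occupies genomic positions `[start+1, start+7]` on the + strand and
   `[end−7, end−1]` on the −strand. Forward-strand VCF alleles are
   complemented into miRNA sense on the − strand; SNPs whose projected REF
   disagrees with the annotated seed base are flagged and excluded. Variants
   are classed *rare* (MAF < 5 %), *common* or *unknown*.
2. **Predicts allele-dependent targets** by canonical seed matching
   (8mer, 7mer-m8, 7mer-A1; 6mer available) of the reference seed and of
   each ALT-substituted *derived* seed against the UTR collection.
3. **Scores the functional effect** of each seed substitution with the
   cosine percent overlap of the two target sets,

   `percent_overlap = |R ∩ D| / √(|R|·|D|)`,

   where `R` and `D` are the reference- and derived-allele target sets
   (1 = target spectrum unchanged, 0 = completely rewired).
4. **Clusters miRNA genes**: precursors on the same chromosome and strand
   whose neighboring loci lie within 10 kb chain into clusters
   (single-linkage, boundary inclusive).
5. **Tests the associations**: a 2×2 Pearson chi-square for enrichment of
   seed-SNP carriers in clusters, a two-sided Student *t*-test comparing
   percent overlap between clustered and nonclustered carriers, and a
   hypergeometric over-representation analysis (BH-corrected) of carrier
   miRNAs in user-supplied pathway sets.

A fully deterministic **synthetic-data generator** emits all five input
files with planted clusters, planted enrichment at a configurable odds
ratio, and planted per-SNP target counts whose percent overlap is known in
closed form — so every stage can be validated end-to-end against exact
ground truth.

## Worked example

`examples/simulate_and_recover.py` plants a study (60 precursors, 40
expected seed SNPs, enrichment odds ratio 2.5) and recovers it:

```
planted: 8 clusters, 24 seed SNPs (table {'a': 16, 'b': 32, 'c': 8, 'd': 64})
self-verification: clean
recovered enrichment table: {'a': 16, 'b': 32, 'c': 8, 'd': 64} (matches planted: True)
clustered miRNAs: 33.3% of seed-SNP carriers vs 11.1% of non-carriers, chi-square p = 0.00287
mean percent overlap: clustered 0.568 vs nonclustered 0.152, t-test p = 5.67e-19
planted pathway recovered as top ORA hit: PLANTED_PATHWAY
```

Reading: seed-SNP carriers are over-represented in clusters (33.3 % vs
11.1 % clustered, chi-square p ≈ 0.003), and substitutions in clustered
seeds leave target spectra much more intact (overlap 0.57 vs 0.15) — i.e.
a lower functional cost, consistent with functional complementarity among
co-clustered miRNAs. The other examples cover seed mapping
(`seed_snp_mapping.py`), allele-dependent prediction and the overlap score
(`allele_targets_overlap.py`) and the clustering rule plus the published
2×2 enrichment test (`clustering_enrichment.py`).

A thin CLI wraps the same library:

```bash
mirseed simulate --seed 1 --out sim/
mirseed run-all --gff sim/mirna.gff3 --mature-fasta sim/mirna_mature.fa \
    --vcf sim/snps.vcf --utr-fasta sim/utr.fa --mirna-sets sim/mirna_sets.gmt \
    --out results/
mirseed verify sim/
```

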