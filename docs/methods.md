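# Methods

## Model and procedure

miRNA-mediated repression hinges on Watson–Crick pairing between the seed
(mature positions 2–8) and complementary sites, mostly in 3′UTRs. A seed
SNP therefore changes which mRNAs a miRNA can repress. The analysis asks
two questions: (i) are miRNAs that carry seed SNPs distributed unevenly
with respect to genomic clustering, and (ii) is the *functional cost* of a
seed substitution — loss of previous targets plus gain of novel ones —
smaller in clustered miRNAs, as functional complementarity among
co-clustered, co-expressed miRNAs would predict?

The pipeline is deterministic end to end: seed mapping → clustering →
allele-dependent target prediction → percent overlap → inference.

### Seed coordinates and allele projection

All in-memory coordinates are 1-based inclusive (the GFF3/VCF convention);
conversion to 0-based half-open happens only inside the interval-tree
helper and at BED write time. On the + strand the seed is
`[start+1, start+7]`; on the − strand the mature's 5′ end sits at the
highest genomic coordinate, so the seed is `[end−7, end−1]`. A SNP at
forward position *p* has in-seed offset `p − start + 1` (+ strand) or
`end − p + 1` (− strand), counted 1..7 in miRNA sense. Because VCF alleles
are single bases, projection into miRNA sense on the − strand is a
complement (no reversal), followed by T→U. A SNP whose projected REF does
not equal the annotated seed base signals an annotation/genome-build
inconsistency; it is excluded with a warning, never force-substituted,
since substitution would fabricate a seed supported by neither input.

SNPs are counted per distinct rsID per mature (a multiallelic record is
one SNP in count tables) but analysed per ALT allele downstream. Rarity is
strict: rare ⇔ MAF < 0.05; records without a parseable frequency are
"unknown" and excluded from rare/common tabulations but still mapped.

### Target prediction

Prediction is canonical seed matching, with no context scoring,
conservation filtering or 3′-supplementary pairing. Writing M for the DNA
reverse complement of the 7 nt seed, the site classes searched on the
forward mRNA strand are `7mer-m8 = M`, `8mer = M + A`,
`7mer-A1 = M[2..7] + A` (reverse complement of seed positions 2–7 followed
by a genomic A — the A1 adenine is a sequence requirement, not a pairing),
and `6mer = M[2..7]`. The default enabled set is {8mer, 7mer-m8, 7mer-A1};
6mer sites, which are weak and noisy, are off by default but available.
Co-located matches collapse to the most specific class
(8mer > 7mer-m8 > 7mer-A1 > 6mer), keyed by the shared 6mer core so that,
e.g., an 8mer is not double-counted as its contained 7mers. A gene is a
target iff it has ≥ 1 enabled site; callers must pre-collapse UTR isoforms
to one sequence per gene.

### Percent overlap

For reference target set R and derived set D,
`percent_overlap = |R∩D| / √(|R|·|D|)` — the cosine similarity of the two
indicator vectors. The square root damps miRNAs with very many targets and
bounds the score in [0, 1]. When either set is empty the score is
*undefined* and excluded from aggregates (with a reported count) rather
than coded 0, which would bias means downward; a seed with no predicted
targets simply carries no overlap information. Multiallelic SNPs get one
score per ALT; per-SNP aggregation is the mean across alleles
(configurable to min/max). Because it is not stated whether published
aggregate overlaps were per SNP or per miRNA, the pipeline reports both
granularities.

### Clustering

Precursors (the unit of clustering) on one chromosome and strand chain
single-linkage: a precursor joins the open chain when its edge-to-edge gap
to the chain (`max(0, start − prev_end − 1)`, tracking the running maximum
end so nested loci behave) is ≤ 10,000 bp, boundary inclusive ("within
10 kb" read as ≤). Chains of ≥ 2 become clusters; singletons are
nonclustered; matures inherit the status of their precursor. The distance
convention of the original clustering annotation is not recoverable, so
the gap definition is switchable (`edge` | `start`) and `max_gap` is a
parameter; the edge-to-edge default is the most natural reading of
inter-locus distance. Single-linkage chaining is equivalent to the
transitive closure of the pairwise rule (property-tested against a
brute-force closure oracle).

### Inference

* **Enrichment**: the 2×2 of seed-SNP carriage × cluster status is tested
  with the Pearson chi-square (df = 1), continuity correction off by
  default — the published p-value (6.06 × 10⁻⁴ on the printed counts) is
  reproduced by the uncorrected statistic; Yates is available and is never
  larger. Zero-marginal tables are an error pointing to Fisher's exact
  test, except in the percentage summary where an all-clustered (or
  all-nonclustered) cohort degenerates to identical proportions and p = 1.
* **Functional effect**: two-sided two-sample *t*-test, pooled variance by
  default (a Welch switch exists). Samples that are both numerically
  constant are rejected as degenerate (detected with a relative variance
  tolerance, since constant float samples can show ~1e−34 variance from
  cancellation).
* **Pathway over-representation**: one-sided hypergeometric test per
  miRNA set (members intersected with the universe first),
  Benjamini–Hochberg adjusted across sets; raw p-values are also emitted
  because published pathway tables report raw p < 0.01.

## Synthetic data: what it emulates, and what it does not

The generator emits a scaled-down genome whose *statistical structure*
matches the real analysis: clusters whose internal gaps (default
500–9,500 bp) fall under the 10 kb rule while inter-locus gaps (default
50–200 kb) exceed it, so clustering is always exercised on both sides of
the boundary; seed SNPs planted at uniform offsets 1–7 on both strands,
with carriers enriched among clustered matures at a planted odds ratio;
a rare/common MAF mixture; and per-SNP target genes carrying exactly the
configured numbers of reference-only / derived-only / common 7mer-m8
sites, so each percent overlap is known in closed form.

Default conditions mirror the real study's observed proportions at roughly
1/15 scale: 120 precursors × 2 matures, ~42 % of matures carrying a seed
SNP (expected count 100), 97.5 % of MAFs below 5 %, ~20 % of precursors in
clusters of 2–4, enrichment odds ratio 1.5 (the published table implies
≈ 1.36), and planted overlap triples (3, 3, 4) for clustered vs (6, 6, 1)
for nonclustered carriers with ±1 per-SNP jitter — the jitter gives the
two overlap cohorts within-group variance, without which the *t*-test is
degenerate. `n_seed_snps` is an *expected* count: carriers are Bernoulli
draws at group-specific probabilities solved (by bisection) to hit the
expected total at the planted odds ratio. Exact allocation would be
wrong under the null — with an odds ratio of 1 the chi-square must reject
at ≈ α, which requires genuine sampling noise.

Exactness of planted target counts is guaranteed *collection-wide*, not
just per UTR: every UTR is screened against the patterns of every planted
allele, accidental matches removed by resampling their non-planted
positions (geometric convergence, bounded, with whole-UTR regeneration as
fallback); all reference and derived seeds are kept pairwise distinct, and
each planted 7-mer is checked against every other allele's patterns so a
gene dedicated to one SNP cannot surface as a target of another. At most
one seed SNP is planted per mature; multi-SNP matures are exercised in
unit tests rather than by the generator.

What the generator does **not** emulate: real chromosome lengths and gene
density, linkage disequilibrium, miRBase naming, sequence composition
biases (UTRs are i.i.d. uniform DNA), context scoring of the kind external
target-prediction services apply, or UTR isoform structure. Passing end-to-end tests therefore
demonstrates correctness of the *computations* — mapping arithmetic,
clustering, set overlap, test statistics — on data with known answers, not
that canonical seed matching reproduces any particular external
prediction tool on real transcriptomes. Genome-scale published values
(absolute SNP counts against specific dbSNP/miRBase releases, the 15.8 %
genome-wide mean overlap, specific pathway p-values) depend on database
versions and an external web service and are deliberately out of scope;
the printed 2×2 statistics and histogram identities are reproduced
exactly, and everything else is validated property-wise.

## Numerical choices and problem sizes

* Chi-square p-values come from the χ²₁ survival function; p is floored at
  the smallest positive double so the (0, 1] invariant holds.
* percent-overlap comparisons against closed-form ground truth use an
  absolute tolerance of 1e−12.
* The interval tree returns seed hits in sorted order, and all generator
  randomness flows through a single `numpy.random.default_rng(seed)`
  stream with fixed file write order, so outputs are byte-reproducible.
* Test-suite and acceptance problem sizes: oracle cross-checks use 500
  random layouts (clustering), 1000 SNPs × 100 seeds (mapping), 200 random
  tables (chi-square), 1000/200 null replicates (t/chi-square type-I
  error); exact-overlap recovery aggregates default-scale simulations
  until ≥ 500 planted SNPs are checked; the end-to-end recovery study uses
  300 precursors (600 matures), an expected 255 carriers at odds ratio 2.5
  and ~4,100 UTRs, sized to give the single-run chi-square ≈ 99.5 % power
  at α = 0.05.

## Known limitations

* Seed-match prediction is sequence-only; scores, conservation and site
  accessibility are out of scope, so absolute target counts are not
  comparable to scored predictors.
* The reader keeps all placements of rsIDs mapping to multiple loci
  (flagged); how such records were handled in the original annotation is
  unknown.
* A SNP overlapping two overlapping mature seeds yields one record per
  (SNP, mature) pair; both per-pair and per-rsID granularities are
  reported because the original counting convention is unstated.
* Exact reproduction of the published cluster census (99 clusters / 352
  genes / 634 matures) on a specific miRBase release is not claimed: the
  inherited clustering's distance convention is unknown, so clustering is
  always recomputed from the supplied annotation under the documented
  rule.
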