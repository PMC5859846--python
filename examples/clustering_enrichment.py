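"""Cluster miRNA genes by the 10 kb same-strand rule and test enrichment.

First clusters a toy chromosome layout (gaps straddling the 10 kb rule),
then reproduces the published enrichment analysis from its printed 2x2
counts: of 1226 miRNAs with a seed SNP, 314 are clustered; of 1587 without,
320 are clustered.
"""

from mirseedsnp import ContingencyTable2x2, MirnaPrecursor
from mirseedsnp.clustering import cluster_precursors
from mirseedsnp.stats import chi_square_2x2

layout = [
    MirnaPrecursor("MI1", "mir-a", "chr1", 10_000, 10_080, "+"),
    MirnaPrecursor("MI2", "mir-b", "chr1", 14_000, 14_090, "+"),   # 3.9 kb gap
    MirnaPrecursor("MI3", "mir-c", "chr1", 23_000, 23_085, "+"),   # 8.9 kb gap
    MirnaPrecursor("MI4", "mir-d", "chr1", 60_000, 60_070, "+"),   # 36.9 kb gap
    MirnaPrecursor("MI5", "mir-e", "chr1", 62_000, 62_075, "-"),   # near, other strand
]
clusters = cluster_precursors(layout, max_gap=10_000)
for c in clusters:
    print(f"{c.cluster_id}: {', '.join(c.member_precursor_ids)} "
          f"({c.chrom}:{c.span_start}-{c.span_end} {c.strand})")
print("mir-d is isolated (> 10 kb) and mir-e sits on the other strand, "
      "so neither joins the cluster.\n")

table = ContingencyTable2x2(a=314, b=1226 - 314, c=320, d=1587 - 320)
res = chi_square_2x2(table)
print(f"with seed SNP:    {table.a}/{table.a + table.b} clustered "
      f"({100 * table.a / (table.a + table.b):.1f}%)")
print(f"without seed SNP: {table.c}/{table.c + table.d} clustered "
      f"({100 * table.c / (table.c + table.d):.1f}%)")
print(f"chi-square = {res.statistic:.2f}, df = {res.df}, p = {res.p_value:.3g}")
print("\nSeed-SNP-carrying miRNAs are significantly over-represented in "
      "genomic clusters - consistent with clustered miRNAs tolerating seed "
      "variation through functional complementarity.")
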