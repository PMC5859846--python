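"""Generate a synthetic study with known ground truth and recover it.

The generator plants miRNA clusters, seed SNPs enriched in clustered
miRNAs (odds ratio 2.5 here), and per-SNP target sets whose percent
overlap is known in closed form; the full pipeline then re-derives all of
it from the emitted standard files alone.
"""

import tempfile
from pathlib import Path

from mirseedsnp.pipeline import PipelineConfig, run_full
from mirseedsnp.synthetic import SimulationConfig, simulate, verify_ground_truth

cfg = SimulationConfig(seed=42, n_precursors=60, n_seed_snps=40,
                       n_genes=700, enrichment_odds_ratio=2.5)
with tempfile.TemporaryDirectory() as td:
    simdir = Path(td) / "sim"
    gt = simulate(cfg, simdir)
    print(f"planted: {len(gt['clusters'])} clusters, "
          f"{len(gt['seed_snps'])} seed SNPs "
          f"(table {gt['enrichment_table']})")

    check = verify_ground_truth(simdir)
    print(f"self-verification: {'clean' if check['ok'] else check['discrepancies']}")

    report = run_full(PipelineConfig(
        gff_path=str(simdir / "mirna.gff3"),
        mature_fasta_path=str(simdir / "mirna_mature.fa"),
        vcf_path=str(simdir / "snps.vcf"),
        utr_fasta_path=str(simdir / "utr.fa"),
        mirna_sets_path=str(simdir / "mirna_sets.gmt"),
        output_dir=str(Path(td) / "run"),
    ))

enr = report["enrichment"]
print(f"\nrecovered enrichment table: {enr['table']} "
      f"(matches planted: {enr['table'] == gt['enrichment_table']})")
print(f"clustered miRNAs: {enr['pct_clustered_with_snp']}% of seed-SNP "
      f"carriers vs {enr['pct_clustered_without_snp']}% of non-carriers, "
      f"chi-square p = {enr['chi_square']['p_value']:.3g}")
ov = report["overlap"]
print(f"mean percent overlap: clustered "
      f"{ov['mean_by_cluster_status']['clustered']:.3f} vs nonclustered "
      f"{ov['mean_by_cluster_status']['nonclustered']:.3f}"
      + (f", t-test p = {ov['t_test_per_snp']['p_value']:.3g}"
         if ov["t_test_per_snp"] else ""))
print(f"planted pathway recovered as top ORA hit: "
      f"{report['ora']['clustered']['top_set']}")
print("\nBoth planted effects - enrichment of carriers in clusters and the "
      "higher overlap (lower functional cost) of clustered carriers - are "
      "recovered from the raw files.")
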