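"""Strand-aware mapping of SNPs into miRNA seed regions.

The seed of a mature miRNA is nucleotides 2-8 from its 5' end.  On the +
strand the 5' end is the lowest genomic coordinate, so the seed occupies
``[start+1, start+7]``; on the - strand the 5' end sits at the highest
coordinate and the seed occupies ``[end-7, end-1]``.  SNP alleles, reported
on the forward genomic strand by VCF convention, are projected into miRNA
sense: complemented (single bases, so no reversal) on the - strand, then
T -> U.
"""

from __future__ import annotations

import logging
from collections import Counter, defaultdict

from intervaltree import IntervalTree

from .records import (
    MatureMirna,
    Rarity,
    SeedInterval,
    SeedSnp,
    SnpRecord,
    complement_base,
    transcribe,
)

logger = logging.getLogger(__name__)

MAF_RARE_THRESHOLD = 0.05


def compute_seed_interval(mature: MatureMirna) -> SeedInterval:
    """Genomic interval of mature positions 2-8, strand-aware."""
    if mature.sequence is None:
        raise ValueError(f"mature {mature.id} has no sequence attached")
    if mature.strand == "+":
        start, end = mature.start + 1, mature.start + 7
    else:
        start, end = mature.end - 7, mature.end - 1
    return SeedInterval(
        mature_id=mature.id, chrom=mature.chrom, start=start, end=end,
        strand=mature.strand, seed_sequence=mature.sequence[1:8],
    )


def classify_rarity(snp: SnpRecord, threshold: float = MAF_RARE_THRESHOLD) -> Rarity:
    """Rare iff MAF strictly below the threshold; unknown when MAF is missing."""
    if snp.maf is None:
        return Rarity.UNKNOWN
    return Rarity.RARE if snp.maf < threshold else Rarity.COMMON


def project_allele(base_forward: str, strand: str) -> str:
    """Project a forward-strand DNA base into miRNA sense (RNA)."""
    b = base_forward if strand == "+" else complement_base(base_forward)
    return transcribe(b)


def map_snps_to_seeds(
    seeds: list[SeedInterval],
    snps: list[SnpRecord],
    maf_threshold: float = MAF_RARE_THRESHOLD,
) -> tuple[list[SeedSnp], dict]:
    """Intersect SNPs with seed intervals, one SeedSnp per (SNP, seed) pair.

    The seed offset is 1..7 in miRNA sense: ``pos - start + 1`` on the +
    strand, ``end - pos + 1`` on the - strand.  A pair is emitted only when
    the projected REF base equals the seed base at that offset; a mismatch
    signals an annotation/genome-build inconsistency and the pair is excluded
    with a warning rather than force-substituted.
    """
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    by_id = {}
    for sd in seeds:
        # interval tree uses half-open [start, end+1)
        trees[sd.chrom].addi(sd.start, sd.end + 1, sd)
        by_id[sd.mature_id] = sd

    out: list[SeedSnp] = []
    n_ref_mismatch = 0
    for snp in snps:
        tree = trees.get(snp.chrom)
        if tree is None:
            continue
        for iv in sorted(tree.at(snp.pos)):
            sd: SeedInterval = iv.data
            if sd.strand == "+":
                offset = snp.pos - sd.start + 1
            else:
                offset = sd.end - snp.pos + 1
            ref_sense = project_allele(snp.ref_allele, sd.strand)
            i = offset - 1
            if sd.seed_sequence[i] != ref_sense:
                logger.warning(
                    "SNP %s at %s:%d: projected REF %s != seed base %s of %s; excluded",
                    snp.rsid, snp.chrom, snp.pos, ref_sense, sd.seed_sequence[i],
                    sd.mature_id,
                )
                n_ref_mismatch += 1
                continue
            derived = tuple(
                (alt, sd.seed_sequence[:i] + project_allele(alt, sd.strand)
                 + sd.seed_sequence[i + 1:])
                for alt in snp.alt_alleles
            )
            out.append(SeedSnp(
                rsid=snp.rsid, mature_id=sd.mature_id, genomic_pos=snp.pos,
                seed_offset=offset, ref_seed=sd.seed_sequence,
                derived_seeds=derived, rarity=classify_rarity(snp, maf_threshold),
                maf=snp.maf,
            ))
    return out, {"n_reference_mismatch": n_ref_mismatch, "n_seed_snps": len(out)}


def snp_count_distribution(
    seed_snps: list[SeedSnp], all_matures: list[MatureMirna]
) -> dict[int, int]:
    """Per-mature histogram of distinct seed rsIDs, including zero-SNP matures.

    Sum of counts equals the number of matures; the k-weighted sum equals
    the number of distinct (mature, rsID) pairs.
    """
    per_mature: dict[str, set[str]] = defaultdict(set)
    for ss in seed_snps:
        per_mature[ss.mature_id].add(ss.rsid)
    hist: Counter[int] = Counter()
    for m in all_matures:
        hist[len(per_mature.get(m.id, ()))] += 1
    return dict(sorted(hist.items()))


def seed_snp_table_rows(seed_snps: list[SeedSnp], seeds: dict[str, SeedInterval]):
    """Rows for the per-SNP annotation TSV (one row per derived allele)."""
    for ss in seed_snps:
        sd = seeds[ss.mature_id]
        for alt, der in ss.derived_seeds:
            yield {
                "rsid": ss.rsid, "mature_id": ss.mature_id, "chrom": sd.chrom,
                "pos": ss.genomic_pos, "strand": sd.strand,
                "seed_offset": ss.seed_offset, "ref_seed": ss.ref_seed,
                "alt_allele": alt, "derived_seed": der,
                "maf": "" if ss.maf is None else ss.maf,
                "rarity": ss.rarity.value,
            }


def seed_intervals_to_bed(seeds: list[SeedInterval]) -> list[str]:
    """BED6 lines for seed intervals (0-based half-open conversion here only)."""
    return [
        f"{sd.chrom}\t{sd.start - 1}\t{sd.end}\t{sd.mature_id}\t0\t{sd.strand}"
        for sd in seeds
    ]
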