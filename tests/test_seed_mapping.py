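"""Seed-interval arithmetic, strand-aware SNP projection, and counting."""

import numpy as np
import pytest

from mirseedsnp.records import MatureMirna, Rarity, SnpRecord
from mirseedsnp.seed_mapping import (
    classify_rarity,
    compute_seed_interval,
    map_snps_to_seeds,
    snp_count_distribution,
)

RNA = "ACGU"


def _mature(i, chrom, start, end, strand, seq):
    return MatureMirna(id=f"M{i}", name=f"miR-{i}", precursor_id=f"P{i}",
                       chrom=chrom, start=start, end=end, strand=strand,
                       sequence=seq)


def test_seed_interval_plus_strand(let7_mature):
    """+ strand: mature positions 2-8 sit at [start+1, start+7]."""
    sd = compute_seed_interval(let7_mature)
    assert (sd.start, sd.end) == (1001, 1007)
    assert sd.seed_sequence == "GAGGUAG"


def test_seed_interval_minus_strand():
    """- strand: the 5' end is at the genomic end, seed at [end-7, end-1]."""
    m = _mature(1, "chr1", 1000, 1021, "-", "UGAGGUAGUAGGUUGUAUAGUU")
    sd = compute_seed_interval(m)
    assert (sd.start, sd.end) == (1014, 1020)
    assert sd.seed_sequence == "GAGGUAG"


@pytest.mark.parametrize("strand,start,end", [("+", 500, 521), ("-", 500, 521)])
def test_seed_interval_always_7nt(strand, start, end):
    m = _mature(1, "chr2", start, end, strand, "UGAGGUAGUAGGUUGUAUAGUU")
    sd = compute_seed_interval(m)
    assert sd.end - sd.start + 1 == 7


def test_snp_offset_and_ref_match_plus_strand(let7_mature):
    """SNP at chr1:1003 (REF=G) hits seed offset 3 of the + strand seed."""
    sd = compute_seed_interval(let7_mature)
    snp = SnpRecord(rsid="rs1", chrom="chr1", pos=1003, ref_allele="G",
                    alt_alleles=("A",))
    hits, meta = map_snps_to_seeds([sd], [snp])
    assert len(hits) == 1 and meta["n_reference_mismatch"] == 0
    h = hits[0]
    assert h.seed_offset == 3
    assert h.ref_seed == "GAGGUAG"
    assert h.derived_seeds == (("A", "GAAGUAG"),)


def test_snp_projection_minus_strand_complements():
    """On the - strand forward REF/ALT are complemented (not reversed) into
    miRNA sense: forward A under a seed U, ALT C becomes G in the seed."""
    m = _mature(1, "chr1", 1000, 1021, "-", "UGAGGUAGUAGGUUGUAUAGUU")
    sd = compute_seed_interval(m)
    # offset 5 in miRNA sense = genomic position end - 5 + 1 - ... ; seed base U
    # seed GAGGUAG, offset 5 -> U; genomic pos = sd.end - 5 + 1 = 1016
    snp = SnpRecord(rsid="rs2", chrom="chr1", pos=1016, ref_allele="A",
                    alt_alleles=("C",))
    hits, _ = map_snps_to_seeds([sd], [snp])
    assert len(hits) == 1
    h = hits[0]
    assert h.seed_offset == 5
    assert h.ref_seed[4] == "U"
    assert h.derived_seeds[0][1][4] == "G"


def test_reference_mismatch_is_excluded(let7_mature):
    sd = compute_seed_interval(let7_mature)
    snp = SnpRecord(rsid="rs3", chrom="chr1", pos=1003, ref_allele="T",
                    alt_alleles=("A",))  # seed base there is G
    hits, meta = map_snps_to_seeds([sd], [snp])
    assert hits == [] and meta["n_reference_mismatch"] == 1


def _random_instance(rng, n_seeds=100, n_snps=1000, genome=50_000):
    matures, positions = [], set()
    i = 0
    while len(matures) < n_seeds:
        i += 1
        start = int(rng.integers(1, genome))
        strand = "+" if rng.integers(2) else "-"
        seq = "".join(RNA[k] for k in rng.integers(0, 4, 22))
        m = _mature(i, f"chr{int(rng.integers(1, 4))}", start, start + 21,
                    strand, seq)
        matures.append(m)
    seeds = [compute_seed_interval(m) for m in matures]
    snps = []
    for j in range(n_snps):
        chrom = f"chr{int(rng.integers(1, 4))}"
        pos = int(rng.integers(1, genome + 22))
        ref = "ACGT"[int(rng.integers(4))]
        alt = rng.choice([b for b in "ACGT" if b != ref])
        snps.append(SnpRecord(rsid=f"rs{j}", chrom=chrom, pos=pos,
                              ref_allele=ref, alt_alleles=(str(alt),)))
    return seeds, snps


def _naive_pairs(seeds, snps):
    """Brute-force double loop over every (SNP, seed) pair."""
    from mirseedsnp.seed_mapping import project_allele
    out = set()
    for snp in snps:
        for sd in seeds:
            if snp.chrom != sd.chrom or not sd.start <= snp.pos <= sd.end:
                continue
            offset = (snp.pos - sd.start + 1 if sd.strand == "+"
                      else sd.end - snp.pos + 1)
            if sd.seed_sequence[offset - 1] == project_allele(
                    snp.ref_allele, sd.strand):
                out.add((snp.rsid, sd.mature_id, offset))
    return out


def test_mapping_agrees_with_naive_double_loop_oracle():
    """Interval-indexed mapping equals exhaustive enumeration of all pairs
    (>= 1000 SNPs x 100 seeds, random strands and chromosomes)."""
    rng = np.random.default_rng(42)
    seeds, snps = _random_instance(rng)
    hits, _ = map_snps_to_seeds(seeds, snps)
    got = {(h.rsid, h.mature_id, h.seed_offset) for h in hits}
    assert got == _naive_pairs(seeds, snps)
    assert got, "oracle instance produced no overlaps; enlarge the instance"


def test_strand_mirror_property():
    """Mirroring coordinates (x -> L+1-x), flipping strands and complementing
    forward alleles yields identical seed offsets and derived seeds."""
    L = 100_000
    from mirseedsnp.records import DNA_COMPLEMENT, SeedInterval
    rng = np.random.default_rng(7)
    seeds2, snps2 = _random_instance(rng, n_seeds=40, n_snps=400,
                                     genome=10_000)
    hits, _ = map_snps_to_seeds(seeds2, snps2)
    m_seeds = [
        SeedInterval(mature_id=sd.mature_id, chrom=sd.chrom,
                     start=L + 1 - sd.end, end=L + 1 - sd.start,
                     strand="-" if sd.strand == "+" else "+",
                     seed_sequence=sd.seed_sequence)
        for sd in seeds2
    ]
    m_snps = [
        SnpRecord(rsid=s.rsid, chrom=s.chrom, pos=L + 1 - s.pos,
                  ref_allele=DNA_COMPLEMENT[s.ref_allele],
                  alt_alleles=tuple(DNA_COMPLEMENT[a] for a in s.alt_alleles))
        for s in snps2
    ]
    m_hits, _ = map_snps_to_seeds(m_seeds, m_snps)
    key = lambda hs: {(h.rsid, h.mature_id, h.seed_offset, h.ref_seed,
                       tuple(d for _, d in h.derived_seeds)) for h in hs}
    assert key(m_hits) == key(hits)


def test_derived_seed_reconstruction_property():
    """Substituting the projected ALT at seed_offset reproduces each derived seed."""
    rng = np.random.default_rng(3)
    seeds, snps = _random_instance(rng, n_seeds=60, n_snps=600, genome=20_000)
    hits, _ = map_snps_to_seeds(seeds, snps)
    assert hits
    from mirseedsnp.seed_mapping import project_allele
    sd_strand = {sd.mature_id: sd.strand for sd in seeds}
    for h in hits:
        i = h.seed_offset - 1
        for alt_fwd, der in h.derived_seeds:
            expected = (h.ref_seed[:i]
                        + project_allele(alt_fwd, sd_strand[h.mature_id])
                        + h.ref_seed[i + 1:])
            assert der == expected


def test_snp_count_distribution_matches_reported_histogram():
    """The per-miRNA histogram 1587/749/340/102/31/4 for 0..5 SNPs implies
    1226 miRNAs with SNPs and 1879 (mature, SNP) pairs."""
    hist = {0: 1587, 1: 749, 2: 340, 3: 102, 4: 31, 5: 4}
    assert sum(hist.values()) == 2813
    assert sum(k * n for k, n in hist.items()) == 1879
    assert sum(n for k, n in hist.items() if k > 0) == 1226


def test_snp_count_distribution_counts_all_matures(let7_mature):
    """Zero-SNP matures are included; distinct rsIDs counted per mature."""
    sd = compute_seed_interval(let7_mature)
    other = _mature(2, "chr9", 100, 121, "+", "UGAGGUAGUAGGUUGUAUAGUU")
    snps = [
        SnpRecord(rsid="rs1", chrom="chr1", pos=1003, ref_allele="G",
                  alt_alleles=("A",)),
        SnpRecord(rsid="rs2", chrom="chr1", pos=1004, ref_allele="G",
                  alt_alleles=("C", "T")),  # multiallelic: one distinct rsID
    ]
    hits, _ = map_snps_to_seeds([sd], snps)
    dist = snp_count_distribution(hits, [let7_mature, other])
    assert dist == {0: 1, 2: 1}


def test_no_snps_distribution(let7_mature):
    assert snp_count_distribution([], [let7_mature]) == {0: 1}


@pytest.mark.parametrize("maf,expected", [
    (0.049, Rarity.RARE),
    (0.05, Rarity.COMMON),   # boundary: strict <
    (None, Rarity.UNKNOWN),
])
def test_rarity_classification(maf, expected):
    snp = SnpRecord(rsid="rs1", chrom="chr1", pos=1, ref_allele="A",
                    alt_alleles=("G",), maf=maf)
    assert classify_rarity(snp) is expected
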