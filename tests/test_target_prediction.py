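"""Canonical seed-match patterns and target-set prediction."""

import numpy as np
import pytest

from mirseedsnp.records import SeedSnp, SiteType
from mirseedsnp.target_prediction import (
    allele_dependent_targets,
    predict_targets,
    seed_match_patterns,
)

ALL_TYPES = frozenset(SiteType)


def test_patterns_for_let7_seed():
    """For seed GAGGUAG (let-7): 7mer-m8 = CTACCTC, 8mer adds the A1 adenine,
    7mer-A1 pairs seed positions 2-7 plus A, 6mer is the bare 2-7 match."""
    pats = seed_match_patterns("GAGGUAG")
    assert pats[SiteType.SEVENMER_M8] == "CTACCTC"
    assert pats[SiteType.EIGHTMER] == "CTACCTCA"
    assert pats[SiteType.SEVENMER_A1] == "TACCTCA"
    assert pats[SiteType.SIXMER] == "TACCTC"


def test_pattern_structure_for_random_seeds():
    """8mer = 7mer-m8 + A; 7mer-A1 = 6mer + A; 6mer is the m8 pattern minus
    its first (position-8) base — for any seed."""
    rng = np.random.default_rng(0)
    for _ in range(50):
        seed = "".join("ACGU"[k] for k in rng.integers(0, 4, 7))
        p = seed_match_patterns(seed)
        assert p[SiteType.EIGHTMER] == p[SiteType.SEVENMER_M8] + "A"
        assert p[SiteType.SEVENMER_A1] == p[SiteType.SIXMER] + "A"
        assert p[SiteType.SIXMER] == p[SiteType.SEVENMER_M8][1:]


def test_invalid_seed_alphabet_is_fatal():
    with pytest.raises(ValueError):
        seed_match_patterns("GAGGTAG")  # DNA letters


def test_prediction_example_utr():
    """UTR AAACTACCTCAAA carries CTACCTC at 1-based position 4."""
    ts = predict_targets("GAGGUAG", {"g1": "AAACTACCTCAAA"},
                         frozenset({SiteType.SEVENMER_M8}))
    assert ts.genes == {"g1"}
    assert ts.sites["g1"] == [(4, SiteType.SEVENMER_M8)]


def test_no_match_means_no_target():
    ts = predict_targets("GAGGUAG", {"g1": "TTTTTTTTTTTT"})
    assert ts.genes == set()


def test_8mer_requires_trailing_adenine():
    """CTACCTCG has no A1 adenine: not a target under {8mer} alone."""
    ts = predict_targets("GAGGUAG", {"g1": "AACTACCTCGAA"},
                         frozenset({SiteType.EIGHTMER}))
    assert ts.genes == set()


def test_site_collapse_to_most_specific():
    """An 8mer locus also matches 7mer-m8 and 7mer-A1; with all types enabled
    it is reported once, as the 8mer."""
    ts = predict_targets("GAGGUAG", {"g1": "AACTACCTCAAA"}, ALL_TYPES)
    assert ts.sites["g1"] == [(3, SiteType.EIGHTMER)]


def test_monotonicity_in_enabled_site_types():
    """Enlarging the enabled set never shrinks the target gene set."""
    rng = np.random.default_rng(1)
    utrs = {f"g{i}": "".join("ACGT"[k] for k in rng.integers(0, 4, 300))
            for i in range(60)}
    seed = "GAGGUAG"
    small = predict_targets(seed, utrs, frozenset({SiteType.EIGHTMER}))
    mid = predict_targets(seed, utrs,
                          frozenset({SiteType.EIGHTMER, SiteType.SEVENMER_M8}))
    full = predict_targets(seed, utrs, ALL_TYPES)
    assert small.genes <= mid.genes <= full.genes


def test_pattern_containment_across_types():
    """8mer targets are a subset of 7mer-m8 targets and of 7mer-A1 targets
    when each type is enabled alone."""
    rng = np.random.default_rng(2)
    utrs = {f"g{i}": "".join("ACGT"[k] for k in rng.integers(0, 4, 500))
            for i in range(80)}
    for seed in ("GAGGUAG", "ACGUACG", "UUUGCAC"):
        t8 = predict_targets(seed, utrs, frozenset({SiteType.EIGHTMER})).genes
        tm8 = predict_targets(seed, utrs, frozenset({SiteType.SEVENMER_M8})).genes
        ta1 = predict_targets(seed, utrs, frozenset({SiteType.SEVENMER_A1})).genes
        assert t8 <= tm8 and t8 <= ta1


def _sliding_window_oracle(seed, utr, enabled):
    """Regex-free re-derivation: check every window against first principles.

    A window of length 7 starting at i is a 7mer-m8 site iff it equals the
    reverse complement of the seed; the A1 variants are checked against the
    seed's positions 2-7 plus a literal A.
    """
    comp = {"A": "T", "C": "G", "G": "C", "U": "A"}
    rc7 = "".join(comp[b] for b in reversed(seed))
    rc6 = "".join(comp[b] for b in reversed(seed[:6]))
    hit = False
    n = len(utr)
    for i in range(n):
        if SiteType.SEVENMER_M8 in enabled and utr[i:i + 7] == rc7:
            hit = True
        if SiteType.EIGHTMER in enabled and utr[i:i + 8] == rc7 + "A":
            hit = True
        if SiteType.SEVENMER_A1 in enabled and utr[i:i + 7] == rc6 + "A":
            hit = True
        if SiteType.SIXMER in enabled and utr[i:i + 6] == rc6:
            hit = True
    return hit


def test_agreement_with_sliding_window_oracle():
    """Prediction agrees with a naive window-by-window oracle on random UTRs
    (> 10^4 windows), for several enabled-type combinations."""
    rng = np.random.default_rng(3)
    # short UTRs + a planted site in some to get both outcomes
    utrs = {}
    for i in range(150):
        s = "".join("ACGT"[k] for k in rng.integers(0, 4, 120))
        if i % 3 == 0:
            p = int(rng.integers(0, 110))
            s = s[:p] + "CTACCTC" + s[p + 7:]
        utrs[f"g{i}"] = s
    combos = [frozenset({SiteType.SEVENMER_M8}),
              frozenset({SiteType.EIGHTMER, SiteType.SEVENMER_A1}),
              ALL_TYPES]
    for seed in ("GAGGUAG", "CCAUCGA"):
        for enabled in combos:
            ts = predict_targets(seed, utrs, enabled)
            expected = {g for g, u in utrs.items()
                        if _sliding_window_oracle(seed, u, enabled)}
            assert ts.genes == expected


def _seed_snp(n_alts=1):
    ref = "GAGGUAG"
    alts = [("A", "GAGAUAG"), ("C", "GAGCUAG")][:n_alts]
    return SeedSnp(rsid="rs1", mature_id="M1", genomic_pos=100, seed_offset=4,
                   ref_seed=ref, derived_seeds=tuple(alts))


def test_allele_dependent_prediction_is_allele_specific():
    """A UTR carrying only the reference pattern is dropped from the derived
    target set."""
    utrs = {"refonly": "AAACTACCTCAAA",    # matches ref (CTACCTC)
            "deronly": "AAACTATCTCAAA"}    # matches derived GAGAUAG (CTATCTC)
    ref, ders = allele_dependent_targets(_seed_snp(), utrs,
                                         frozenset({SiteType.SEVENMER_M8}))
    assert ref.genes == {"refonly"}
    assert ders[0].genes == {"deronly"}


def test_two_alt_alleles_give_two_derived_sets():
    _, ders = allele_dependent_targets(_seed_snp(n_alts=2), {"g": "ACGTACGT"})
    assert len(ders) == 2
    assert [d.allele_label for d in ders] == ["derived:A", "derived:C"]


def test_prediction_is_deterministic():
    rng = np.random.default_rng(4)
    utrs = {f"g{i}": "".join("ACGT"[k] for k in rng.integers(0, 4, 200))
            for i in range(40)}
    a = predict_targets("GAGGUAG", utrs)
    b = predict_targets("GAGGUAG", utrs)
    assert a.genes == b.genes and a.sites == b.sites
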