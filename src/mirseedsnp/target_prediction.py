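"""Allele-dependent target prediction by canonical seed matching.

A gene is called a target of a seed allele when its 3'UTR carries at least
one enabled canonical site.  Writing M for the reverse complement of the
7 nt seed in DNA (M left-to-right pairs mature positions 8..2):

* ``7mer-m8``: M itself (perfect match to seed positions 2-8);
* ``8mer``:    M followed by A (the A1 adenine);
* ``7mer-A1``: M without its first base (match to positions 2-7) followed by A;
* ``6mer``:    M without its first base (match to positions 2-7 only).

The A1 position is required to be a genomic A in the UTR, following the
canonical site-type definition, not a pairing requirement.  Matching is on
the forward mRNA (UTR) strand in DNA space; there is no context scoring,
conservation filter or 3'-supplementary pairing.  Overlapping matches of
different types at the same 6mer core collapse to the most specific type
(8mer > 7mer-m8 > 7mer-A1 > 6mer).
"""

from __future__ import annotations

import logging

from Bio.Seq import Seq

from .records import (
    DEFAULT_SITE_TYPES,
    RNA_ALPHABET,
    SITE_TYPE_RANK,
    SeedSnp,
    SiteType,
    TargetSet,
    reverse_transcribe,
)

logger = logging.getLogger(__name__)


def seed_match_patterns(seed: str) -> dict[SiteType, str]:
    """DNA patterns searched in the UTR for each canonical site type."""
    if set(seed) - RNA_ALPHABET or len(seed) != 7:
        raise ValueError(f"seed must be 7 nt RNA, got {seed!r}")
    m = str(Seq(reverse_transcribe(seed)).reverse_complement())
    return {
        SiteType.SEVENMER_M8: m,
        SiteType.EIGHTMER: m + "A",
        SiteType.SEVENMER_A1: m[1:] + "A",
        SiteType.SIXMER: m[1:],
    }


def _core_start(site_type: SiteType, match_start: int) -> int:
    """Start of the shared 6mer core (pairs seed positions 2-7) for a match."""
    if site_type in (SiteType.SEVENMER_M8, SiteType.EIGHTMER):
        return match_start + 1
    return match_start


def _find_all(pattern: str, text: str) -> list[int]:
    hits, i = [], text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def predict_targets(
    seed: str,
    utrs: dict[str, str],
    enabled_site_types: frozenset[SiteType] = DEFAULT_SITE_TYPES,
    allele_label: str = "reference",
) -> TargetSet:
    """Scan every UTR for enabled site types of one seed allele.

    Site positions are recorded 1-based (start of the matched pattern);
    co-located matches keep only the most specific type.
    """
    if not enabled_site_types:
        raise ValueError("enabled_site_types must be non-empty")
    if not utrs:
        logger.warning("empty UTR collection: no targets can be predicted")
        return TargetSet(seed=seed, allele_label=allele_label)
    patterns = seed_match_patterns(seed)
    ts = TargetSet(seed=seed, allele_label=allele_label)
    for gene_id, utr in utrs.items():
        best: dict[int, tuple[SiteType, int]] = {}  # core -> (type, match start)
        for st in sorted(enabled_site_types, key=lambda s: SITE_TYPE_RANK[s]):
            for start0 in _find_all(patterns[st], utr):
                core = _core_start(st, start0)
                if core not in best:  # types scanned most-specific first
                    best[core] = (st, start0)
        if best:
            ts.genes.add(gene_id)
            ts.sites[gene_id] = sorted(
                (start0 + 1, st) for st, start0 in best.values()
            )
    return ts


def allele_dependent_targets(
    seed_snp: SeedSnp,
    utrs: dict[str, str],
    enabled_site_types: frozenset[SiteType] = DEFAULT_SITE_TYPES,
) -> tuple[TargetSet, list[TargetSet]]:
    """Targets of the reference seed and of each derived (ALT-substituted) seed."""
    ref = predict_targets(seed_snp.ref_seed, utrs, enabled_site_types, "reference")
    derived = [
        predict_targets(der_seed, utrs, enabled_site_types, f"derived:{alt}")
        for alt, der_seed in seed_snp.derived_seeds
    ]
    return ref, derived


def target_table_rows(ts: TargetSet):
    """Rows for the per-allele target TSV."""
    for gene_id in sorted(ts.genes):
        sites = ts.sites[gene_id]
        best = min(sites, key=lambda s: SITE_TYPE_RANK[s[1]])[1]
        yield {
            "gene_id": gene_id,
            "allele": ts.allele_label,
            "n_sites": len(sites),
            "best_site_type": best.value,
            "positions": ";".join(str(p) for p, _ in sites),
        }
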