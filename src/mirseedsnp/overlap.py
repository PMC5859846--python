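"""Cosine percent overlap between reference and derived target sets.

percent_overlap = |R ∩ D| / sqrt(|R| · |D|), the cosine similarity of the
two target sets viewed as indicator vectors.  The square root damps the
influence of seeds with abnormally many targets and bounds the score in
[0, 1]: 1 means identical target spectra, 0 disjoint ones.  A lower value
means a larger functional effect of the seed substitution (more regulatory
control lost and/or gained).  When either set is empty the score is
undefined (None) rather than 0: a seed with no predicted targets carries no
overlap information, and coding it as 0 would bias aggregates downward.
"""

from __future__ import annotations

import math
import statistics
from dataclasses import dataclass

from .records import OverlapResult, SeedSnp, TargetSet


def percent_overlap(ref_targets: set[str], der_targets: set[str]) -> float | None:
    """|R∩D| / sqrt(|R|·|D|); None when either set is empty; symmetric."""
    n_ref, n_der = len(ref_targets), len(der_targets)
    if n_ref == 0 or n_der == 0:
        return None
    return len(ref_targets & der_targets) / math.sqrt(n_ref * n_der)


def overlap_result(
    seed_snp: SeedSnp, ref: TargetSet, der: TargetSet, alt_allele: str
) -> OverlapResult:
    return OverlapResult(
        rsid=seed_snp.rsid, mature_id=seed_snp.mature_id, alt_allele=alt_allele,
        n_ref=len(ref.genes), n_der=len(der.genes),
        n_common=len(ref.genes & der.genes),
        percent_overlap=percent_overlap(ref.genes, der.genes),
    )


@dataclass(frozen=True)
class OverlapSummary:
    mean: float | None
    median: float | None
    n_defined: int
    n_undefined: int


def summarize_overlaps(results: list[OverlapResult]) -> OverlapSummary:
    """Mean/median over defined results only; undefined ones counted alongside."""
    defined = [r.percent_overlap for r in results if r.percent_overlap is not None]
    n_undef = len(results) - len(defined)
    if not defined:
        return OverlapSummary(mean=None, median=None, n_defined=0, n_undefined=n_undef)
    return OverlapSummary(
        mean=statistics.fmean(defined), median=statistics.median(defined),
        n_defined=len(defined), n_undefined=n_undef,
    )


def per_snp_overlap(
    results: list[OverlapResult], aggregate: str = "mean"
) -> dict[tuple[str, str], float]:
    """One value per (rsid, mature): multiallelic SNPs aggregated across alleles.

    ``aggregate`` is ``mean`` (default), ``min`` or ``max``; undefined
    alleles are excluded, and a SNP whose alleles are all undefined is
    omitted.
    """
    agg = {"mean": statistics.fmean, "min": min, "max": max}[aggregate]
    by_snp: dict[tuple[str, str], list[float]] = {}
    for r in results:
        if r.percent_overlap is not None:
            by_snp.setdefault((r.rsid, r.mature_id), []).append(r.percent_overlap)
    return {k: agg(v) for k, v in by_snp.items()}


def overlap_table_rows(results: list[OverlapResult]):
    for r in results:
        yield {
            "rsid": r.rsid, "mature_id": r.mature_id, "alt_allele": r.alt_allele,
            "n_ref": r.n_ref, "n_der": r.n_der, "n_common": r.n_common,
            "percent_overlap": "NA" if r.percent_overlap is None
            else f"{r.percent_overlap:.6f}",
        }
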