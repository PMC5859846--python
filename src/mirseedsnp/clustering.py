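"""Genomic clustering of miRNA precursors by the 10 kb same-strand rule.

Two neighboring precursors belong to the same cluster when they lie on the
same chromosome and strand within ``max_gap`` (default 10,000 bp, boundary
inclusive).  Chaining is single-linkage: A-B <= 10 kb and B-C <= 10 kb puts
A, B, C in one cluster even if A-C > 10 kb, matching standard genomic-
cluster practice.  Distance is the edge-to-edge gap between precursor
intervals by default (``max(0, next.start - prev.end - 1)``); a
start-to-start mode is available for comparison with annotations that used
that convention.  Chains of length >= 2 become clusters; singletons are
non-clustered.
"""

from __future__ import annotations

from collections import defaultdict
from typing import Literal

from .records import Cluster, MatureMirna, MirnaPrecursor

DEFAULT_MAX_GAP = 10_000

DistanceMode = Literal["edge", "start"]


def _gap(prev_end: int, prev_start: int, cur: MirnaPrecursor, mode: DistanceMode) -> int:
    if mode == "edge":
        return max(0, cur.start - prev_end - 1)
    return cur.start - prev_start


def cluster_precursors(
    precursors: list[MirnaPrecursor],
    max_gap: int = DEFAULT_MAX_GAP,
    distance_mode: DistanceMode = "edge",
) -> list[Cluster]:
    """Single-linkage chains per (chrom, strand); gap <= max_gap joins the chain."""
    groups: dict[tuple[str, str], list[MirnaPrecursor]] = defaultdict(list)
    for p in precursors:
        groups[(p.chrom, p.strand)].append(p)

    clusters: list[Cluster] = []
    for (chrom, strand) in sorted(groups):
        members = sorted(groups[(chrom, strand)], key=lambda p: (p.start, p.end, p.id))
        chain: list[MirnaPrecursor] = []
        chain_end = -1  # max end seen in the open chain (handles nesting)
        for p in members:
            if chain and _gap(chain_end, chain[-1].start, p, distance_mode) <= max_gap:
                chain.append(p)
                chain_end = max(chain_end, p.end)
            else:
                if len(chain) >= 2:
                    clusters.append(_make_cluster(chain, chrom, strand, len(clusters)))
                chain = [p]
                chain_end = p.end
        if len(chain) >= 2:
            clusters.append(_make_cluster(chain, chrom, strand, len(clusters)))
    return clusters


def _make_cluster(chain: list[MirnaPrecursor], chrom: str, strand: str, idx: int) -> Cluster:
    return Cluster(
        cluster_id=f"cluster_{idx + 1:04d}",
        chrom=chrom, strand=strand,
        member_precursor_ids=tuple(p.id for p in chain),
        span_start=min(p.start for p in chain),
        span_end=max(p.end for p in chain),
    )


def mature_cluster_status(
    matures: list[MatureMirna], clusters: list[Cluster]
) -> dict[str, str]:
    """Map mature_id -> 'clustered'/'nonclustered' via its precursor's membership."""
    clustered_precursors = {
        pid for c in clusters for pid in c.member_precursor_ids
    }
    return {
        m.id: "clustered" if m.precursor_id in clustered_precursors else "nonclustered"
        for m in matures
    }


def cluster_table_rows(clusters: list[Cluster]):
    for c in clusters:
        yield {
            "cluster_id": c.cluster_id, "chrom": c.chrom, "strand": c.strand,
            "span_start": c.span_start, "span_end": c.span_end,
            "n_members": len(c.member_precursor_ids),
            "members": ";".join(c.member_precursor_ids),
        }


def clusters_to_bed(clusters: list[Cluster]) -> list[str]:
    return [
        f"{c.chrom}\t{c.span_start - 1}\t{c.span_end}\t{c.cluster_id}\t0\t{c.strand}"
        for c in clusters
    ]
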