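"""Synthetic input generator with exact ground truth for every pipeline stage.

The generator emits a small self-contained "genome" as the five input files
the pipeline consumes (miRBase-dialect GFF3, mature FASTA, VCF v4.2, 3'UTR
FASTA, GMT-like miRNA-set file) plus a ``ground_truth.json`` recording
everything that was planted:

* precursor layout with planted clusters whose internal gaps fall below the
  10 kb rule and inter-locus gaps far above it, so clustering is exercised
  on both sides of the boundary;
* seed SNPs planted at uniformly chosen seed offsets on both strands, with
  clustered matures carrying SNPs at a configurable planted odds ratio
  relative to nonclustered ones, and MAFs drawn from a rare/common mixture;
* per-SNP target genes with exactly the configured numbers of
  reference-only / derived-only / common seed-match sites (injected as
  7mer-m8 matches), so the cosine percent overlap of every planted SNP is
  known in closed form.

Exactness is guaranteed collection-wide: every UTR is screened against the
seed-match patterns of *every* planted allele (not just its own), accidental
matches being removed by locally resampling non-planted positions; all
reference and derived seeds are kept pairwise distinct, and each planted
7-mer site is checked against all other alleles' patterns, so a gene
dedicated to one SNP can never surface as a target of another.

All randomness flows from the single config seed through one
``numpy.random.default_rng`` stream and the file write order is fixed, so a
given config reproduces byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as mio
from .clustering import cluster_precursors, mature_cluster_status
from .overlap import percent_overlap
from .records import (
    ContingencyTable2x2,
    MatureMirna,
    MirnaPrecursor,
    MirnaSetAnnotation,
    SnpRecord,
    complement_base,
    reverse_transcribe,
    transcribe,
)
from .seed_mapping import compute_seed_interval, map_snps_to_seeds
from .target_prediction import allele_dependent_targets, seed_match_patterns

logger = logging.getLogger(__name__)

RNA_BASES = "ACGU"
DNA_BASES = "ACGT"

GROUND_TRUTH_FILE = "ground_truth.json"
FILE_NAMES = {
    "gff": "mirna.gff3",
    "mature_fasta": "mirna_mature.fa",
    "vcf": "snps.vcf",
    "utr_fasta": "utr.fa",
    "mirna_sets": "mirna_sets.gmt",
}


class ConfigError(ValueError):
    """The requested simulation is internally impossible."""


@dataclass(frozen=True)
class MafMixture:
    """Rare/common MAF mixture: rare MAFs are scaled Beta draws below 0.05,
    common ones Beta draws mapped into [0.05, 0.5]."""

    fraction_rare: float = 0.975
    rare_beta: tuple[float, float] = (1.0, 3.0)
    common_beta: tuple[float, float] = (1.0, 1.0)
    fraction_missing: float = 0.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic dataset (scaled-down human-like)."""

    seed: int = 0
    n_chromosomes: int = 3
    n_precursors: int = 120
    cluster_fraction: float = 0.20
    cluster_size_range: tuple[int, int] = (2, 4)
    intra_cluster_gap_range: tuple[int, int] = (500, 9_500)
    inter_locus_gap_range: tuple[int, int] = (50_000, 200_000)
    matures_per_precursor: int = 2
    n_seed_snps: int = 100            # expected count under enrichment planting
    n_background_snps: int = 150
    maf_distribution: MafMixture = field(default_factory=MafMixture)
    enrichment_odds_ratio: float = 1.5
    n_genes: int = 1_600
    utr_length_range: tuple[int, int] = (300, 800)
    planted_overlap_spec: dict = field(default_factory=lambda: {
        "clustered": (3, 3, 4),      # (n_ref_only, n_der_only, n_common)
        "nonclustered": (6, 6, 1),
    })
    overlap_count_jitter: int = 1    # per-SNP +/- jitter on each planted count

    def validate(self) -> None:
        if self.n_chromosomes < 1 or self.n_precursors < 1:
            raise ConfigError("need at least one chromosome and one precursor")
        if not 0.0 <= self.cluster_fraction <= 1.0:
            raise ConfigError("cluster_fraction must be in [0, 1]")
        if self.matures_per_precursor not in (1, 2):
            raise ConfigError("matures_per_precursor must be 1 or 2")
        if self.intra_cluster_gap_range[1] > 10_000:
            raise ConfigError("intra-cluster gaps must stay within the 10 kb rule")
        if self.inter_locus_gap_range[0] <= 10_000:
            raise ConfigError("inter-locus gaps must exceed the 10 kb rule")
        lo, hi = self.cluster_size_range
        if lo < 2 or hi < lo:
            raise ConfigError("cluster sizes must be >= 2")
        n_matures = self.n_precursors * self.matures_per_precursor
        if self.n_seed_snps >= n_matures:
            raise ConfigError(
                f"n_seed_snps={self.n_seed_snps} must be below the number of "
                f"matures ({n_matures}) for enrichment planting"
            )
        for grp in ("clustered", "nonclustered"):
            spec = self.planted_overlap_spec.get(grp)
            if spec is None or len(spec) != 3 or min(spec) < 0:
                raise ConfigError(f"planted_overlap_spec[{grp!r}] must be 3 counts")
        if self.overlap_count_jitter < 0:
            raise ConfigError("overlap_count_jitter must be >= 0")
        max_genes_per_snp = max(sum(self.planted_overlap_spec[g])
                                for g in ("clustered", "nonclustered"))
        max_genes_per_snp += 3 * self.overlap_count_jitter
        if self.n_genes < self.n_seed_snps * max_genes_per_snp:
            raise ConfigError(
                "n_genes is too small for the planted per-SNP target counts "
                "(more planted sites than UTR capacity)"
            )
        if self.utr_length_range[0] < 30:
            raise ConfigError("UTRs shorter than 30 nt cannot hold planted sites")


# ---------------------------------------------------------------------------
# internal generation pieces
# ---------------------------------------------------------------------------

def _rand_seq(rng: np.random.Generator, n: int, alphabet: str = RNA_BASES) -> str:
    return "".join(alphabet[k] for k in rng.integers(0, len(alphabet), n))


def _partition_cluster_sizes(rng: np.random.Generator, n: int,
                             size_range: tuple[int, int]) -> list[int]:
    """Split n into cluster sizes within size_range (never leaving a remainder of 1)."""
    lo, hi = size_range
    sizes: list[int] = []
    rem = n
    while rem > 0:
        options = [s for s in range(lo, hi + 1) if s <= rem and rem - s != 1]
        if not options:
            sizes[-1] += rem if sizes else 0
            if not sizes:
                raise ConfigError(f"cannot partition {n} precursors into clusters")
            break
        s = int(rng.choice(options))
        sizes.append(s)
        rem -= s
    return sizes


def _layout_genome(cfg: SimulationConfig, rng: np.random.Generator):
    """Place precursors on chromosomes; returns (precursors, chrom_lengths)."""
    n_clustered = int(round(cfg.cluster_fraction * cfg.n_precursors))
    if n_clustered == 1:
        n_clustered = 2
    n_clustered = min(n_clustered, cfg.n_precursors)
    sizes = _partition_cluster_sizes(rng, n_clustered, cfg.cluster_size_range) \
        if n_clustered else []
    units: list[int] = sizes + [1] * (cfg.n_precursors - n_clustered)
    order = rng.permutation(len(units))
    units = [units[i] for i in order]

    precursors: list[MirnaPrecursor] = []
    cursors = {f"chr{c + 1}": int(rng.integers(5_000, 20_000))
               for c in range(cfg.n_chromosomes)}
    idx = 0
    for u, size in enumerate(units):
        chrom = f"chr{(u % cfg.n_chromosomes) + 1}"
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        pos = cursors[chrom]
        for j in range(size):
            length = int(rng.integers(60, 111))
            idx += 1
            precursors.append(MirnaPrecursor(
                id=f"MI{idx:07d}", name=f"syn-mir-{idx}", chrom=chrom,
                start=pos, end=pos + length - 1, strand=strand,
            ))
            gap = int(rng.integers(*cfg.intra_cluster_gap_range)) if j < size - 1 \
                else int(rng.integers(*cfg.inter_locus_gap_range))
            pos = pos + length + gap
        cursors[chrom] = pos
    chrom_lengths = {c: cursors[c] + 10_000 for c in sorted(cursors)}
    return precursors, chrom_lengths


def _make_matures(cfg: SimulationConfig, rng: np.random.Generator,
                  precursors: list[MirnaPrecursor]) -> list[MatureMirna]:
    matures: list[MatureMirna] = []
    midx = 0
    for p in precursors:
        arms = ["-5p", "-3p"] if cfg.matures_per_precursor == 2 else [""]
        for arm in arms:
            midx += 1
            if arm == "-3p":
                start, end = p.end - 23, p.end - 2
            else:
                start, end = p.start + 2, p.start + 23
            matures.append(MatureMirna(
                id=f"MIMAT{midx:07d}",
                name=f"syn-miR-{p.name.split('-')[-1]}{arm}",
                precursor_id=p.id, chrom=p.chrom, start=start, end=end,
                strand=p.strand, sequence=_rand_seq(rng, 22),
            ))
    return matures


def _solve_carrier_probs(n_c: int, n_nc: int, n_expected: int,
                         odds_ratio: float) -> tuple[float, float]:
    """Per-mature carrier probabilities (clustered, nonclustered) such that the
    expected carrier total is n_expected at the planted odds ratio."""
    def expected(o_nc: float) -> float:
        p_nc = o_nc / (1 + o_nc)
        p_c = odds_ratio * o_nc / (1 + odds_ratio * o_nc)
        return n_c * p_c + n_nc * p_nc

    lo, hi = 1e-9, 1e9
    for _ in range(200):
        mid = (lo * hi) ** 0.5
        if expected(mid) < n_expected:
            lo = mid
        else:
            hi = mid
    o = (lo * hi) ** 0.5
    return odds_ratio * o / (1 + odds_ratio * o), o / (1 + o)


class _SeedRegistry:
    """Keeps planted 7-mer site strings and search patterns cross-consistent.

    Accepting an allele requires that its 7mer-m8 site string cannot be hit
    by any other allele's 7 nt pattern, and that its own 7 nt patterns
    cannot hit any previously planted site string.
    """

    def __init__(self) -> None:
        self.planted7: set[str] = set()    # planted 7mer-m8 site strings
        self.patterns7: set[str] = set()   # all 7 nt patterns (m8 and A1)

    @staticmethod
    def _pats(seed_rna: str) -> tuple[str, str]:
        from .records import SiteType
        p = seed_match_patterns(seed_rna)
        return p[SiteType.SEVENMER_M8], p[SiteType.SEVENMER_A1]

    def ok(self, seed_rna: str) -> bool:
        m8, a1 = self._pats(seed_rna)
        if m8 in self.patterns7 or a1 in self.planted7 or m8 == a1:
            return False
        if m8[:6] == m8[1:]:  # homopolymer-like: own A1 would double-hit
            return False
        return True

    def add(self, seed_rna: str) -> None:
        m8, a1 = self._pats(seed_rna)
        self.planted7.add(m8)
        self.patterns7.update((m8, a1))


def _plant_seed_snps(cfg: SimulationConfig, rng: np.random.Generator,
                     matures: list[MatureMirna], status: dict[str, str]):
    """Choose carrier matures (enrichment-planted), re-draw their sequences
    until all ref/derived seeds are globally safe, and build SNP records.

    Returns (updated matures, seed snp ground-truth dicts, registry).
    """
    n_c = sum(1 for m in matures if status[m.id] == "clustered")
    n_nc = len(matures) - n_c
    p_c, p_nc = _solve_carrier_probs(n_c, n_nc, cfg.n_seed_snps,
                                     cfg.enrichment_odds_ratio)
    registry = _SeedRegistry()
    out_matures: list[MatureMirna] = []
    truths: list[dict] = []
    snp_idx = 0
    for m in matures:
        p_carry = p_c if status[m.id] == "clustered" else p_nc
        if rng.random() >= p_carry:
            out_matures.append(m)
            continue
        # carrier: resample sequence/offset/alt until every seed is safe
        for _attempt in range(1000):
            seq = _rand_seq(rng, m.length)
            ref_seed = seq[1:8]
            if not registry.ok(ref_seed):
                continue
            offset = int(rng.integers(1, 8))
            i = offset - 1
            alts = [b for b in RNA_BASES if b != ref_seed[i]]
            rng.shuffle(alts)
            derived = None
            for alt_rna in alts:
                cand = ref_seed[:i] + alt_rna + ref_seed[i + 1:]
                if cand != ref_seed and registry.ok(cand):
                    derived = (alt_rna, cand)
                    break
            if derived is None:
                continue
            registry.add(ref_seed)
            registry.add(derived[1])
            break
        else:  # pragma: no cover - probabilistically unreachable
            raise ConfigError("could not find a safe seed in 1000 attempts")

        mature = dataclasses.replace(m, sequence=seq)
        out_matures.append(mature)
        sd = compute_seed_interval(mature)
        if sd.strand == "+":
            pos = sd.start + offset - 1
        else:
            pos = sd.end - offset + 1
        ref_fwd = reverse_transcribe(ref_seed[i]) if sd.strand == "+" \
            else complement_base(reverse_transcribe(ref_seed[i]))
        alt_fwd = reverse_transcribe(derived[0]) if sd.strand == "+" \
            else complement_base(reverse_transcribe(derived[0]))
        maf = _draw_maf(cfg.maf_distribution, rng)
        snp_idx += 1
        truths.append({
            "rsid": f"rs2{snp_idx:06d}", "mature_id": m.id,
            "mature_name": m.name, "chrom": m.chrom, "pos": int(pos),
            "strand": m.strand, "seed_offset": offset,
            "ref_seed": ref_seed, "derived_seed": derived[1],
            "ref_allele": ref_fwd, "alt_allele": alt_fwd,
            "maf": maf, "rarity": _rarity_of(maf),
            "clustered": status[m.id] == "clustered",
        })
    return out_matures, truths, registry


def _draw_maf(mix: MafMixture, rng: np.random.Generator) -> float | None:
    if rng.random() < mix.fraction_missing:
        return None
    if rng.random() < mix.fraction_rare:
        a, b = mix.rare_beta
        return float(max(1e-4, 0.05 * rng.beta(a, b)))
    a, b = mix.common_beta
    return float(0.05 + 0.45 * rng.beta(a, b))


def _rarity_of(maf: float | None) -> str:
    if maf is None:
        return "unknown"
    return "rare" if maf < 0.05 else "common"


def _background_snps(cfg: SimulationConfig, rng: np.random.Generator,
                     chrom_lengths: dict[str, int],
                     forbidden: set[tuple[str, int]]) -> list[dict]:
    chroms = sorted(chrom_lengths)
    out: list[dict] = []
    used = set(forbidden)
    k = 0
    while len(out) < cfg.n_background_snps:
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
        if (chrom, pos) in used:
            continue
        used.add((chrom, pos))
        ref = DNA_BASES[int(rng.integers(0, 4))]
        alt = rng.choice([b for b in DNA_BASES if b != ref])
        maf = _draw_maf(cfg.maf_distribution, rng)
        k += 1
        out.append({"rsid": f"rs1{k:06d}", "chrom": chrom, "pos": pos,
                    "ref_allele": ref, "alt_allele": str(alt), "maf": maf})
    return out


# --- UTR planting ----------------------------------------------------------

def _build_pattern_index(alleles: list[tuple[str, str]]):
    """allele list of (allele_id, seed_rna) -> pattern string -> [(allele_id, kind)].

    kind is 'core+1' for 7mer-m8/8mer (core starts one past the match start)
    or 'core+0' for 7mer-A1.
    """
    from .records import SiteType
    index: dict[str, list[tuple[str, int]]] = {}
    for allele_id, seed in alleles:
        pats = seed_match_patterns(seed)
        for st, shift in ((SiteType.SEVENMER_M8, 1), (SiteType.EIGHTMER, 1),
                          (SiteType.SEVENMER_A1, 0)):
            index.setdefault(pats[st], []).append((allele_id, shift))
    return index


def _screen_utr(utr: list[str], index, allowed: set[tuple[str, int]],
                planted_pos: set[int], rng: np.random.Generator,
                max_rounds: int = 60) -> bool:
    """Remove accidental pattern matches by resampling non-planted positions.

    Returns True when clean; False if the UTR could not be cleaned (the
    caller then regenerates it from scratch).
    """
    n = len(utr)
    for _ in range(max_rounds):
        dirty: set[int] = set()
        text = "".join(utr)
        for length in (7, 8):
            for i in range(n - length + 1):
                hits = index.get(text[i:i + length])
                if not hits:
                    continue
                for allele_id, shift in hits:
                    if (allele_id, i + shift) in allowed:
                        continue
                    dirty.update(k for k in range(i, i + length)
                                 if k not in planted_pos)
        if not dirty:
            return True
        if not dirty - planted_pos:
            return False  # violation sits wholly inside planted sites
        for k in sorted(dirty):
            utr[k] = DNA_BASES[int(rng.integers(0, 4))]
    return False


def _make_planted_utr(rng: np.random.Generator, length: int,
                      sites: list[tuple[str, str]], index) -> str | None:
    """One UTR of given length carrying exactly the planted 7mer-m8 sites.

    ``sites`` is a list of (allele_id, site_string).  Returns the sequence,
    or None when screening failed for this placement attempt.
    """
    utr = list(_rand_seq(rng, length, DNA_BASES))
    positions: list[int] = []
    for _ in range(200):
        p = int(rng.integers(0, length - 7 + 1))
        if all(abs(p - q) >= 8 for q in positions):
            positions.append(p)
        if len(positions) == len(sites):
            break
    if len(positions) < len(sites):
        return None
    allowed: set[tuple[str, int]] = set()
    planted_pos: set[int] = set()
    for (allele_id, s), p in zip(sites, positions):
        utr[p:p + 7] = list(s)
        allowed.add((allele_id, p + 1))  # core of a 7mer-m8 match at p
        planted_pos.update(range(p, p + 7))
    if _screen_utr(utr, index, allowed, planted_pos, rng):
        return "".join(utr)
    return None


def _plant_utrs(cfg: SimulationConfig, rng: np.random.Generator,
                seed_truths: list[dict]) -> tuple[dict[str, str], list[dict]]:
    """Build the UTR collection; annotate each seed-SNP truth with its genes."""
    alleles: list[tuple[str, str]] = []
    for t in seed_truths:
        alleles.append((f"{t['rsid']}:ref", t["ref_seed"]))
        alleles.append((f"{t['rsid']}:der", t["derived_seed"]))
    index = _build_pattern_index(alleles)

    utrs: dict[str, str] = {}
    gene_idx = 0

    def new_gene(sites: list[tuple[str, str]]) -> str:
        nonlocal gene_idx
        gene_idx += 1
        gid = f"G{gene_idx:05d}"
        for _ in range(1000):
            length = int(rng.integers(*cfg.utr_length_range))
            seq = _make_planted_utr(rng, length, sites, index)
            if seq is not None:
                utrs[gid] = seq
                return gid
        raise ConfigError(f"could not build a clean UTR for {gid} in 1000 attempts")

    for t in seed_truths:
        group = "clustered" if t["clustered"] else "nonclustered"
        base = cfg.planted_overlap_spec[group]
        j = cfg.overlap_count_jitter
        n_ref_only, n_der_only, n_common = (
            max(0, int(b + rng.integers(-j, j + 1))) if j else int(b)
            for b in base
        )
        rid = t["rsid"]
        ref_genes, der_genes = [], []
        for _ in range(n_ref_only):
            ref_genes.append(new_gene([(f"{rid}:ref", index_site(t, "ref"))]))
        for _ in range(n_der_only):
            der_genes.append(new_gene([(f"{rid}:der", index_site(t, "der"))]))
        for _ in range(n_common):
            g = new_gene([(f"{rid}:ref", index_site(t, "ref")),
                          (f"{rid}:der", index_site(t, "der"))])
            ref_genes.append(g)
            der_genes.append(g)
        t["planted"] = {"n_ref_only": n_ref_only, "n_der_only": n_der_only,
                        "n_common": n_common}
        t["ref_genes"] = ref_genes
        t["der_genes"] = der_genes
        n_ref, n_der = len(ref_genes), len(der_genes)
        t["expected_overlap"] = (
            None if n_ref == 0 or n_der == 0
            else n_common / (n_ref * n_der) ** 0.5
        )

    if gene_idx > cfg.n_genes:
        raise ConfigError(
            f"realized carrier count needs {gene_idx} planted target genes "
            f"but n_genes={cfg.n_genes} (more planted sites than UTR capacity)"
        )
    while gene_idx < cfg.n_genes:
        new_gene([])  # background gene with no sites for anyone
    return utrs, seed_truths


def index_site(truth: dict, which: str) -> str:
    """The planted 7mer-m8 site string (DNA) for one allele of a seed SNP."""
    from .records import SiteType
    seed = truth["ref_seed"] if which == "ref" else truth["derived_seed"]
    return seed_match_patterns(seed)[SiteType.SEVENMER_M8]


def _make_mirna_sets(cfg: SimulationConfig, rng: np.random.Generator,
                     matures: list[MatureMirna], seed_truths: list[dict],
                     status: dict[str, str]):
    """Pathway-style miRNA sets with one planted enriched set for the
    clustered-carrier query (falls back to all carriers when none clustered)."""
    universe = sorted(m.name for m in matures)
    query = sorted(t["mature_name"] for t in seed_truths if t["clustered"])
    if not query:
        query = sorted(t["mature_name"] for t in seed_truths)
    non_query = sorted(set(universe) - set(query))
    n_in = max(2, int(round(0.8 * len(query))))
    members = [query[i] for i in
               sorted(rng.choice(len(query), size=min(n_in, len(query)),
                                 replace=False))]
    n_out = max(1, len(non_query) // 20)
    members += [non_query[i] for i in
                sorted(rng.choice(len(non_query), size=min(n_out, len(non_query)),
                                  replace=False))]
    sets = [MirnaSetAnnotation("PLANTED_PATHWAY", frozenset(members))]
    for k in range(10):
        size = int(rng.integers(10, 31))
        mem = [universe[i] for i in
               sorted(rng.choice(len(universe), size=min(size, len(universe)),
                                 replace=False))]
        sets.append(MirnaSetAnnotation(f"SET_{k + 1:02d}", frozenset(mem)))
    return sets, query, universe


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, output_dir: str | Path) -> dict:
    """Generate the five input files plus ground_truth.json; returns the
    ground-truth mapping.  Deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    precursors, chrom_lengths = _layout_genome(config, rng)
    clusters = cluster_precursors(precursors)
    matures = _make_matures(config, rng, precursors)
    status = mature_cluster_status(matures, clusters)

    _check_straddle(config, precursors)

    matures, seed_truths, _reg = _plant_seed_snps(config, rng, matures, status)
    utrs, seed_truths = _plant_utrs(config, rng, seed_truths)

    forbidden = set()
    for m in matures:
        sd = compute_seed_interval(m)
        forbidden.update((sd.chrom, p) for p in range(sd.start, sd.end + 1))
    background = _background_snps(config, rng, chrom_lengths, forbidden)

    sets, ora_query, universe = _make_mirna_sets(config, rng, matures,
                                                 seed_truths, status)

    # --- write files (fixed order) ---
    mio.write_mirna_gff(outdir / FILE_NAMES["gff"], precursors, matures)
    mio.write_mature_fasta(outdir / FILE_NAMES["mature_fasta"], matures)
    snps = [
        SnpRecord(rsid=t["rsid"], chrom=t["chrom"], pos=t["pos"],
                  ref_allele=t["ref_allele"], alt_alleles=(t["alt_allele"],),
                  maf=t["maf"])
        for t in seed_truths
    ] + [
        SnpRecord(rsid=b["rsid"], chrom=b["chrom"], pos=b["pos"],
                  ref_allele=b["ref_allele"], alt_alleles=(b["alt_allele"],),
                  maf=b["maf"])
        for b in background
    ]
    mio.write_vcf_snps(outdir / FILE_NAMES["vcf"], snps)
    mio.write_utr_fasta(outdir / FILE_NAMES["utr_fasta"], utrs)
    mio.write_mirna_sets(outdir / FILE_NAMES["mirna_sets"], sets)

    carriers = {t["mature_id"] for t in seed_truths}
    table = _cross_tab(matures, status, carriers)
    ground_truth = {
        "config": _config_dict(config),
        "chrom_lengths": chrom_lengths,
        "clusters": [list(c.member_precursor_ids) for c in clusters],
        "mature_status": {m.id: status[m.id] for m in matures},
        "mature_names": {m.id: m.name for m in matures},
        "seed_snps": seed_truths,
        "background_snp_rsids": [b["rsid"] for b in background],
        "enrichment_table": {"a": table.a, "b": table.b,
                             "c": table.c, "d": table.d},
        "planted_set_name": "PLANTED_PATHWAY",
        "ora_query": ora_query,
        "ora_universe": universe,
    }
    with open(outdir / GROUND_TRUTH_FILE, "w") as fh:
        json.dump(ground_truth, fh, indent=1, sort_keys=True)
        fh.write("\n")
    logger.info("simulated %d precursors, %d matures, %d seed SNPs, %d genes",
                len(precursors), len(matures), len(seed_truths), len(utrs))
    return ground_truth


def _config_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)

    def conv(x):
        if isinstance(x, tuple):
            return list(x)
        if isinstance(x, dict):
            return {k: conv(v) for k, v in x.items()}
        return x
    return {k: conv(v) for k, v in d.items()}


def _check_straddle(cfg: SimulationConfig, precursors: list[MirnaPrecursor]) -> None:
    """Planted layouts must exercise both sides of the 10 kb rule."""
    gaps = []
    by_chrom: dict[str, list[MirnaPrecursor]] = {}
    for p in precursors:
        by_chrom.setdefault(p.chrom, []).append(p)
    for plist in by_chrom.values():
        plist.sort(key=lambda p: p.start)
        gaps += [max(0, b.start - a.end - 1) for a, b in zip(plist, plist[1:])]
    has_close = any(g <= 10_000 for g in gaps)
    has_far = any(g > 10_000 for g in gaps)
    if cfg.cluster_fraction > 0 and not has_close:
        raise ConfigError("no planted pair within the 10 kb rule")
    if len(precursors) > 1 and not has_far:
        raise ConfigError("no planted pair beyond the 10 kb rule")


def _cross_tab(matures, status, carriers) -> ContingencyTable2x2:
    a = sum(1 for m in matures if m.id in carriers and status[m.id] == "clustered")
    b = sum(1 for m in matures if m.id in carriers and status[m.id] != "clustered")
    c = sum(1 for m in matures if m.id not in carriers and status[m.id] == "clustered")
    d = sum(1 for m in matures if m.id not in carriers and status[m.id] == "nonclustered")
    return ContingencyTable2x2(a=a, b=b, c=c, d=d)


def enrichment_table_replicates(
    config: SimulationConfig, n_replicates: int, seed: int
) -> list[ContingencyTable2x2]:
    """Light-weight replicates of the enrichment cross-tabulation.

    Builds the genomic layout once, then re-draws the carrier assignment per
    replicate at the configured planted odds ratio.  Used for type-I-error
    and power simulations without paying for sequence/UTR generation.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    precursors, _ = _layout_genome(config, rng)
    clusters = cluster_precursors(precursors)
    matures = _make_matures(config, rng, precursors)
    status = mature_cluster_status(matures, clusters)
    n_c = sum(1 for m in matures if status[m.id] == "clustered")
    n_nc = len(matures) - n_c
    p_c, p_nc = _solve_carrier_probs(n_c, n_nc, config.n_seed_snps,
                                     config.enrichment_odds_ratio)
    tables = []
    for _ in range(n_replicates):
        carriers = {
            m.id for m in matures
            if rng.random() < (p_c if status[m.id] == "clustered" else p_nc)
        }
        tables.append(_cross_tab(matures, status, carriers))
    return tables


def verify_ground_truth(output_dir: str | Path, max_report: int = 50) -> dict:
    """Re-read the emitted files through the pipeline modules and check every
    ground-truth assertion; any discrepancy is a generator bug."""
    outdir = Path(output_dir)
    with open(outdir / GROUND_TRUTH_FILE) as fh:
        gt = json.load(fh)
    problems: list[str] = []

    precursors, matures, _ = mio.read_mirna_gff(outdir / FILE_NAMES["gff"])
    matures, _ = mio.attach_sequences(matures, outdir / FILE_NAMES["mature_fasta"])
    if len(matures) != len(gt["mature_status"]):
        problems.append(f"mature count {len(matures)} != "
                        f"{len(gt['mature_status'])} in ground truth")

    clusters = cluster_precursors(precursors)
    found = sorted(sorted(c.member_precursor_ids) for c in clusters)
    expected = sorted(sorted(c) for c in gt["clusters"])
    if found != expected:
        problems.append(f"cluster membership differs: {found} != {expected}")
    status = mature_cluster_status(matures, clusters)
    for mid, st in gt["mature_status"].items():
        if status.get(mid) != st:
            problems.append(f"mature {mid}: status {status.get(mid)} != {st}")

    snps, _ = mio.read_vcf_snps(outdir / FILE_NAMES["vcf"])
    seeds = [compute_seed_interval(m) for m in matures]
    seed_snps, meta = map_snps_to_seeds(seeds, snps)
    if meta["n_reference_mismatch"]:
        problems.append(f"{meta['n_reference_mismatch']} reference mismatches")
    found_map = {(s.rsid, s.mature_id): s for s in seed_snps}
    for t in gt["seed_snps"]:
        key = (t["rsid"], t["mature_id"])
        s = found_map.pop(key, None)
        if s is None:
            problems.append(f"planted seed SNP {key} not recovered")
            continue
        if (s.seed_offset != t["seed_offset"] or s.ref_seed != t["ref_seed"]
                or s.derived_seeds[0][1] != t["derived_seed"]):
            problems.append(f"seed SNP {key}: offset/seed mismatch")
        if s.rarity.value != t["rarity"]:
            problems.append(f"seed SNP {key}: rarity {s.rarity.value} != {t['rarity']}")
    for key in found_map:
        problems.append(f"unplanted seed SNP recovered: {key}")
    bg = set(gt["background_snp_rsids"])
    hit_bg = bg & {s.rsid for s in seed_snps}
    if hit_bg:
        problems.append(f"background SNPs landed in seeds: {sorted(hit_bg)[:5]}")

    utrs = mio.read_utr_fasta(outdir / FILE_NAMES["utr_fasta"])
    ss_by_key = {(s.rsid, s.mature_id): s for s in seed_snps}
    for t in gt["seed_snps"]:
        s = ss_by_key.get((t["rsid"], t["mature_id"]))
        if s is None:
            continue
        ref_ts, der_list = allele_dependent_targets(s, utrs)
        if ref_ts.genes != set(t["ref_genes"]):
            problems.append(f"{t['rsid']}: reference targets differ "
                            f"(got {len(ref_ts.genes)}, planted {len(t['ref_genes'])})")
        if der_list[0].genes != set(t["der_genes"]):
            problems.append(f"{t['rsid']}: derived targets differ "
                            f"(got {len(der_list[0].genes)}, planted {len(t['der_genes'])})")
        got = percent_overlap(ref_ts.genes, der_list[0].genes)
        exp = t["expected_overlap"]
        if (got is None) != (exp is None) or (
                got is not None and abs(got - exp) > 1e-12):
            problems.append(f"{t['rsid']}: percent overlap {got} != planted {exp}")

    sets = mio.read_mirna_sets(outdir / FILE_NAMES["mirna_sets"])
    if gt["planted_set_name"] not in {s.set_name for s in sets}:
        problems.append("planted pathway set missing from the GMT file")

    return {
        "ok": not problems,
        "n_discrepancies": len(problems),
        "discrepancies": problems[:max_report],
    }
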