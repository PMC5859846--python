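"""Core domain records for miRNA seed-region SNP analysis.

Coordinates are 1-based inclusive throughout (GFF3/VCF convention); any
conversion to 0-based half-open happens only inside interval helpers or at
BED write time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

RNA_ALPHABET = frozenset("ACGU")
DNA_ALPHABET = frozenset("ACGT")

#: complement tables for single bases
DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "U": "A"}


class InputError(ValueError):
    """Fatal problem with an input file or record."""


@dataclass(frozen=True)
class MirnaPrecursor:
    """A miRNA gene (pre-miRNA hairpin locus); the unit of genomic clustering."""

    id: str
    name: str
    chrom: str
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    strand: str

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class MatureMirna:
    """A mature miRNA with its genomic interval and (optionally) its sequence.

    ``sequence`` is the mature RNA 5'->3' in miRNA sense; it may be ``None``
    until :func:`mirseedsnp.io.attach_sequences` has run.  Once present it
    must span the genomic interval exactly and be at least 8 nt so that a
    seed (positions 2-8) exists.
    """

    id: str
    name: str
    precursor_id: str
    chrom: str
    start: int
    end: int
    strand: str
    sequence: str | None = None

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.length < 8:
            raise ValueError(f"{self.id}: mature length {self.length} < 8, no seed region")
        if self.sequence is not None:
            if len(self.sequence) != self.length:
                raise ValueError(
                    f"{self.id}: sequence length {len(self.sequence)} != interval "
                    f"length {self.length}"
                )
            bad = set(self.sequence) - RNA_ALPHABET
            if bad:
                raise ValueError(f"{self.id}: non-RNA characters {sorted(bad)} in sequence")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class SnpRecord:
    """A single-nucleotide variant; alleles are on the forward genomic strand."""

    rsid: str
    chrom: str
    pos: int
    ref_allele: str
    alt_alleles: tuple[str, ...]
    maf: float | None = None

    def __post_init__(self) -> None:
        if len(self.ref_allele) != 1:
            raise ValueError(f"{self.rsid}: REF {self.ref_allele!r} is not a single base")
        if not self.alt_alleles:
            raise ValueError(f"{self.rsid}: no ALT alleles")
        for a in self.alt_alleles:
            if len(a) != 1:
                raise ValueError(f"{self.rsid}: ALT {a!r} is not a single base")
        if self.ref_allele in self.alt_alleles:
            raise ValueError(f"{self.rsid}: REF allele listed among ALTs")
        if self.maf is not None and not (0.0 <= self.maf <= 1.0):
            raise ValueError(f"{self.rsid}: MAF {self.maf} outside [0, 1]")


@dataclass(frozen=True)
class MirnaSetAnnotation:
    """A named set of miRNAs (pathway / category membership), GMT-style."""

    set_name: str
    member_mirna_names: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_mirna_names:
            raise ValueError(f"{self.set_name}: empty member set")


@dataclass(frozen=True)
class SeedInterval:
    """Genomic interval of a mature miRNA's seed (mature positions 2-8)."""

    mature_id: str
    chrom: str
    start: int
    end: int
    strand: str
    seed_sequence: str  # 7 nt, miRNA sense 5'->3'

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != 7:
            raise ValueError(f"{self.mature_id}: seed interval is not 7 nt")
        if len(self.seed_sequence) != 7:
            raise ValueError(f"{self.mature_id}: seed sequence is not 7 nt")


class Rarity(str, Enum):
    RARE = "rare"
    COMMON = "common"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class SeedSnp:
    """A SNP projected into a miRNA seed, with allele-substituted seeds.

    ``seed_offset`` is 1..7 within the seed, 5'->3' in miRNA sense
    (mature position = seed_offset + 1).  ``derived_seeds`` pairs each
    forward-strand ALT base with the resulting 7 nt seed in miRNA sense.
    """

    rsid: str
    mature_id: str
    genomic_pos: int
    seed_offset: int
    ref_seed: str
    derived_seeds: tuple[tuple[str, str], ...]
    rarity: Rarity = Rarity.UNKNOWN
    maf: float | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.seed_offset <= 7:
            raise ValueError(f"{self.rsid}: seed_offset {self.seed_offset} outside 1..7")
        i = self.seed_offset - 1
        for alt, der in self.derived_seeds:
            diffs = [k for k in range(7) if der[k] != self.ref_seed[k]]
            if diffs != [i]:
                raise ValueError(
                    f"{self.rsid}: derived seed {der} does not differ from {self.ref_seed} "
                    f"exactly at offset {self.seed_offset} (alt {alt})"
                )


class SiteType(str, Enum):
    """Canonical seed-match site classes, most specific first."""

    EIGHTMER = "8mer"
    SEVENMER_M8 = "7mer-m8"
    SEVENMER_A1 = "7mer-A1"
    SIXMER = "6mer"


#: specificity ranking used when overlapping matches collapse to one site
SITE_TYPE_RANK = {
    SiteType.EIGHTMER: 0,
    SiteType.SEVENMER_M8: 1,
    SiteType.SEVENMER_A1: 2,
    SiteType.SIXMER: 3,
}

DEFAULT_SITE_TYPES = frozenset(
    {SiteType.EIGHTMER, SiteType.SEVENMER_M8, SiteType.SEVENMER_A1}
)


@dataclass
class TargetSet:
    """Predicted target genes of one seed allele against a UTR collection."""

    seed: str
    allele_label: str  # "reference" or "derived:<alt>"
    genes: set[str] = field(default_factory=set)
    sites: dict[str, list[tuple[int, SiteType]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.genes != set(self.sites):
            raise ValueError("genes must equal the keys of sites")


@dataclass(frozen=True)
class OverlapResult:
    """Cosine percent overlap between reference and derived target sets."""

    rsid: str
    mature_id: str
    alt_allele: str
    n_ref: int
    n_der: int
    n_common: int
    percent_overlap: float | None

    def __post_init__(self) -> None:
        if self.n_common > min(self.n_ref, self.n_der):
            raise ValueError(f"{self.rsid}: n_common exceeds a set size")


@dataclass(frozen=True)
class Cluster:
    """A maximal group of >= 2 same-strand precursors with neighbors <= max_gap apart."""

    cluster_id: str
    chrom: str
    strand: str
    member_precursor_ids: tuple[str, ...]
    span_start: int
    span_end: int

    def __post_init__(self) -> None:
        if len(self.member_precursor_ids) < 2:
            raise ValueError(f"{self.cluster_id}: a cluster needs >= 2 members")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts a,b / c,d; rows = with/without seed SNP, columns = clustered/not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative count in contingency table")
        if self.total == 0:
            raise ValueError("empty contingency table")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int | None
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p-value {self.p_value} outside (0, 1]")


def complement_base(base: str, rna: bool = False) -> str:
    """Complement of one nucleotide; DNA by default, RNA table if ``rna``."""
    table = RNA_COMPLEMENT if rna else DNA_COMPLEMENT
    try:
        return table[base]
    except KeyError:
        raise ValueError(f"cannot complement base {base!r}") from None


def transcribe(seq: str) -> str:
    """DNA -> RNA (T -> U); idempotent on RNA."""
    return seq.upper().replace("T", "U")


def reverse_transcribe(seq: str) -> str:
    """RNA -> DNA (U -> T); idempotent on DNA."""
    return seq.upper().replace("U", "T")
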