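"""Readers and writers for the pipeline's standard input formats.

Supported dialects:

* miRBase-style GFF3 with ``miRNA_primary_transcript`` (precursor) and
  ``miRNA`` (mature) features, the mature linked to its precursor through a
  ``Derives_from`` attribute (parsed with :mod:`gffutils`);
* FASTA of mature miRNA sequences, record names matching mature names or ids
  (Biopython);
* plain-text VCF v4.x, SNVs only, with the minor-allele frequency taken from
  a configurable INFO key;
* a GMT-like tab-separated miRNA-set file (set name, description, members).

Readers drop records that violate the domain-type invariants with a logged
warning, never coercing them silently, and report reject counts in a
metadata mapping.
"""

from __future__ import annotations

import logging
from collections import Counter
from pathlib import Path

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import (
    InputError,
    MatureMirna,
    MirnaPrecursor,
    MirnaSetAnnotation,
    SnpRecord,
    transcribe,
)

logger = logging.getLogger(__name__)

PRECURSOR_FEATURE = "miRNA_primary_transcript"
MATURE_FEATURE = "miRNA"

_VALID_BASES = frozenset("ACGT")


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def read_mirna_gff(path: str | Path) -> tuple[list[MirnaPrecursor], list[MatureMirna], dict]:
    """Read a miRBase-dialect GFF3 into precursor and mature records.

    Returns ``(precursors, matures, meta)`` where ``meta`` carries reject
    counts keyed by reason.  Matures with a dangling ``Derives_from`` or an
    interval shorter than 8 nt (no seed region) are dropped with a warning.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"GFF3 file not found: {path}")
    try:
        db = gffutils.create_db(
            str(path), dbfn=":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # pragma: no cover - gffutils wraps many errors
        raise InputError(f"cannot parse GFF3 {path}: {exc}") from exc

    rejects: Counter[str] = Counter()
    precursors: dict[str, MirnaPrecursor] = {}
    for feat in db.features_of_type(PRECURSOR_FEATURE):
        pid = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [pid])[0]
        try:
            rec = MirnaPrecursor(
                id=pid, name=name, chrom=feat.seqid,
                start=feat.start, end=feat.end, strand=feat.strand,
            )
        except ValueError as exc:
            logger.warning("dropping precursor %s: %s", pid, exc)
            rejects["precursor_invalid"] += 1
            continue
        if pid in precursors:
            logger.warning("dropping duplicate precursor id %s", pid)
            rejects["precursor_duplicate_id"] += 1
            continue
        precursors[pid] = rec

    matures: list[MatureMirna] = []
    for feat in db.features_of_type(MATURE_FEATURE):
        mid = feat.attributes.get("ID", [feat.id])[0]
        name = feat.attributes.get("Name", [mid])[0]
        derives = feat.attributes.get("Derives_from", [None])[0]
        if derives is None or derives not in precursors:
            logger.warning("dropping mature %s: Derives_from %r not found", mid, derives)
            rejects["mature_dangling_derives_from"] += 1
            continue
        parent = precursors[derives]
        if feat.seqid != parent.chrom or feat.strand != parent.strand:
            logger.warning("dropping mature %s: chrom/strand differ from precursor", mid)
            rejects["mature_parent_mismatch"] += 1
            continue
        try:
            matures.append(MatureMirna(
                id=mid, name=name, precursor_id=derives, chrom=feat.seqid,
                start=feat.start, end=feat.end, strand=feat.strand,
            ))
        except ValueError as exc:
            logger.warning("dropping mature %s: %s", mid, exc)
            rejects["mature_invalid"] += 1

    meta = {"n_rejected": sum(rejects.values()), "reject_reasons": dict(rejects)}
    return list(precursors.values()), matures, meta


def write_mirna_gff(
    path: str | Path,
    precursors: list[MirnaPrecursor],
    matures: list[MatureMirna],
) -> None:
    """Write records back out in the miRBase GFF3 dialect."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for p in precursors:
            fh.write(
                f"{p.chrom}\t.\t{PRECURSOR_FEATURE}\t{p.start}\t{p.end}\t.\t"
                f"{p.strand}\t.\tID={p.id};Name={p.name}\n"
            )
        for m in matures:
            fh.write(
                f"{m.chrom}\t.\t{MATURE_FEATURE}\t{m.start}\t{m.end}\t.\t"
                f"{m.strand}\t.\tID={m.id};Name={m.name};Derives_from={m.precursor_id}\n"
            )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def attach_sequences(
    matures: list[MatureMirna], fasta_path: str | Path
) -> tuple[list[MatureMirna], dict]:
    """Attach mature RNA sequences from a FASTA keyed by mature name or id.

    DNA input (T) is transcribed to RNA (U).  A mature with no matching FASTA
    record is dropped with a warning; a sequence whose length disagrees with
    the genomic interval is fatal, because the coordinates can then not be
    trusted.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.is_file():
        raise InputError(f"FASTA file not found: {fasta_path}")
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        seqs[rec.id] = transcribe(str(rec.seq))

    out: list[MatureMirna] = []
    rejects = 0
    for m in matures:
        seq = seqs.get(m.name, seqs.get(m.id))
        if seq is None:
            logger.warning("dropping mature %s: no FASTA record named %s or %s",
                           m.id, m.name, m.id)
            rejects += 1
            continue
        if len(seq) != m.length:
            raise InputError(
                f"mature {m.id}: FASTA sequence is {len(seq)} nt but the genomic "
                f"interval spans {m.length} nt; coordinates untrustworthy"
            )
        out.append(MatureMirna(
            id=m.id, name=m.name, precursor_id=m.precursor_id, chrom=m.chrom,
            start=m.start, end=m.end, strand=m.strand, sequence=seq,
        ))
    return out, {"n_rejected": rejects}


def write_mature_fasta(path: str | Path, matures: list[MatureMirna]) -> None:
    records = []
    for m in matures:
        if m.sequence is None:
            raise ValueError(f"mature {m.id} has no sequence to write")
        records.append(SeqRecord(Seq(m.sequence), id=m.name, description=""))
    SeqIO.write(records, str(path), "fasta")


def read_utr_fasta(path: str | Path) -> dict[str, str]:
    """Read a 3'UTR FASTA into a gene_id -> DNA sequence mapping.

    Empty sequences and duplicate gene ids are rejected (fatal: the caller
    must pre-collapse isoforms to one sequence per gene).
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"UTR FASTA not found: {path}")
    utrs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise InputError(f"UTR record {rec.id} is empty")
        if rec.id in utrs:
            raise InputError(f"duplicate UTR gene id {rec.id}; collapse isoforms first")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise InputError(f"UTR {rec.id}: non-DNA characters {sorted(bad)}")
        utrs[rec.id] = seq
    return utrs


def write_utr_fasta(path: str | Path, utrs: dict[str, str]) -> None:
    SeqIO.write(
        [SeqRecord(Seq(s), id=g, description="") for g, s in utrs.items()],
        str(path), "fasta",
    )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_snps(
    path: str | Path,
    maf_info_keys: tuple[str, ...] = ("AF", "CAF"),
) -> tuple[list[SnpRecord], dict]:
    """Read SNVs from a plain-text VCF v4.x.

    Only single-nucleotide substitutions are retained: indel ALTs of
    multiallelic records are silently filtered (with a logged count); records
    with no SNV ALT left are dropped.  The minor-allele frequency is taken
    from the first INFO key in ``maf_info_keys`` that parses; a CAF-style
    comma list is interpreted as reference-first allele frequencies, the
    minor allele frequency being ``min(f, 1-f)`` of the first ALT frequency.
    Malformed lines are skipped with a warning; a file with no parseable
    record at all is fatal.
    """
    path = Path(path)
    if not path.is_file():
        raise InputError(f"VCF file not found: {path}")
    snps: list[SnpRecord] = []
    n_malformed = 0
    n_indel_alts = 0
    n_dropped_records = 0
    seen_rsids: Counter[str] = Counter()
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 8:
                logger.warning("%s:%d: malformed VCF line (%d fields), skipping",
                               path.name, lineno, len(fields))
                n_malformed += 1
                continue
            chrom, pos_s, rsid, ref, alt_s, _qual, _filt, info = fields[:8]
            try:
                pos = int(pos_s)
            except ValueError:
                logger.warning("%s:%d: non-integer POS %r, skipping", path.name, lineno, pos_s)
                n_malformed += 1
                continue
            ref = ref.upper()
            alts_all = [a.upper() for a in alt_s.split(",") if a]
            snv_alts = tuple(
                a for a in alts_all
                if len(a) == 1 and a in _VALID_BASES and a != ref
            )
            n_indel_alts += sum(1 for a in alts_all if len(a) != 1)
            if len(ref) != 1 or ref not in _VALID_BASES or not snv_alts:
                n_dropped_records += 1
                continue
            maf = _parse_maf(info, maf_info_keys)
            try:
                rec = SnpRecord(rsid=rsid, chrom=chrom, pos=pos, ref_allele=ref,
                                alt_alleles=snv_alts, maf=maf)
            except ValueError as exc:
                logger.warning("%s:%d: invalid SNP record: %s", path.name, lineno, exc)
                n_malformed += 1
                continue
            seen_rsids[rsid] += 1
            snps.append(rec)
    if not snps:
        raise InputError(f"no parseable SNV records in {path}")
    multi_mapped = sorted(r for r, n in seen_rsids.items() if n > 1 and r != ".")
    if multi_mapped:
        logger.warning("%d rsIDs map to more than one locus; all placements kept",
                       len(multi_mapped))
    meta = {
        "n_snps": len(snps),
        "n_malformed_lines": n_malformed,
        "n_indel_alts_filtered": n_indel_alts,
        "n_records_dropped": n_dropped_records,
        "multi_mapped_rsids": multi_mapped,
    }
    return snps, meta


def _parse_maf(info: str, keys: tuple[str, ...]) -> float | None:
    kv: dict[str, str] = {}
    for item in info.split(";"):
        if "=" in item:
            k, v = item.split("=", 1)
            kv[k] = v
    for key in keys:
        if key not in kv:
            continue
        try:
            parts = [float(x) for x in kv[key].split(",") if x not in (".", "")]
        except ValueError:
            continue
        if not parts:
            continue
        if key == "CAF":
            # reference-first: the first ALT frequency is parts[1] if present
            f = parts[1] if len(parts) > 1 else 1.0 - parts[0]
        else:
            f = parts[0]
        return min(f, 1.0 - f)
    return None


def write_vcf_snps(path: str | Path, snps: list[SnpRecord], maf_key: str = "AF") -> None:
    """Write SNVs as a minimal VCF v4.2 (sorted by chrom, pos)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write(f'##INFO=<ID={maf_key},Number=A,Type=Float,'
                 'Description="Allele frequency">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for s in sorted(snps, key=lambda r: (r.chrom, r.pos, r.rsid)):
            info = f"{maf_key}={s.maf:.6g}" if s.maf is not None else "."
            fh.write(f"{s.chrom}\t{s.pos}\t{s.rsid}\t{s.ref_allele}\t"
                     f"{','.join(s.alt_alleles)}\t.\t.\t{info}\n")


# ---------------------------------------------------------------------------
# miRNA-set (GMT-like) file
# ---------------------------------------------------------------------------

def read_mirna_sets(path: str | Path) -> list[MirnaSetAnnotation]:
    """Read a GMT-like TSV: set name, ignored description, member names."""
    path = Path(path)
    if not path.is_file():
        raise InputError(f"miRNA-set file not found: {path}")
    sets: list[MirnaSetAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                logger.warning("%s:%d: fewer than 3 columns, skipping", path.name, lineno)
                continue
            members = frozenset(m for m in fields[2:] if m)
            if not members:
                logger.warning("%s:%d: set %s has no members, skipping",
                               path.name, lineno, fields[0])
                continue
            sets.append(MirnaSetAnnotation(set_name=fields[0], member_mirna_names=members))
    return sets


def write_mirna_sets(path: str | Path, sets: list[MirnaSetAnnotation]) -> None:
    with open(path, "w") as fh:
        for s in sets:
            members = "\t".join(sorted(s.member_mirna_names))
            fh.write(f"{s.set_name}\tna\t{members}\n")
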