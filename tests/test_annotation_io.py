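"""Format readers: miRBase GFF3, mature FASTA, VCF, miRNA-set file."""

import pytest

from mirseedsnp import io as mio
from mirseedsnp.records import InputError, MatureMirna, MirnaPrecursor

GFF_HEADER = "##gff-version 3\n"


def _write(path, text):
    path.write_text(text)
    return path


def test_well_formed_gff_roundtrip(tmp_path):
    """One precursor with two matures parses completely, and writing the
    parsed records back reproduces them identically."""
    gff = _write(tmp_path / "m.gff3", GFF_HEADER + (
        "chr1\t.\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\tID=MI1;Name=mir-1\n"
        "chr1\t.\tmiRNA\t102\t123\t.\t+\t.\tID=MA1;Name=miR-1-5p;Derives_from=MI1\n"
        "chr1\t.\tmiRNA\t157\t178\t.\t+\t.\tID=MA2;Name=miR-1-3p;Derives_from=MI1\n"
    ))
    precursors, matures, meta = mio.read_mirna_gff(gff)
    assert [p.id for p in precursors] == ["MI1"]
    assert [m.id for m in matures] == ["MA1", "MA2"]
    assert meta["n_rejected"] == 0

    out = tmp_path / "round.gff3"
    mio.write_mirna_gff(out, precursors, matures)
    p2, m2, meta2 = mio.read_mirna_gff(out)
    assert p2 == precursors and m2 == matures and meta2["n_rejected"] == 0


@pytest.mark.parametrize("bad_line, reason", [
    # 6 nt mature: too short to contain a seed
    ("chr1\t.\tmiRNA\t102\t107\t.\t+\t.\tID=MA1;Name=x;Derives_from=MI1\n",
     "mature_invalid"),
    # dangling Derives_from
    ("chr1\t.\tmiRNA\t102\t123\t.\t+\t.\tID=MA1;Name=x;Derives_from=NOPE\n",
     "mature_dangling_derives_from"),
    # strand disagrees with precursor
    ("chr1\t.\tmiRNA\t102\t123\t.\t-\t.\tID=MA1;Name=x;Derives_from=MI1\n",
     "mature_parent_mismatch"),
])
def test_invalid_matures_are_dropped_not_coerced(tmp_path, bad_line, reason):
    gff = _write(tmp_path / "m.gff3", GFF_HEADER + (
        "chr1\t.\tmiRNA_primary_transcript\t100\t180\t.\t+\t.\tID=MI1;Name=mir-1\n"
    ) + bad_line)
    precursors, matures, meta = mio.read_mirna_gff(gff)
    assert len(precursors) == 1
    assert matures == []
    assert meta["reject_reasons"] == {reason: 1}


def test_simulation_gff_roundtrip(small_simulation):
    """Write -> read on generator output is the identity on every record."""
    _, outdir, _ = small_simulation
    precursors, matures, meta = mio.read_mirna_gff(outdir / "mirna.gff3")
    assert meta["n_rejected"] == 0
    out = outdir / "rewritten.gff3"
    mio.write_mirna_gff(out, precursors, matures)
    p2, m2, _ = mio.read_mirna_gff(out)
    assert p2 == precursors and m2 == matures


def _mature(seq_len=22, **kw):
    defaults = dict(id="MA1", name="miR-1", precursor_id="MI1", chrom="chr1",
                    start=100, end=100 + seq_len - 1, strand="+")
    defaults.update(kw)
    return MatureMirna(**defaults)


def test_attach_sequences_rna_and_dna(tmp_path):
    """RNA attaches unchanged; DNA input is transcribed (T -> U)."""
    fasta = _write(tmp_path / "m.fa",
                   ">miR-1\nUGAGGUAGUAGGUUGUAUAGUU\n>miR-2\nTGAGGTAGTAGGTTGTATAGTT\n")
    m1, m2 = _mature(), _mature(id="MA2", name="miR-2")
    out, meta = mio.attach_sequences([m1, m2], fasta)
    assert out[0].sequence == "UGAGGUAGUAGGUUGUAUAGUU"
    assert out[1].sequence == "UGAGGUAGUAGGUUGUAUAGUU"
    assert meta["n_rejected"] == 0


def test_attach_sequences_length_mismatch_is_fatal(tmp_path):
    fasta = _write(tmp_path / "m.fa", ">miR-1\nUGAGGUAGUAGGUUGUAUAGU\n")  # 21 nt
    with pytest.raises(InputError, match="untrustworthy"):
        mio.attach_sequences([_mature()], fasta)


def test_attach_sequences_missing_record_dropped(tmp_path):
    fasta = _write(tmp_path / "m.fa", ">other\nUGAGGUAGUAGGUUGUAUAGUU\n")
    out, meta = mio.attach_sequences([_mature()], fasta)
    assert out == [] and meta["n_rejected"] == 1


VCF_HEADER = ("##fileformat=VCFv4.2\n"
              '##INFO=<ID=AF,Number=A,Type=Float,Description="AF">\n'
              "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")


def test_vcf_snv_parsing(tmp_path):
    """SNVs kept (multiallelic with all single-base ALTs), indels filtered,
    malformed lines skipped, MAF read from the INFO key."""
    vcf = _write(tmp_path / "s.vcf", VCF_HEADER + (
        "chr1\t100\trs1\tA\tG\t.\t.\tAF=0.01\n"
        "chr1\t200\trs2\tA\tG,T\t.\t.\tAF=0.30\n"
        "chr1\t300\trs3\tAT\tA\t.\t.\tAF=0.10\n"      # deletion: dropped
        "chr1\t400\trs4\tA\tG,ATT\t.\t.\t.\n"          # indel ALT filtered
        "garbage line\n"
        "chr1\tXX\trs5\tA\tG\t.\t.\t.\n"               # bad POS
    ))
    snps, meta = mio.read_vcf_snps(vcf)
    assert [s.rsid for s in snps] == ["rs1", "rs2", "rs4"]
    assert snps[1].alt_alleles == ("G", "T")
    assert snps[0].maf == pytest.approx(0.01)
    assert snps[1].maf == pytest.approx(0.30)
    assert snps[2].alt_alleles == ("G",) and snps[2].maf is None
    assert meta["n_malformed_lines"] == 2
    assert meta["n_records_dropped"] == 1
    assert meta["n_indel_alts_filtered"] >= 1


def test_vcf_maf_folds_to_minor_allele(tmp_path):
    """AF above 0.5 is folded: the minor allele frequency is min(f, 1-f)."""
    vcf = _write(tmp_path / "s.vcf", VCF_HEADER +
                 "chr1\t100\trs1\tA\tG\t.\t.\tAF=0.97\n")
    snps, _ = mio.read_vcf_snps(vcf)
    assert snps[0].maf == pytest.approx(0.03)


def test_vcf_with_no_records_is_fatal(tmp_path):
    vcf = _write(tmp_path / "s.vcf", VCF_HEADER + "chr1\t300\trs3\tAT\tA\t.\t.\t.\n")
    with pytest.raises(InputError):
        mio.read_vcf_snps(vcf)


def test_vcf_multimapped_rsid_kept_and_flagged(tmp_path):
    vcf = _write(tmp_path / "s.vcf", VCF_HEADER + (
        "chr1\t100\trs1\tA\tG\t.\t.\t.\n"
        "chr2\t900\trs1\tC\tT\t.\t.\t.\n"
    ))
    snps, meta = mio.read_vcf_snps(vcf)
    assert len(snps) == 2
    assert meta["multi_mapped_rsids"] == ["rs1"]


def test_vcf_roundtrip(small_simulation):
    _, outdir, _ = small_simulation
    snps, _ = mio.read_vcf_snps(outdir / "snps.vcf")
    out = outdir / "rewritten.vcf"
    mio.write_vcf_snps(out, snps)
    snps2, _ = mio.read_vcf_snps(out)
    assert snps2 == sorted(snps, key=lambda s: (s.chrom, s.pos, s.rsid))


def test_mirna_sets_roundtrip_and_validation(tmp_path):
    gmt = _write(tmp_path / "s.gmt", ("PATH_A\tdesc\tmiR-1\tmiR-2\n"
                                      "BAD_NO_MEMBERS\tdesc\n"
                                      "PATH_B\tdesc\tmiR-3\n"))
    sets = mio.read_mirna_sets(gmt)
    assert [s.set_name for s in sets] == ["PATH_A", "PATH_B"]
    assert sets[0].member_mirna_names == {"miR-1", "miR-2"}
    out = tmp_path / "round.gmt"
    mio.write_mirna_sets(out, sets)
    assert mio.read_mirna_sets(out) == sets


def test_utr_fasta_rejects_duplicates_and_empty(tmp_path):
    dup = _write(tmp_path / "d.fa", ">g1\nACGT\n>g1\nACGT\n")
    with pytest.raises(InputError, match="duplicate"):
        mio.read_utr_fasta(dup)
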