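import pytest

from vntrscope import seqio
from vntrscope.detector import RepeatBlock, VntrCall
from vntrscope.haplopaint import HaplotypeSegment


# ---------------------------------------------------------------- read_fasta

def test_read_fasta_case_folds_and_takes_first_token(tmp_path):
    p = tmp_path / "a.fa"
    p.write_text(">x some description\nacgt\n")
    assert seqio.read_fasta(p) == {"x": "ACGT"}


def test_read_fasta_empty_file(tmp_path):
    p = tmp_path / "empty.fa"
    p.write_text("")
    assert seqio.read_fasta(p) == {}


def test_read_fasta_duplicate_id_names_offender(tmp_path):
    p = tmp_path / "dup.fa"
    p.write_text(">x\nACGT\n>x\nTTTT\n")
    with pytest.raises(seqio.FormatError, match="x"):
        seqio.read_fasta(p)


def test_read_fasta_non_iupac_names_offender(tmp_path):
    p = tmp_path / "bad.fa"
    p.write_text(">ok\nACGT\n>weird\nACZT\n")
    with pytest.raises(seqio.FormatError, match="weird"):
        seqio.read_fasta(p)


def test_read_fasta_rejects_headerless_text(tmp_path):
    p = tmp_path / "junk.fa"
    p.write_text("this is not fasta\n")
    with pytest.raises(seqio.FormatError):
        seqio.read_fasta(p)


# --------------------------------------------------------------- extract_cds

GFF_HEADER = "##gff-version 3\n"


def _gff(tmp_path, body):
    p = tmp_path / "ann.gff3"
    p.write_text(GFF_HEADER + body)
    return p


def test_single_exon_plus_strand(tmp_path):
    genome = {"chr1": "AAAAAAAAAACGTCGAAAAA"}
    gff = _gff(tmp_path, "\n".join([
        "chr1\t.\tgene\t11\t16\t.\t+\t.\tID=g1",
        "chr1\t.\tmRNA\t11\t16\t.\t+\t.\tID=t1;Parent=g1",
        "chr1\t.\tCDS\t11\t16\t.\t+\t0\tID=c1;Parent=t1",
    ]) + "\n")
    (rec,) = seqio.extract_cds(genome, gff)
    assert rec.seq == "CGTCGA"
    assert rec.gene_id == "g1"
    assert rec.exon_intervals == ((10, 16),)


def test_two_exon_minus_strand_is_revcomp_of_genomic_concat(tmp_path):
    # exons (1-based) [3,8]="ACGTAA" and [11,16]="GGCCTT";
    # spliced minus-strand CDS = revcomp("ACGTAAGGCCTT") = "AAGGCCTTACGT"
    genome = {"chr1": "NNACGTAANNGGCCTTNN"}
    gff = _gff(tmp_path, "\n".join([
        "chr1\t.\tgene\t3\t16\t.\t-\t.\tID=g1",
        "chr1\t.\tmRNA\t3\t16\t.\t-\t.\tID=t1;Parent=g1",
        "chr1\t.\tCDS\t3\t8\t.\t-\t0\tID=c1a;Parent=t1",
        "chr1\t.\tCDS\t11\t16\t.\t-\t0\tID=c1b;Parent=t1",
    ]) + "\n")
    (rec,) = seqio.extract_cds(genome, gff)
    assert rec.seq == "AAGGCCTTACGT"
    assert rec.strand == "-"
    assert rec.exon_intervals == ((2, 8), (10, 16))


def test_missing_chromosome_rejected(tmp_path):
    gff = _gff(tmp_path, "\n".join([
        "chrZ\t.\tCDS\t1\t6\t.\t+\t0\tID=c1;Parent=t1",
    ]) + "\n")
    with pytest.raises(seqio.FormatError, match="chrZ"):
        seqio.extract_cds({"chr1": "ACGTACGT"}, gff)


def test_mixed_strand_transcript_rejected(tmp_path):
    gff = _gff(tmp_path, "\n".join([
        "chr1\t.\tCDS\t1\t6\t.\t+\t0\tID=c1;Parent=t1",
        "chr1\t.\tCDS\t9\t12\t.\t-\t0\tID=c2;Parent=t1",
    ]) + "\n")
    with pytest.raises(seqio.FormatError, match="mixed"):
        seqio.extract_cds({"chr1": "ACGTACGTACGTACGT"}, gff)


# ------------------------------------------------------------ pair_orthologs

def _cds(gene, tid, seq="ACGTACGT"):
    return seqio.CdsRecord(gene_id=gene, transcript_id=tid, strain="s",
                           chrom="chr1", exon_intervals=((0, len(seq)),),
                           strand="+", seq=seq)


def test_pairing_is_gene_id_intersection():
    pairs, skipped = seqio.pair_orthologs(
        [_cds("g1", "t1"), _cds("g2", "t2")],
        [_cds("g2", "t3"), _cds("g3", "t4")])
    assert [p.gene_id for p in pairs] == ["g2"]
    assert skipped == {"g1": "missing_in_strain", "g3": "missing_in_ref"}


def test_longest_transcript_wins_ties_lexicographic():
    pairs, _ = seqio.pair_orthologs(
        [_cds("g1", "t_b", "ACGTACGTACGT"), _cds("g1", "t_a", "ACGT"),
         _cds("g1", "t_c", "ACGTACGTACGT")],
        [_cds("g1", "s1")])
    assert pairs[0].ref_cds.transcript_id == "t_b"


def test_empty_strain_skips_everything():
    pairs, skipped = seqio.pair_orthologs([_cds("g1", "t1")], [])
    assert pairs == [] and skipped == {"g1": "missing_in_strain"}


def test_paired_plus_skipped_partitions_gene_ids():
    ref = [_cds(f"g{i}", f"t{i}") for i in range(6)]
    strain = [_cds(f"g{i}", f"s{i}") for i in range(3, 9)]
    pairs, skipped = seqio.pair_orthologs(ref, strain)
    paired = {p.gene_id for p in pairs}
    assert paired | set(skipped) == {f"g{i}" for i in range(9)}
    assert not paired & set(skipped)
    assert len(pairs) <= min(6, 6)


# ------------------------------------------------------------- write_outputs

def _block(gene="g1", a=(0, 420), b=(0, 1050), unit=42):
    return RepeatBlock(gene_id=gene, a_span=a, b_span=b, unit_len=unit,
                       copies_a=(a[1] - a[0]) / unit,
                       copies_b=(b[1] - b[0]) / unit,
                       r=(b[1] - b[0]) / (a[1] - a[0]),
                       confidence=0.95, n_diagonals=10)


def test_empty_outputs_have_headers_only(tmp_path):
    paths = seqio.write_outputs([], [], [], tmp_path)
    lines = paths["calls"].read_text().splitlines()
    assert len(lines) == 1 and lines[0].startswith("gene\t")
    assert paths["blocks_ref"].read_text() == ""
    assert paths["paint"].read_text() == ""


def test_single_call_row_fully_populated(tmp_path):
    call = VntrCall(gene_id="g1", strain="cast", blocks=(_block(),),
                    flagged=True, reason="ratio_high")
    paths = seqio.write_outputs([call], [_block()], [], tmp_path)
    header, row = paths["calls"].read_text().splitlines()
    fields = dict(zip(header.split("\t"), row.split("\t")))
    assert fields["gene"] == "g1" and fields["strain"] == "cast"
    assert fields["unit_len"] == "42" and fields["flagged"] == "1"
    assert fields["reason"] == "ratio_high"
    assert float(fields["r"]) == pytest.approx(2.5)


def test_bed_round_trip(tmp_path):
    blocks = [_block("g1", (5, 425)), _block("g2", (100, 940), (7, 847), 28)]
    segs = [HaplotypeSegment("z", 0, 50_000, "b", {"b": 1}),
            HaplotypeSegment("z", 50_000, 100_000, "z", {})]
    paths = seqio.write_outputs([], blocks, segs, tmp_path)
    ref_rows = seqio.read_bed(paths["blocks_ref"])
    assert [(r[0], r[1], r[2]) for r in ref_rows] == \
        [("g1", 5, 425), ("g2", 100, 940)]
    strain_rows = seqio.read_bed(paths["blocks_strain"])
    assert [(r[1], r[2]) for r in strain_rows] == [(0, 1050), (7, 847)]
    paint_rows = seqio.read_bed(paths["paint"])
    assert paint_rows[0][:4] == ("z", 0, 50_000, "b")
    assert paint_rows[1][3] == "z"
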