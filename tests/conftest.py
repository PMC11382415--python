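import pytest

from splicedx.annotation import GenomicInterval, TranscriptModel, TranscriptSet


@pytest.fixture
def three_exon_transcript() -> TranscriptModel:
    """Plus-strand transcript: exons 101-200, 301-400, 501-600 on chr1."""
    return TranscriptModel(
        transcript_id="T1",
        gene_symbol="GENE_A",
        gene_type="protein_coding",
        strand="+",
        exons=[
            GenomicInterval("chr1", 101, 200, "+"),
            GenomicInterval("chr1", 301, 400, "+"),
            GenomicInterval("chr1", 501, 600, "+"),
        ],
        cds_start=101,
        cds_end=600,
    )


@pytest.fixture
def three_exon_ts(three_exon_transcript) -> TranscriptSet:
    return TranscriptSet([three_exon_transcript])


@pytest.fixture
def three_exon_gtf(tmp_path) -> str:
    path = tmp_path / "fixture.gtf"
    attrs = 'gene_id "GENE_A"; transcript_id "T1"; gene_name "GENE_A"; gene_type "protein_coding";'
    lines = [
        f"chr1\ttest\texon\t{s}\t{e}\t.\t+\t.\t{attrs}"
        for s, e in [(101, 200), (301, 400), (501, 600)]
    ]
    path.write_text("\n".join(lines) + "\n")
    return str(path)


def write_sj_file(path, junctions):
    """Write an SJ.out.tab file from [(chrom, start, end, strand, unique), ...]."""
    code = {"+": "1", "-": "2", ".": "0"}
    with open(path, "w") as fh:
        for chrom, s, e, strand, uniq in junctions:
            fh.write(f"{chrom}\t{s}\t{e}\t{code[strand]}\t1\t0\t{uniq}\t0\t30\n")
    return str(path)


VCF_HEADER = """##fileformat=VCFv4.2
##INFO=<ID=FS,Number=1,Type=Float,Description="x">
##INFO=<ID=QD,Number=1,Type=Float,Description="x">
##INFO=<ID=GENE,Number=1,Type=String,Description="x">
##INFO=<ID=GENE_TYPE,Number=1,Type=String,Description="x">
##INFO=<ID=CSQ,Number=1,Type=String,Description="x">
##INFO=<ID=MAF,Number=A,Type=Float,Description="x">
##INFO=<ID=DS_AG,Number=A,Type=Float,Description="x">
##INFO=<ID=DS_AL,Number=A,Type=Float,Description="x">
##INFO=<ID=DS_DG,Number=A,Type=Float,Description="x">
##INFO=<ID=DS_DL,Number=A,Type=Float,Description="x">
##FORMAT=<ID=GT,Number=1,Type=String,Description="x">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="x">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="x">
##contig=<ID=chr1,length=100000000>
##contig=<ID=chr8,length=200000000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tPROBAND
"""


def write_vcf(path, records):
    """Write a single-sample VCF; records are pre-formatted body lines."""
    with open(path, "w") as fh:
        fh.write(VCF_HEADER)
        for line in records:
            fh.write(line + "\n")
    return str(path)


def vcf_record(
    chrom="chr1", pos=1000, ref="C", alt="T", qual=200.0, fs=2.0, qd=20.0,
    gene="GENE_A", gene_type="protein_coding", maf=0.0001,
    sai=(0.85, 0.02, 0.8, 0.05), gq=99, dp=40,
):
    info = (
        f"FS={fs};QD={qd};GENE={gene};GENE_TYPE={gene_type};CSQ=splice_region;"
        f"MAF={maf};DS_AG={sai[0]};DS_AL={sai[1]};DS_DG={sai[2]};DS_DL={sai[3]}"
    )
    return f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t{qual}\t.\t{info}\tGT:GQ:DP\t0/1:{gq}:{dp}"
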