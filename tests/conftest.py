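import pytest

from oncopanel.core_io import AssayConfig, DomainAnnotation, GenomicInterval, TranscriptModel


@pytest.fixture
def config():
    return AssayConfig()


@pytest.fixture
def two_exon_plus():
    """Plus-strand toy transcript: exons [100,200) and [300,400), CDS all-exon."""
    seq1 = "ATG" + "GCA" * 32 + "C"  # 100 nt
    seq2 = "AAACGT" * 16 + "TAAA"  # 100 nt
    return TranscriptModel(
        gene_id="TOY5",
        transcript_id="TOY5-201",
        strand="+",
        exons=(
            GenomicInterval("1", 100, 200),
            GenomicInterval("1", 300, 400),
        ),
        cds_start=100,
        cds_end=400,
        promoter=GenomicInterval("1", 0, 100),
        protein_id="TOY5-P1",
        exon_sequences=(seq1, seq2),
    )


@pytest.fixture
def domains_small():
    return [
        DomainAnnotation(protein_id="P", name="early", aa_start=1, aa_end=10),
        DomainAnnotation(protein_id="P", name="late", aa_start=40, aa_end=60),
    ]
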