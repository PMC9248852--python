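import textwrap

import pytest

from acrkit import genome_io


@pytest.fixture
def tiny_genome_files(tmp_path):
    """One contig, two plus-strand CDS, one minus-strand CDS."""
    fasta = tmp_path / "g.fasta"
    gff = tmp_path / "g.gff3"
    fasta.write_text(">chr1\nAAATTTGGGCCCAAATTTGGGCCCAAATTTGGGCCC\n")
    gff.write_text(
        textwrap.dedent(
            """\
            ##gff-version 3
            chr1\tsrc\tCDS\t1\t9\t.\t+\t0\tID=g1;product=hypothetical protein
            chr1\tsrc\tCDS\t13\t21\t.\t+\t0\tID=g2;protein_id=WP_2;product=DNA polymerase
            chr1\tsrc\tCDS\t25\t33\t.\t-\t0\tID=g3
            """
        )
    )
    return fasta, gff


@pytest.fixture
def tiny_genome(tiny_genome_files):
    return genome_io.read_genome(*tiny_genome_files)
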