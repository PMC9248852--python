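"""Genome, annotation and hit-table I/O.

All coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
and BED (0-based half-open) are converted at the boundary. Reverse-strand
CDS sequences are stored reverse-complemented so that ``nt_seq`` is always
in coding orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

__all__ = [
    "GeneRecord",
    "GenomeRecord",
    "HitRecord",
    "read_genome",
    "read_hits",
    "write_genome",
]


@dataclass
class GeneRecord:
    """A protein-coding gene (CDS) with its coding-orientation sequence.

    ``start``/``end`` are 0-based half-open on the forward strand of
    ``contig``; for a gene on the minus strand ``nt_seq`` is the
    reverse complement of the genomic slice.
    """

    gene_id: str
    contig: str
    start: int
    end: int
    strand: str
    nt_seq: str
    protein_id: str | None = None
    product: str = ""

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end ({self.start} >= {self.end})")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


@dataclass
class GenomeRecord:
    """A genome: contig sequences, its gene models and filtering metadata."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for g in self.genes:
            if g.contig not in self.contigs:
                raise ValueError(f"gene {g.gene_id} references unknown contig {g.contig!r}")
            if g.end > len(self.contigs[g.contig]):
                raise ValueError(
                    f"gene {g.gene_id} end {g.end} exceeds contig {g.contig!r} "
                    f"length {len(self.contigs[g.contig])}"
                )
        self.metadata.setdefault("n_cds", len(self.genes))

    @property
    def n_cds(self) -> int:
        return int(self.metadata["n_cds"])


@dataclass
class HitRecord:
    """One row of a BLAST tabular (outfmt-6 style) similarity search."""

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    mismatches: int
    evalue: float
    query_len: int | None = None
    coverage: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError(f"pct_identity out of [0,100]: {self.pct_identity}")
        if self.evalue < 0:
            raise ValueError(f"negative e-value: {self.evalue}")
        if self.coverage is None and self.query_len:
            self.coverage = self.align_len / self.query_len
        if self.coverage is not None and not 0.0 <= self.coverage <= 1.0:
            raise ValueError(f"coverage out of [0,1]: {self.coverage}")


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def read_genome(fasta_path: str | Path, gff_path: str | Path, genome_id: str | None = None) -> GenomeRecord:
    """Load a genome from a FASTA and its GFF3 CDS annotation.

    Multi-segment CDS (several GFF3 CDS lines sharing one ``ID``) are
    concatenated in transcription order. Genes come back sorted by
    (contig, start). A CDS referencing an unknown contig or lying out of
    bounds raises ``ValueError`` naming the feature.
    """
    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not contigs:
        raise ValueError(f"no sequences parsed from {fasta_path}")

    db = gffutils.create_db(
        str(gff_path), ":memory:", force=True, keep_order=True, merge_strategy="create_unique"
    )
    # group CDS segments by their declared ID so spliced CDS concatenate
    segments: dict[str, list[gffutils.Feature]] = {}
    order: list[str] = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        fid = feat.attributes.get("ID", [feat.id])[0]
        if fid not in segments:
            segments[fid] = []
            order.append(fid)
        segments[fid].append(feat)

    genes: list[GeneRecord] = []
    for fid in order:
        parts = sorted(segments[fid], key=lambda f: f.start)
        contig = parts[0].seqid
        if contig not in contigs:
            raise ValueError(f"CDS {fid!r} references unknown contig {contig!r}")
        strand = parts[0].strand if parts[0].strand in {"+", "-"} else "+"
        pieces = []
        for f in parts:
            start0, end0 = f.start - 1, f.end
            if start0 < 0 or end0 > len(contigs[contig]):
                raise ValueError(f"CDS {fid!r} coordinates {f.start}..{f.end} out of bounds on {contig!r}")
            pieces.append(contigs[contig][start0:end0])
        nt = "".join(pieces)
        if strand == "-":
            nt = _revcomp(nt)
        genes.append(
            GeneRecord(
                gene_id=fid,
                contig=contig,
                start=parts[0].start - 1,
                end=parts[-1].end,
                strand=strand,
                nt_seq=nt,
                protein_id=(parts[0].attributes.get("protein_id") or [None])[0],
                product=(parts[0].attributes.get("product") or [""])[0],
            )
        )
    genes.sort(key=lambda g: (g.contig, g.start))
    gid = genome_id if genome_id is not None else Path(fasta_path).stem
    return GenomeRecord(genome_id=gid, contigs=contigs, genes=genes)


def write_genome(genome: GenomeRecord, fasta_path: str | Path, gff_path: str | Path) -> None:
    """Write contigs to FASTA and gene models to GFF3 (1-based inclusive)."""
    with open(fasta_path, "w") as fh:
        for name in sorted(genome.contigs):
            fh.write(f">{name}\n")
            seq = genome.contigs[name]
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    with open(gff_path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genome.genes:
            attrs = [f"ID={g.gene_id}"]
            if g.protein_id:
                attrs.append(f"protein_id={g.protein_id}")
            if g.product:
                attrs.append(f"product={g.product}")
            fh.write(
                "\t".join(
                    [g.contig, "acrkit", "CDS", str(g.start + 1), str(g.end), ".", g.strand, "0", ";".join(attrs)]
                )
                + "\n"
            )


def read_hits(tsv_path: str | Path) -> list[HitRecord]:
    """Parse a BLAST tabular (outfmt 6) TSV into :class:`HitRecord` rows.

    Expects the standard 12 columns (qseqid sseqid pident length mismatch
    gapopen qstart qend sstart send evalue bitscore) with an optional 13th
    column qlen, from which query coverage is derived. Malformed rows are
    skipped with a logged warning; a file yielding no valid rows is an
    error.
    """
    hits: list[HitRecord] = []
    n_bad = 0
    with open(tsv_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if len(cols) < 12:
                    raise ValueError("fewer than 12 columns")
                qlen = int(cols[12]) if len(cols) >= 13 and cols[12] != "" else None
                hits.append(
                    HitRecord(
                        query_id=cols[0],
                        subject_id=cols[1],
                        pct_identity=float(cols[2]),
                        align_len=int(cols[3]),
                        mismatches=int(cols[4]),
                        evalue=float(cols[10]),
                        query_len=qlen,
                    )
                )
            except (ValueError, IndexError) as exc:
                n_bad += 1
                logger.warning("skipping malformed hit row %d of %s: %s", lineno, tsv_path, exc)
    if not hits:
        raise ValueError(f"no hits parsed from {tsv_path} ({n_bad} malformed rows)")
    if n_bad:
        logger.warning("%d malformed rows skipped in %s", n_bad, tsv_path)
    return hits


def read_metadata(tsv_path: str | Path) -> list[dict]:
    """Read a genome metadata TSV (genome_id, assembly_level, host_domain, n_cds)."""
    import pandas as pd

    df = pd.read_csv(tsv_path, sep="\t", comment="#")
    return df.to_dict(orient="records")


def read_bed(bed_path: str | Path) -> list[tuple[str, int, int]]:
    """Read 3-column BED intervals (0-based half-open)."""
    import pandas as pd

    df = pd.read_csv(
        bed_path, sep="\t", comment="#", header=None, usecols=[0, 1, 2],
        names=["contig", "start", "end"],
    )
    return [(str(r.contig), int(r.start), int(r.end)) for r in df.itertuples()]


def write_bed(intervals: Iterable[tuple[str, int, int]], bed_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for contig, start, end in intervals:
            fh.write(f"{contig}\t{start}\t{end}\n")
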