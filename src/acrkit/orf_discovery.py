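"""Six-frame ORF discovery, intergenic classification and genome filtering.

An ORF runs from an ATG to the first in-frame stop codon (TAA/TAG/TGA;
translation table 11 stops), the stop included in the reported interval.
Nested ORFs sharing a stop are collapsed to the longest (5'-most ATG).
Phage genomes code densely, so an ORF is called *intergenic* when its
nucleotide overlap with the union of all annotated CDS is below a small
fraction of its own length (default 3%, strict).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from Bio.Seq import Seq

from .genome_io import GeneRecord

STOP_CODONS = {"TAA", "TAG", "TGA"}
START_CODON = "ATG"

__all__ = [
    "OrfRecord",
    "FilterReport",
    "find_orfs",
    "overlap_ratio",
    "classify_intergenic",
    "filter_virus_genomes",
]


@dataclass
class OrfRecord:
    """A six-frame ORF in forward-strand coordinates (0-based half-open).

    ``nt_seq`` is the coding-orientation sequence: it begins with ATG and
    ends with a stop codon. ``frame`` is the 0–2 reading offset on the
    scanned strand. ``overlap_ratio`` and ``cls`` are filled in by
    :func:`classify_intergenic`.
    """

    contig: str
    start: int
    end: int
    strand: str
    frame: int
    nt_seq: str
    overlap_ratio: float | None = None
    cls: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def find_orfs(contig_seq: str, min_len_nt: int = 75, contig: str = "contig") -> list[OrfRecord]:
    """Scan all six reading frames of ``contig_seq`` for ORFs.

    Only ORFs of length >= ``min_len_nt`` (stop codon included) are
    returned; ``min_len_nt`` must be a positive multiple of 3. Reverse
    strand ORFs are reported in forward coordinates with ``strand='-'``.
    """
    if min_len_nt < 3 or min_len_nt % 3:
        raise ValueError(f"min_len_nt must be a positive multiple of 3, got {min_len_nt}")
    seq = contig_seq.upper()
    L = len(seq)
    orfs: list[OrfRecord] = []
    for strand in ("+", "-"):
        s = seq if strand == "+" else str(Seq(seq).reverse_complement())
        for frame in range(3):
            start: int | None = None  # scanned-strand coord of 5'-most ATG since last stop
            for pos in range(frame, L - 2, 3):
                codon = s[pos : pos + 3]
                if codon in STOP_CODONS:
                    if start is not None:
                        end = pos + 3
                        if end - start >= min_len_nt:
                            if strand == "+":
                                fwd = (start, end)
                            else:
                                fwd = (L - end, L - start)
                            orfs.append(
                                OrfRecord(
                                    contig=contig,
                                    start=fwd[0],
                                    end=fwd[1],
                                    strand=strand,
                                    frame=frame,
                                    nt_seq=s[start:end],
                                )
                            )
                        start = None
                elif codon == START_CODON and start is None:
                    start = pos
    orfs.sort(key=lambda o: (o.start, o.end, o.strand, o.frame))
    return orfs


def _union_overlap(start: int, end: int, intervals: Iterable[tuple[int, int]]) -> int:
    """Length of the union of ``intervals`` clipped to [start, end)."""
    clipped = sorted(
        (max(start, a), min(end, b)) for a, b in intervals if max(start, a) < min(end, b)
    )
    total = 0
    cur_s: int | None = None
    cur_e = 0
    for a, b in clipped:
        if cur_s is None:
            cur_s, cur_e = a, b
        elif a <= cur_e:
            cur_e = max(cur_e, b)
        else:
            total += cur_e - cur_s
            cur_s, cur_e = a, b
    if cur_s is not None:
        total += cur_e - cur_s
    return total


def overlap_ratio(orf: OrfRecord, cds_list: list[GeneRecord]) -> float:
    """Fraction of the ORF covered by the union of all CDS intervals.

    Strand-agnostic; the denominator is the ORF's own length.
    """
    if orf.length <= 0:
        raise ValueError("zero-length ORF")
    intervals = [(g.start, g.end) for g in cds_list if g.contig == orf.contig]
    return _union_overlap(orf.start, orf.end, intervals) / orf.length


def classify_intergenic(
    orfs: list[OrfRecord], cds_list: list[GeneRecord], threshold: float = 0.03
) -> dict[str, list[OrfRecord]]:
    """Partition ORFs into intergenic vs. CDS-overlapping classes.

    An ORF is intergenic iff its overlap ratio is strictly below
    ``threshold``. Sets ``overlap_ratio`` and ``cls`` on every record and
    returns the partition ``{"intergenic": [...], "cds_overlapping": [...]}``.
    """
    if not 0.0 <= threshold < 1.0:
        raise ValueError(f"threshold must lie in [0, 1), got {threshold}")
    out: dict[str, list[OrfRecord]] = {"intergenic": [], "cds_overlapping": []}
    for orf in orfs:
        r = overlap_ratio(orf, cds_list)
        orf.overlap_ratio = r
        orf.cls = "intergenic" if r < threshold else "cds_overlapping"
        out[orf.cls].append(orf)
    return out


@dataclass
class FilterReport:
    """Outcome of the virus-genome inclusion filter for one genome."""

    genome_id: str
    passed: bool
    reasons: list[str]


_PROKARYOTE_HOSTS = {"bacteria", "archaea"}


def filter_virus_genomes(metadata: Iterable[Mapping]) -> list[FilterReport]:
    """Apply the virus-genome inclusion filter to metadata rows.

    A genome passes iff its assembly level is "complete", its host domain
    is bacteria or archaea, and its CDS count lies in 20–50 inclusive.
    A missing field fails the row with a ``missing_<field>`` reason
    instead of raising.
    """
    reports: list[FilterReport] = []
    for row in metadata:
        reasons: list[str] = []
        gid = str(row.get("genome_id", "?"))
        level = row.get("assembly_level")
        if level is None:
            reasons.append("missing_assembly_level")
        elif str(level).strip().lower() != "complete":
            reasons.append("not_complete")
        host = row.get("host_domain")
        if host is None:
            reasons.append("missing_host_domain")
        elif str(host).strip().lower() not in _PROKARYOTE_HOSTS:
            reasons.append("non_prokaryote_host")
        n_cds = row.get("n_cds")
        if n_cds is None:
            reasons.append("missing_n_cds")
        elif not 20 <= int(n_cds) <= 50:
            reasons.append("cds_out_of_range")
        reports.append(FilterReport(genome_id=gid, passed=not reasons, reasons=reasons))
    return reports
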