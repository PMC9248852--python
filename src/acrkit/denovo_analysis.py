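"""De-novo-origin deviation analysis for anti-CRISPR genes.

Genes born de novo from ancestrally non-genic DNA should carry the codon
usage of intergenic sequence rather than of the genome's coding genes.
For each putative acr we therefore compute two CUB distances — against
the pooled annotated CDS and against the pooled intergenic ORFs — and
report their difference:

    deviation = CUB(acr vs CDS pool) - CUB(acr vs intergenic-ORF pool).

A positive deviation means the acr's codon usage sits closer to the
intergenic pool, the de novo signature; a mostly-positive deviation
distribution across genomes supports de novo birth.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_stats import CodonFrequencyVector, count_codons, cub_distance, pooled_vector
from .genome_io import GeneRecord, HitRecord
from .orf_discovery import OrfRecord

__all__ = ["DeviationRecord", "pinpoint_acrs", "compute_deviation", "summarize_deviation"]


@dataclass
class DeviationRecord:
    """Per-acr CUB against the CDS pool vs. the intergenic-ORF pool."""

    acr_id: str
    genome_id: str
    cub_cds: float
    cub_inter: float

    @property
    def deviation(self) -> float:
        return self.cub_cds - self.cub_inter


def pinpoint_acrs(hits: list[HitRecord], evalue_cutoff: float) -> set[str]:
    """Subject CDS ids hit by a verified-Acr query at e-value <= cutoff.

    The cutoff is inclusive; the returned set is deduplicated.
    """
    if evalue_cutoff < 0:
        raise ValueError(f"negative e-value cutoff: {evalue_cutoff}")
    return {h.subject_id for h in hits if h.evalue <= evalue_cutoff}


def compute_deviation(
    acr_genes: list[GeneRecord],
    cds_pool: list[GeneRecord],
    interorf_pool: list[OrfRecord],
    genome_id: str = "",
    exclude_acr_from_cds: bool = True,
) -> list[DeviationRecord]:
    """Compute the de novo deviation for each acr gene of one genome.

    ``cds_pool`` is the genome's annotated CDS and ``interorf_pool`` its
    intergenic ORFs. By default the focal acr is left out of the CDS pool
    so the reference is not contaminated by the very gene being measured
    (toggle with ``exclude_acr_from_cds``).
    """
    if not cds_pool:
        raise ValueError(f"genome {genome_id!r}: empty CDS pool")
    if not interorf_pool:
        raise ValueError(f"genome {genome_id!r}: empty intergenic-ORF pool, cannot compute deviation")
    inter_vec = count_codons("".join(o.nt_seq for o in interorf_pool))
    if inter_vec.n_codons == 0:
        raise ValueError(f"genome {genome_id!r}: intergenic pool has zero codons")
    full_cds_vec = pooled_vector(cds_pool)
    records: list[DeviationRecord] = []
    for acr in acr_genes:
        acr_vec = count_codons(acr.nt_seq)
        if acr_vec.n_codons == 0:
            raise ValueError(f"acr {acr.gene_id}: no codons")
        if exclude_acr_from_cds and any(g.gene_id == acr.gene_id for g in cds_pool):
            rest = [g for g in cds_pool if g.gene_id != acr.gene_id]
            if not rest:
                raise ValueError(f"genome {genome_id!r}: CDS pool contains only the acr itself")
            cds_vec: CodonFrequencyVector = pooled_vector(rest)
        else:
            cds_vec = full_cds_vec
        records.append(
            DeviationRecord(
                acr_id=acr.gene_id,
                genome_id=genome_id,
                cub_cds=cub_distance(acr_vec, cds_vec),
                cub_inter=cub_distance(acr_vec, inter_vec),
            )
        )
    return records


def summarize_deviation(records: list[DeviationRecord], bin_width: float = 0.01) -> dict:
    """Summarize a deviation distribution.

    Returns the record count, the fraction of strictly positive
    deviations, and a deterministic histogram with bins of ``bin_width``
    aligned to multiples of the bin width.
    """
    if not records:
        raise ValueError("no deviation records to summarize")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    dev = np.array([r.deviation for r in records])
    lo = np.floor(dev.min() / bin_width) * bin_width
    hi = np.ceil(dev.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    counts, edges = np.histogram(dev, bins=edges)
    return {
        "n": len(records),
        "fraction_positive": float((dev > 0).sum()) / len(records),
        "histogram": {"edges": edges.tolist(), "counts": counts.tolist()},
    }
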