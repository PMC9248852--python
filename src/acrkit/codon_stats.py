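"""Codon frequency vectors, the codon-usage-bias (CUB) distance and CUBRank.

A gene's codon usage is summarized as a 64-bin frequency vector over the
DNA triplets TTT, TTC, TTA ... GGG (base order T, C, A, G). The CUB of a
gene against a reference pool is the Euclidean distance between the two
frequency vectors,

    d_i = sqrt( sum_j (f_ij - f_wj)^2 ),

where the reference profile f_w comes from an "artificial gene" built by
concatenating every protein-coding gene of the genome. Sorting a genome's
genes by d_i from largest to smallest and taking 1-based positions yields
CUBRank: rank 1 is the gene whose codon usage deviates most from its host,
the signature expected of horizontally transferred or de-novo-born genes.

All 64 codons are counted, stop codons included: the concatenated
artificial gene contains internal stops, and excluding bins would silently
change the geometry of the distance.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np

from .genome_io import GeneRecord, GenomeRecord

logger = logging.getLogger(__name__)

#: the 64 DNA codons in the classical codon-table order TTT, TTC, ... GGG
CODONS: tuple[str, ...] = tuple("".join(p) for p in itertools.product("TCAG", repeat=3))
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}

__all__ = ["CODONS", "CodonFrequencyVector", "CubResult", "count_codons", "pooled_vector", "cub_distance", "cubrank"]


@dataclass
class CodonFrequencyVector:
    """Codon counts and normalized frequencies of a gene or gene pool."""

    _counts: np.ndarray
    n_skipped: int = 0

    @property
    def n_codons(self) -> int:
        return int(self._counts.sum())

    @property
    def counts(self) -> dict[str, int]:
        return {c: int(n) for c, n in zip(CODONS, self._counts)}

    @property
    def freqs(self) -> dict[str, float]:
        return {c: float(f) for c, f in zip(CODONS, self.freq_array)}

    @property
    def freq_array(self) -> np.ndarray:
        n = self._counts.sum()
        if n == 0:
            return np.zeros(64, dtype=float)
        return self._counts / float(n)

    @property
    def count_array(self) -> np.ndarray:
        return self._counts.copy()


def count_codons(nt_seq: str) -> CodonFrequencyVector:
    """Count non-overlapping triplets of ``nt_seq`` read from position 0.

    Triplets containing non-ACGT characters are dropped and tallied in
    ``n_skipped``, as is any trailing 1–2 nt remainder. A sequence shorter
    than one codon yields an empty vector with a logged warning.
    """
    seq = nt_seq.upper()
    counts = np.zeros(64, dtype=np.int64)
    skipped = 0
    n_full = len(seq) // 3
    for i in range(n_full):
        codon = seq[3 * i : 3 * i + 3]
        idx = CODON_INDEX.get(codon)
        if idx is None:
            skipped += 1
        else:
            counts[idx] += 1
    if len(seq) % 3:
        skipped += 1
    if n_full == 0:
        logger.warning("sequence shorter than one codon (%d nt); empty vector", len(seq))
    return CodonFrequencyVector(counts, n_skipped=skipped)


def pooled_vector(genes: list[GeneRecord]) -> CodonFrequencyVector:
    """Codon vector of the artificial gene: all coding sequences concatenated.

    Equivalent to ``count_codons`` on the concatenation of every
    ``nt_seq`` in input order (so when some gene length is not a multiple
    of 3, codons spanning a junction are read exactly as the concatenated
    artificial gene dictates).
    """
    if not genes:
        raise ValueError("pooled_vector requires at least one gene")
    return count_codons("".join(g.nt_seq for g in genes))


def cub_distance(f_i: CodonFrequencyVector, f_w: CodonFrequencyVector) -> float:
    """Euclidean distance between two 64-bin codon frequency vectors.

    Symmetric, bounded by sqrt(2); both vectors must be non-empty.
    """
    if f_i.n_codons == 0 or f_w.n_codons == 0:
        raise ValueError("cub_distance requires non-empty codon vectors")
    return float(np.linalg.norm(f_i.freq_array - f_w.freq_array))


@dataclass
class CubResult:
    """Per-gene CUB distance, its genome rank and percentile.

    ``rank`` is the 1-based position after a stable descending sort of
    the distances (rank 1 = strongest bias); ``percentile`` is
    rank / number of protein-coding genes, in (0, 1].
    """

    gene_id: str
    distance: float
    rank: int
    percentile: float


def cubrank(genome: GenomeRecord) -> list[CubResult]:
    """Rank every protein-coding gene of ``genome`` by CUB distance.

    The reference profile pools all protein-coding genes, the focal gene
    included. Ties in distance are broken by input gene order (stable
    sort), so ranks are always a permutation of 1..n. Results are
    returned in input gene order.
    """
    genes = genome.genes
    if not genes:
        raise ValueError(f"genome {genome.genome_id}: no protein-coding genes")
    pool = pooled_vector(genes)
    if pool.n_codons == 0:
        raise ValueError(f"genome {genome.genome_id}: zero codons in total")
    vectors = [count_codons(g.nt_seq) for g in genes]
    dists = np.array([cub_distance(v, pool) if v.n_codons else 0.0 for v in vectors])
    n = len(genes)
    # stable descending sort: sort on negated distance keeps input order on ties
    order = np.argsort(-dists, kind="stable")
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(1, n + 1)
    return [
        CubResult(gene_id=g.gene_id, distance=float(d), rank=int(r), percentile=float(r) / n)
        for g, d, r in zip(genes, dists, ranks)
    ]
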