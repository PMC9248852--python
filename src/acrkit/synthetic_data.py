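"""Seeded generators for every input the analysis modules consume.

Real inputs for these analyses are thousands of NCBI genomes; the
generators below emulate their statistical structure at desk scale so
the full pipeline can run and be tested without any download. Codon
usage is modeled by Dirichlet-sampled codon distributions concentrated
on two disjoint preferred-codon sets; a ``separation`` weight in [0, 1]
linearly interpolates a gene pool from the background model toward the
alternative one, standing in for horizontal transfer (shifted genes,
genomic islands) or de novo birth (acrs sharing the intergenic model).

All generators are pure functions of their arguments: the same seed
gives byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .codon_stats import CODONS
from .genome_io import GeneRecord, GenomeRecord
from .orf_discovery import STOP_CODONS, OrfRecord

__all__ = [
    "CodonModel",
    "make_codon_models",
    "make_host_genome",
    "make_phage_genome",
    "make_gi_genome",
    "make_hit_table",
]

_SENSE = np.array([i for i, c in enumerate(CODONS) if c not in STOP_CODONS])
_STOPS = [CODONS.index(c) for c in sorted(STOP_CODONS)]


@dataclass
class CodonModel:
    """A 64-bin codon distribution; stop codons carry zero internal mass."""

    probs: np.ndarray
    label: str

    def __post_init__(self) -> None:
        if self.probs.shape != (64,) or not np.isclose(self.probs.sum(), 1.0):
            raise ValueError("probs must be a 64-vector summing to 1")

    def mix(self, other: "CodonModel", weight: float) -> "CodonModel":
        """Linear interpolation toward ``other`` with the given weight."""
        if not 0.0 <= weight <= 1.0:
            raise ValueError(f"separation/mixing weight must lie in [0,1], got {weight}")
        return CodonModel(
            probs=(1.0 - weight) * self.probs + weight * other.probs,
            label=f"{self.label}~{weight:g}~{other.label}",
        )


def make_codon_models(seed: int | np.random.Generator) -> tuple[CodonModel, CodonModel]:
    """Two codon models concentrated on disjoint halves of the sense codons."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pref_a, pref_b = _SENSE[::2], _SENSE[1::2]
    models = []
    for pref, label in ((pref_a, "background"), (pref_b, "alternative")):
        alpha = np.full(len(_SENSE), 0.2)
        alpha[np.isin(_SENSE, pref)] = 5.0
        probs = np.zeros(64)
        probs[_SENSE] = rng.dirichlet(alpha)
        models.append(CodonModel(probs=probs, label=label))
    return models[0], models[1]


def _sample_cds(rng: np.random.Generator, model: CodonModel, n_codons: int) -> str:
    """A coding sequence: ATG, internal codons from the model, one stop."""
    if n_codons < 3:
        raise ValueError("a coding sequence needs at least 3 codons")
    internal = rng.choice(64, size=n_codons - 2, p=model.probs)
    stop = CODONS[_STOPS[rng.integers(len(_STOPS))]]
    return "ATG" + "".join(CODONS[i] for i in internal) + stop


def _random_pad(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _assemble(
    rng: np.random.Generator,
    coding_seqs: list[str],
    strands: list[str],
    gap_len_range: tuple[int, int],
    contig: str,
    gene_prefix: str = "gene",
) -> tuple[str, list[GeneRecord]]:
    from .genome_io import _revcomp

    parts: list[str] = []
    genes: list[GeneRecord] = []
    pos = 0
    for i, (seq, strand) in enumerate(zip(coding_seqs, strands)):
        pad = _random_pad(rng, int(rng.integers(gap_len_range[0], gap_len_range[1] + 1)))
        parts.append(pad)
        pos += len(pad)
        genomic = seq if strand == "+" else _revcomp(seq)
        parts.append(genomic)
        genes.append(
            GeneRecord(
                gene_id=f"{gene_prefix}{i:04d}",
                contig=contig,
                start=pos,
                end=pos + len(seq),
                strand=strand,
                nt_seq=seq,
                protein_id=f"{gene_prefix.upper()}{i:04d}",
                product="hypothetical protein",
            )
        )
        pos += len(seq)
    parts.append(_random_pad(rng, int(rng.integers(gap_len_range[0], gap_len_range[1] + 1))))
    return "".join(parts), genes


def make_host_genome(
    n_genes: int,
    n_shifted: int,
    separation: float,
    seed: int,
    gene_len_range: tuple[int, int] = (150, 600),
    genome_id: str | None = None,
) -> tuple[GenomeRecord, list[bool]]:
    """A host genome whose minority of genes carries a shifted codon bias.

    Background genes are drawn from the background codon model, the
    ``n_shifted`` genes from the background mixed toward the alternative
    model with weight ``separation`` (0 = identical, 1 = fully
    alternative). Returns the genome and per-gene truth labels aligned
    with ``genome.genes`` (True = shifted).
    """
    if not 0 <= n_shifted <= n_genes:
        raise ValueError("need 0 <= n_shifted <= n_genes")
    rng = np.random.default_rng(seed)
    background, alternative = make_codon_models(rng)
    shifted_model = background.mix(alternative, separation)
    shifted_idx = set(rng.choice(n_genes, size=n_shifted, replace=False).tolist())
    seqs, strands, labels = [], [], []
    for i in range(n_genes):
        model = shifted_model if i in shifted_idx else background
        n_codons = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        seqs.append(_sample_cds(rng, model, n_codons))
        strands.append("+" if rng.random() < 0.5 else "-")
        labels.append(i in shifted_idx)
    contig = "contig1"
    seq, genes = _assemble(rng, seqs, strands, (20, 100), contig)
    gid = genome_id or f"host_s{seed}"
    genome = GenomeRecord(
        genome_id=gid,
        contigs={contig: seq},
        genes=genes,
        metadata={"assembly_level": "complete", "host_domain": "bacteria", "n_cds": n_genes},
    )
    return genome, labels


def make_gi_genome(
    n_genes: int,
    n_gi_genes: int,
    separation: float,
    seed: int,
    gene_len_range: tuple[int, int] = (150, 600),
) -> tuple[GenomeRecord, list[tuple[str, int, int]], list[bool]]:
    """A genome with one contiguous genomic island of bias-shifted genes.

    The ``n_gi_genes`` island genes are packed into a contiguous block of
    gene positions and emitted as a single BED-style interval. Returns
    (genome, intervals, truth labels aligned with ``genome.genes``).
    """
    if not 0 < n_gi_genes <= n_genes:
        raise ValueError("need 0 < n_gi_genes <= n_genes")
    rng = np.random.default_rng(seed)
    background, alternative = make_codon_models(rng)
    shifted_model = background.mix(alternative, separation)
    block_start = int(rng.integers(0, n_genes - n_gi_genes + 1))
    gi_idx = range(block_start, block_start + n_gi_genes)
    seqs, strands, labels = [], [], []
    for i in range(n_genes):
        in_gi = i in gi_idx
        model = shifted_model if in_gi else background
        n_codons = int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))
        seqs.append(_sample_cds(rng, model, n_codons))
        strands.append("+" if rng.random() < 0.5 else "-")
        labels.append(in_gi)
    contig = "contig1"
    seq, genes = _assemble(rng, seqs, strands, (20, 100), contig)
    first, last = genes[block_start], genes[block_start + n_gi_genes - 1]
    intervals = [(contig, first.start, last.end)]
    genome = GenomeRecord(
        genome_id=f"gi_s{seed}",
        contigs={contig: seq},
        genes=genes,
        metadata={"assembly_level": "complete", "host_domain": "bacteria", "n_cds": n_genes},
    )
    return genome, intervals, labels


# a stop in the planted ORF's frame in each of its three upstream codon
# slots, so no upstream ATG can run through into the planted interval
_ORF_GUARD = "TAATAATAA"


def make_phage_genome(
    n_cds: int = 30,
    n_intergenic_orfs: int = 8,
    n_acrs: int = 4,
    acr_source: str = "intergenic_like",
    separation: float = 0.8,
    seed: int = 0,
    cds_len_range: tuple[int, int] = (150, 300),
    orf_len_range: tuple[int, int] = (80, 160),
    acr_len_range: tuple[int, int] = (62, 202),
    gap_len_range: tuple[int, int] = (40, 120),
) -> tuple[GenomeRecord, list[OrfRecord], list[str]]:
    """A phage-like genome: dense CDS plus planted intergenic ORFs.

    ``n_cds`` annotated CDS are drawn from the CDS codon model;
    ``n_acrs`` of them are the acrs, drawn from the intergenic model
    when ``acr_source='intergenic_like'`` (the de novo scenario) or from
    the CDS model when ``'cds_like'``. The intergenic model is the CDS
    model mixed toward the alternative codon preference with weight
    ``separation`` (0 makes all pools share one distribution — the null
    condition). Planted ORFs sit wholly inside annotation gaps, each
    preceded by in-frame stop codons so a six-frame scan recovers
    exactly the planted interval. Lengths are in codons.

    Returns (genome, truth intergenic OrfRecords, acr gene ids); the
    genome's metadata passes the virus-genome filter by construction
    when 20 <= n_cds <= 50.
    """
    if acr_source not in {"intergenic_like", "cds_like"}:
        raise ValueError(f"acr_source must be 'intergenic_like' or 'cds_like', got {acr_source!r}")
    if not 0 <= n_acrs <= n_cds:
        raise ValueError("need 0 <= n_acrs <= n_cds")
    if n_intergenic_orfs > n_cds + 1:
        raise ValueError(
            f"{n_intergenic_orfs} intergenic ORFs cannot fit: only {n_cds + 1} annotation gaps"
        )
    rng = np.random.default_rng(seed)
    cds_model, alternative = make_codon_models(rng)
    intergenic_model = cds_model.mix(alternative, separation)
    acr_model = intergenic_model if acr_source == "intergenic_like" else cds_model

    acr_idx = set(rng.choice(n_cds, size=n_acrs, replace=False).tolist()) if n_acrs else set()
    orf_slots = set(rng.choice(n_cds + 1, size=n_intergenic_orfs, replace=False).tolist())

    contig = "phage1"
    parts: list[str] = []
    genes: list[GeneRecord] = []
    truth_orfs: list[OrfRecord] = []
    pos = 0

    def emit_gap(slot: int) -> None:
        nonlocal pos
        pad = _random_pad(rng, int(rng.integers(gap_len_range[0], gap_len_range[1] + 1)))
        parts.append(pad)
        pos += len(pad)
        if slot in orf_slots:
            n_codons = int(rng.integers(orf_len_range[0], orf_len_range[1] + 1))
            # +2 codons: _sample_cds counts the ATG and stop; planted length
            # below is the full nucleotide interval including the stop
            orf_seq = _sample_cds(rng, intergenic_model, n_codons)
            parts.append(_ORF_GUARD)
            pos += len(_ORF_GUARD)
            truth_orfs.append(
                OrfRecord(
                    contig=contig,
                    start=pos,
                    end=pos + len(orf_seq),
                    strand="+",
                    frame=pos % 3,
                    nt_seq=orf_seq,
                )
            )
            parts.append(orf_seq)
            pos += len(orf_seq)
            tail = _random_pad(rng, int(rng.integers(gap_len_range[0], gap_len_range[1] + 1)))
            parts.append(tail)
            pos += len(tail)

    for i in range(n_cds):
        emit_gap(i)
        is_acr = i in acr_idx
        lo, hi = acr_len_range if is_acr else cds_len_range
        n_codons = int(rng.integers(lo, hi + 1))
        seq = _sample_cds(rng, acr_model if is_acr else cds_model, n_codons)
        prefix = "acr" if is_acr else "cds"
        genes.append(
            GeneRecord(
                gene_id=f"{prefix}{i:04d}",
                contig=contig,
                start=pos,
                end=pos + len(seq),
                strand="+",
                nt_seq=seq,
                protein_id=f"{prefix.upper()}{i:04d}",
                product="hypothetical protein",
            )
        )
        parts.append(seq)
        pos += len(seq)
    emit_gap(n_cds)

    genome = GenomeRecord(
        genome_id=f"phage_s{seed}",
        contigs={contig: "".join(parts)},
        genes=genes,
        metadata={"assembly_level": "complete", "host_domain": "bacteria", "n_cds": n_cds},
    )
    acr_ids = [g.gene_id for g in genes if g.gene_id.startswith("acr")]
    return genome, truth_orfs, acr_ids


_RULESETS = {
    "catalog": {"evalue": 0.01, "identity": 35.0},
    "pdb": {"evalue": 1e-10, "mismatch": 1, "coverage": 0.95},
    "acr": {"evalue": 1e-3},
}


def make_hit_table(
    n_rows: int,
    fraction_passing: float,
    ruleset: str = "catalog",
    seed: int = 0,
    thresholds: dict | None = None,
) -> tuple[list[str], list[bool]]:
    """A BLAST-tabular hit table straddling a rule-set's thresholds.

    ``ruleset`` is one of 'catalog' (e-value <= 0.01 and identity >=
    35%), 'pdb' (e-value <= 1e-10, mismatches <= 1, coverage >= 95%) or
    'acr' (e-value <= cutoff). The first two rows sit exactly at and
    just beyond the boundary; remaining rows pass or fail at
    ``fraction_passing``. Returns (TSV lines incl. qlen column, truth
    accept labels).
    """
    if ruleset not in _RULESETS:
        raise ValueError(f"unknown ruleset {ruleset!r}; choose from {sorted(_RULESETS)}")
    if not 0.0 <= fraction_passing <= 1.0:
        raise ValueError("fraction_passing must lie in [0,1]")
    thr = dict(_RULESETS[ruleset])
    if thresholds:
        thr.update(thresholds)
    rng = np.random.default_rng(seed)
    lines: list[str] = []
    truth: list[bool] = []
    qlen = 100
    for i in range(n_rows):
        if i == 0:
            passing, boundary = True, True  # exactly at every threshold
        elif i == 1:
            passing, boundary = False, True  # just beyond one threshold
        else:
            passing, boundary = bool(rng.random() < fraction_passing), False

        evalue = thr["evalue"]
        identity = thr.get("identity", 50.0)
        mismatch = thr.get("mismatch", 0)
        align_len = int(round(thr.get("coverage", 0.5) * qlen))
        if not boundary:
            if passing:
                evalue = thr["evalue"] * rng.uniform(1e-3, 1.0)
                if "identity" in thr:
                    identity = rng.uniform(thr["identity"], 99.0)
                if "coverage" in thr:
                    align_len = int(rng.integers(round(thr["coverage"] * qlen), qlen + 1))
                if "mismatch" in thr:
                    mismatch = int(rng.integers(0, thr["mismatch"] + 1))
            else:
                fail_on = rng.choice(sorted(thr))
                if fail_on == "evalue":
                    evalue = thr["evalue"] * rng.uniform(1.01, 100.0)
                elif fail_on == "identity":
                    identity = rng.uniform(5.0, thr["identity"] - 0.1)
                elif fail_on == "coverage":
                    align_len = int(rng.integers(10, round(thr["coverage"] * qlen) - 1))
                elif fail_on == "mismatch":
                    mismatch = int(thr["mismatch"]) + int(rng.integers(1, 5))
        elif not passing:
            evalue = thr["evalue"] * 1.01

        accept = evalue <= thr["evalue"]
        if "identity" in thr:
            accept = accept and identity >= thr["identity"]
        if "mismatch" in thr:
            accept = accept and mismatch <= thr["mismatch"]
        if "coverage" in thr:
            accept = accept and align_len / qlen >= thr["coverage"]
        truth.append(bool(accept))
        lines.append(
            "\t".join(
                [
                    f"q{i:04d}",
                    f"s{i:04d}",
                    f"{identity:.1f}",
                    str(align_len),
                    str(mismatch),
                    "0",
                    "1",
                    str(align_len),
                    "1",
                    str(align_len),
                    f"{evalue:.6g}",
                    "50.0",
                    str(qlen),
                ]
            )
        )
    return lines, truth
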