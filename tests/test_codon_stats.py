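import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acrkit import synthetic_data
from acrkit.codon_stats import (
    CODONS,
    count_codons,
    cub_distance,
    cubrank,
    pooled_vector,
)
from acrkit.genome_io import GeneRecord, GenomeRecord


def oracle_freqs(seq: str) -> dict[str, float]:
    """Independent codon-frequency computation via Counter."""
    counts = Counter(
        seq[i : i + 3] for i in range(0, len(seq) - len(seq) % 3, 3) if set(seq[i : i + 3]) <= set("ACGT")
    )
    total = sum(counts.values())
    return {c: counts.get(c, 0) / total for c in CODONS}


def oracle_distance(seq_a: str, seq_b: str) -> float:
    fa, fb = oracle_freqs(seq_a), oracle_freqs(seq_b)
    return math.sqrt(sum((fa[c] - fb[c]) ** 2 for c in CODONS))


def _gene(gid: str, seq: str) -> GeneRecord:
    return GeneRecord(gene_id=gid, contig="c", start=0, end=len(seq), strand="+", nt_seq=seq)


def _genome(seqs: list[str]) -> GenomeRecord:
    contig = "".join(seqs)
    genes, pos = [], 0
    for i, s in enumerate(seqs):
        genes.append(GeneRecord(gene_id=f"g{i}", contig="c", start=pos, end=pos + len(s), strand="+", nt_seq=s))
        pos += len(s)
    return GenomeRecord(genome_id="toy", contigs={"c": contig}, genes=genes)


@pytest.mark.parametrize(
    "seq,expected_counts,n_skipped",
    [
        ("ATGAAATAA", {"ATG": 1, "AAA": 1, "TAA": 1}, 0),
        ("ATGANATAA", {"ATG": 1, "TAA": 1}, 1),
        ("ATGAAATA", {"ATG": 1, "AAA": 1}, 1),  # 2 nt remainder dropped
    ],
)
def test_count_codons_examples(seq, expected_counts, n_skipped):
    vec = count_codons(seq)
    assert {c: n for c, n in vec.counts.items() if n} == expected_counts
    assert vec.n_skipped == n_skipped
    assert vec.n_codons == sum(expected_counts.values())


def test_count_codons_short_sequence_warns_not_raises():
    assert count_codons("AT").n_codons == 0


def test_frequencies_sum_to_one():
    vec = count_codons("ATGAAACCCGGGTAA")
    assert sum(vec.freqs.values()) == pytest.approx(1.0)


def test_pooled_vector_concatenation_and_identity():
    g = _gene("g", "ATGTAA")
    pooled = pooled_vector([g, _gene("h", "ATGTAA")])
    assert {c: n for c, n in pooled.counts.items() if n} == {"ATG": 2, "TAA": 2}
    single = pooled_vector([g])
    assert single.counts == count_codons(g.nt_seq).counts
    with pytest.raises(ValueError):
        pooled_vector([])


def test_pooled_counts_equal_sum_of_per_gene_counts():
    rng = np.random.default_rng(11)
    genes = [
        _gene(f"g{i}", "".join(rng.choice(CODONS, size=rng.integers(5, 40))))
        for i in range(5)
    ]
    pooled = pooled_vector(genes).count_array
    summed = sum(count_codons(g.nt_seq).count_array for g in genes)
    assert (pooled == summed).all()


def test_cub_distance_identity_and_maximal_separation():
    v = count_codons("ATGAAATAA")
    assert cub_distance(v, v) == 0.0
    assert cub_distance(count_codons("TTTTTT"), count_codons("GGGGGG")) == pytest.approx(math.sqrt(2))


def test_cub_distance_matches_independent_oracle():
    seqs = ["ATGAAACCCGGGTAA", "ATGTTTTTCTTATAG", "ATGGGCGGGAAATGA"]
    genome = _genome(seqs)
    pool_seq = "".join(seqs)
    for g in genome.genes:
        expected = oracle_distance(g.nt_seq, pool_seq)
        got = cub_distance(count_codons(g.nt_seq), pooled_vector(genome.genes))
        assert got == pytest.approx(expected, abs=1e-12)


def test_cub_distance_rejects_empty_vectors():
    with pytest.raises(ValueError):
        cub_distance(count_codons(""), count_codons("ATG"))


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.lists(st.integers(0, 5), min_size=64, max_size=64),
       st.lists(st.integers(0, 5), min_size=64, max_size=64),
       st.lists(st.integers(0, 5), min_size=64, max_size=64))
def test_cub_distance_is_a_metric(a, b, c):
    from acrkit.codon_stats import CodonFrequencyVector

    va, vb, vc = (CodonFrequencyVector(np.array(x)) for x in (a, b, c))
    if va.n_codons == 0 or vb.n_codons == 0 or vc.n_codons == 0:
        return
    dab, dba = cub_distance(va, vb), cub_distance(vb, va)
    assert dab == dba
    assert 0.0 <= dab <= math.sqrt(2) + 1e-12
    assert dab <= cub_distance(va, vc) + cub_distance(vc, vb) + 1e-12


def test_distance_invariant_under_sequence_duplication():
    seqs = ["ATGAAACCCTAA", "ATGGGGTTTTAG", "ATGCACCACTGA"]
    genome = _genome(seqs)
    pool = pooled_vector(genome.genes)
    g = genome.genes[0]
    assert cub_distance(count_codons(g.nt_seq * 2), pool) == pytest.approx(
        cub_distance(count_codons(g.nt_seq), pool)
    )


def test_cubrank_orders_by_descending_distance():
    # three genes engineered so their CUB distances are distinct
    seqs = ["GGGGGGGGGGGG", "ATGAAACCCTAA", "ATGAAAGGGTAA"]
    genome = _genome(seqs)
    results = cubrank(genome)
    dists = [r.distance for r in results]
    order = sorted(range(3), key=lambda i: -dists[i])
    for pos, i in enumerate(order, start=1):
        assert results[i].rank == pos
    assert sorted(r.rank for r in results) == [1, 2, 3]
    assert all(r.percentile == pytest.approx(r.rank / 3) for r in results)


def test_cubrank_single_gene_genome():
    genome = _genome(["ATGAAATAA"])
    (res,) = cubrank(genome)
    assert res.distance == 0.0 and res.rank == 1 and res.percentile == 1.0


def test_cubrank_ranks_are_permutation_even_with_ties():
    genome = _genome(["ATGAAATAA", "ATGAAATAA", "ATGCCCTAA", "ATGAAATAA"])
    results = cubrank(genome)
    assert sorted(r.rank for r in results) == [1, 2, 3, 4]
    tied = [r for r, s in zip(results, genome.genes) if s.nt_seq == "ATGAAATAA"]
    # stable sort: tied genes keep input order
    assert [t.rank for t in tied] == sorted(t.rank for t in tied)


def test_fully_shifted_gene_attains_rank_one():
    genome, labels = synthetic_data.make_host_genome(50, 1, 1.0, seed=3)
    results = cubrank(genome)
    (shifted,) = [r for r, l in zip(results, labels) if l]
    others = [r.distance for r, l in zip(results, labels) if not l]
    assert shifted.rank == 1
    assert shifted.distance > max(others)  # exhaustive comparison


def test_shifted_gene_percentile_decreases_with_separation():
    """Stronger codon-bias separation pushes shifted genes toward rank 1."""
    means = []
    for sep in (0.05, 0.15, 0.3):
        vals = []
        for seed in range(10):
            genome, labels = synthetic_data.make_host_genome(50, 5, sep, seed=seed)
            results = cubrank(genome)
            vals += [r.percentile for r, l in zip(results, labels) if l]
        means.append(float(np.mean(vals)))
    assert all(m < 0.5 for m in means)
    assert means[0] > means[1] > means[2]
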