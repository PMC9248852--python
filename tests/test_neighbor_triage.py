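import numpy as np
import pytest

from acrkit.genome_io import GeneRecord, GenomeRecord, HitRecord
from acrkit.neighbor_triage import (
    PREDICTORS,
    NeighborRecord,
    calls_from_region_counts,
    extract_neighbors,
    map_pdb,
    match_catalog,
    screen_candidates,
    venn_consensus,
)


def _genome(n_genes: int, strands: list[str] | None = None) -> GenomeRecord:
    genes, pos = [], 0
    strands = strands or ["+"] * n_genes
    for i in range(n_genes):
        genes.append(
            GeneRecord(
                gene_id=f"g{i}", contig="c", start=pos, end=pos + 300, strand=strands[i],
                nt_seq="ATG" + "AAA" * 98 + "TAA", protein_id=f"P{i}", product="hypothetical protein",
            )
        )
        pos += 400
    return GenomeRecord(genome_id="t", contigs={"c": "A" * pos}, genes=genes)


def _record(aa_length: int = 100, annotation: str = "hypothetical protein") -> NeighborRecord:
    return NeighborRecord(
        protein_id="P", seed_acr_id="s", offset=1, same_strand=True, aa_length=aa_length, annotation=annotation
    )


def _hit(query: str, evalue: float, identity: float, mismatches: int = 0, coverage: float | None = None) -> HitRecord:
    return HitRecord(
        query_id=query, subject_id="subj", pct_identity=identity, align_len=100,
        mismatches=mismatches, evalue=evalue, coverage=coverage,
    )


def test_extract_six_neighbors_mid_contig():
    genome = _genome(9)
    records = extract_neighbors(genome, {"g4"})
    assert len(records) == 6
    assert sorted(r.offset for r in records) == [-3, -2, -1, 1, 2, 3]
    assert {r.protein_id for r in records} == {"P1", "P2", "P3", "P5", "P6", "P7"}


def test_extraction_truncates_at_contig_edge():
    genome = _genome(9)
    records = extract_neighbors(genome, {"g1"})  # 2 genes from the start (1 upstream)
    assert sorted(r.offset for r in records) == [-1, 1, 2, 3]


def test_circular_extraction_wraps_around():
    genome = _genome(9)
    records = extract_neighbors(genome, {"g0"}, circular=True)
    assert len(records) == 6
    assert {r.protein_id for r in records} == {"P6", "P7", "P8", "P1", "P2", "P3"}


def test_same_strand_flag_and_unknown_seed():
    genome = _genome(3, strands=["+", "+", "-"])
    records = extract_neighbors(genome, {"g1"})
    by_offset = {r.offset: r for r in records}
    assert by_offset[-1].same_strand is True and by_offset[1].same_strand is False
    with pytest.raises(ValueError, match="nope"):
        extract_neighbors(genome, {"nope"})


def test_neighbor_adjacent_to_two_seeds_yields_two_records():
    genome = _genome(5)
    records = extract_neighbors(genome, {"g1", "g3"})
    assert sum(1 for r in records if r.protein_id == "P2") == 2


@pytest.mark.parametrize(
    "aa,annotation,expected",
    [
        (59, "hypothetical protein", False),
        (60, "hypothetical protein", True),
        (200, "hypothetical protein", True),
        (201, "hypothetical protein", False),
        (120, "DNA polymerase", False),
        (120, "Uncharacterized protein YabC", True),
        (120, "", True),
        (120, "protein of unknown function", True),
    ],
)
def test_screen_candidates_rules(aa, annotation, expected):
    (rec,) = screen_candidates([_record(aa, annotation)])
    assert rec.passed_screen is expected


def test_screen_is_idempotent():
    recs = [_record(59), _record(100), _record(100, "DNA gyrase")]
    once = [r.passed_screen for r in screen_candidates(recs)]
    twice = [r.passed_screen for r in screen_candidates(recs)]
    assert once == twice


@pytest.mark.parametrize(
    "evalue,identity,expected",
    [(0.01, 35.0, True), (0.02, 90.0, False), (1e-5, 34.9, False), (1e-5, 35.0, True)],
)
def test_catalog_match_inclusive_thresholds(evalue, identity, expected):
    (rec,) = match_catalog([_record()], [_hit("P", evalue, identity)])
    assert rec.catalog_match is expected


@pytest.mark.parametrize(
    "evalue,mismatches,coverage,kept",
    [
        (1e-11, 0, 0.96, True),
        (1e-10, 1, 0.95, True),  # all at the boundary, inclusive
        (1e-11, 2, 0.99, False),
        (1e-9, 0, 1.0, False),
        (1e-11, 0, 0.94, False),
    ],
)
def test_pdb_mapping_thresholds(evalue, mismatches, coverage, kept):
    mapped = map_pdb([_hit("q", evalue, 99.0, mismatches, coverage)])
    assert ("q" in mapped) is kept


def test_pdb_mapping_skips_hits_without_coverage():
    assert map_pdb([_hit("q", 1e-20, 99.0, 0, None)]) == {}


# region sizes of the published three-predictor Venn diagram; the only-counts
# derive from the printed set totals (3918, 6923, 901)
PUBLISHED_REGIONS = {
    ("pacrispr",): 3918 - 1679 - 313 - 361,
    ("acrcatalog",): 6923 - 1679 - 313 - 105,
    ("acranker",): 901 - 361 - 313 - 105,
    ("pacrispr", "acrcatalog"): 1679,
    ("pacrispr", "acranker"): 361,
    ("acranker", "acrcatalog"): 105,
    ("pacrispr", "acranker", "acrcatalog"): 313,
}


def test_venn_consensus_reproduces_published_arithmetic():
    calls = calls_from_region_counts(PUBLISHED_REGIONS)
    counts, stats = venn_consensus(calls)
    assert counts.totals == {"pacrispr": 3918, "acrcatalog": 6923, "acranker": 901}
    assert stats["n_at_least_two"] == 2458
    assert stats["n_all_three"] == 313
    share = stats["overlap_share_pct"]
    assert share[("pacrispr", "acrcatalog")] == 28.77
    assert share[("acranker", "acrcatalog")] == 6.04
    assert share[("pacrispr", "acranker")] == 74.81
    assert share[("acrcatalog", "acranker")] == 46.39


def test_venn_regions_partition_union_and_match_brute_force():
    rng = np.random.default_rng(71)
    calls = {
        f"p{i}": {p for p in PREDICTORS if rng.random() < 0.4}
        for i in range(300)
    }
    counts, stats = venn_consensus(calls)
    union = {pid for pid, preds in calls.items() if preds}
    assert sum(counts.regions.values()) == len(union)
    sets = {p: {pid for pid, preds in calls.items() if p in preds} for p in PREDICTORS}
    for (a, b), pct in stats["overlap_share_pct"].items():
        assert pct == pytest.approx(100 * len(sets[a] & sets[b]) / len(sets[b]), abs=0.005)


def test_venn_empty_middle_and_unknown_predictor():
    _, stats = venn_consensus({"p1": {"pacrispr"}, "p2": {"acranker", "pacrispr"}})
    assert stats["n_all_three"] == 0
    with pytest.raises(ValueError, match="badpred"):
        venn_consensus({"p1": {"badpred"}})
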