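"""Gene-neighborhood triage of anti-CRISPR candidates.

Known Acrs cluster with other anti-defense genes in mobile elements, so
the genes flanking a validated acr form a natural candidate pool. This
module extracts up to three genes on each side of every seed acr, applies
the rule-based screens used to keep plausible unknown-function small
proteins (60–200 aa, no validated functional annotation), marks catalog
and structure matches from precomputed similarity hits, and aggregates
the calls of three external predictors (PaCRISPR, AcRanker, AcrCatalog)
into Venn-region consensus statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping

from .genome_io import GeneRecord, GenomeRecord, HitRecord
from .orf_discovery import STOP_CODONS

PREDICTORS = ("pacrispr", "acranker", "acrcatalog")

#: annotation substrings treated as "unknown function" (case-insensitive)
UNKNOWN_FUNCTION_PATTERNS = ("hypothetical protein", "uncharacterized protein", "unknown")

__all__ = [
    "PREDICTORS",
    "NeighborRecord",
    "VennCounts",
    "extract_neighbors",
    "screen_candidates",
    "match_catalog",
    "map_pdb",
    "venn_consensus",
    "calls_from_region_counts",
]


@dataclass
class NeighborRecord:
    """A gene within +-k positions of a seed acr, with screening state."""

    protein_id: str
    seed_acr_id: str
    offset: int
    same_strand: bool
    aa_length: int
    annotation: str
    passed_screen: bool | None = None
    predictor_calls: set[str] = field(default_factory=set)
    catalog_match: bool | None = None


def _aa_length(gene: GeneRecord) -> int:
    n = len(gene.nt_seq) // 3
    if n and gene.nt_seq[-3:].upper() in STOP_CODONS:
        n -= 1
    return n


def extract_neighbors(
    genome: GenomeRecord, seed_ids: set[str], k: int = 3, circular: bool = False
) -> list[NeighborRecord]:
    """Collect up to ``k`` genes on each side of every seed acr.

    Neighbors are taken in positional order per contig; at contig ends
    the window is truncated silently unless ``circular`` wraps it
    around. A gene adjacent to two seeds yields one record per seed.
    """
    by_contig: dict[str, list[GeneRecord]] = {}
    for g in sorted(genome.genes, key=lambda g: (g.contig, g.start)):
        by_contig.setdefault(g.contig, []).append(g)
    index = {g.gene_id: (g.contig, i) for contig, gs in by_contig.items() for i, g in enumerate(gs)}
    missing = seed_ids - index.keys()
    if missing:
        raise ValueError(f"unknown seed gene ids: {sorted(missing)}")
    records: list[NeighborRecord] = []
    for seed_id in sorted(seed_ids):
        contig, i = index[seed_id]
        genes = by_contig[contig]
        seed = genes[i]
        n = len(genes)
        for offset in [o for o in range(-k, k + 1) if o != 0]:
            j = i + offset
            if circular:
                if n <= 1:
                    continue
                j %= n
                if j == i:
                    continue
            elif not 0 <= j < n:
                continue
            nb = genes[j]
            records.append(
                NeighborRecord(
                    protein_id=nb.protein_id or nb.gene_id,
                    seed_acr_id=seed_id,
                    offset=offset,
                    same_strand=nb.strand == seed.strand,
                    aa_length=_aa_length(nb),
                    annotation=nb.product,
                )
            )
    return records


def screen_candidates(
    records: list[NeighborRecord],
    min_aa: int = 60,
    max_aa: int = 200,
    unknown_patterns: tuple[str, ...] = UNKNOWN_FUNCTION_PATTERNS,
) -> list[NeighborRecord]:
    """Set ``passed_screen`` on each record (idempotent).

    A candidate passes iff its length is within [min_aa, max_aa]
    inclusive and its annotation carries no evidence of validated
    function — i.e. it is empty or matches one of the unknown-function
    patterns (case-insensitive substring).
    """
    pats = tuple(p.lower() for p in unknown_patterns)
    for r in records:
        ann = r.annotation.strip().lower()
        unknown = ann == "" or any(p in ann for p in pats)
        r.passed_screen = (min_aa <= r.aa_length <= max_aa) and unknown
    return records


def match_catalog(
    records: list[NeighborRecord],
    hits: list[HitRecord],
    evalue_max: float = 0.01,
    identity_min: float = 35.0,
) -> list[NeighborRecord]:
    """Set ``catalog_match``: does any hit pass the catalog thresholds?

    Both thresholds are inclusive (e-value <= ``evalue_max`` and percent
    identity >= ``identity_min``); hits are keyed by the record's
    protein id.
    """
    by_query: dict[str, list[HitRecord]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    for r in records:
        r.catalog_match = any(
            h.evalue <= evalue_max and h.pct_identity >= identity_min
            for h in by_query.get(r.protein_id, [])
        )
    return records


def map_pdb(
    hits: list[HitRecord],
    evalue_max: float = 1e-10,
    mismatch_max: int = 1,
    coverage_min: float = 0.95,
) -> dict[str, set[str]]:
    """Map each query to the PDB chains it matches at high similarity.

    A subject chain is retained iff e-value <= 1e-10, mismatches <= 1
    and query coverage >= 95% (all inclusive). Hits lacking coverage are
    skipped with a warning.
    """
    import logging

    out: dict[str, set[str]] = {}
    for h in hits:
        if h.coverage is None:
            logging.getLogger(__name__).warning(
                "hit %s -> %s lacks coverage; skipped", h.query_id, h.subject_id
            )
            continue
        if h.evalue <= evalue_max and h.mismatches <= mismatch_max and h.coverage >= coverage_min:
            out.setdefault(h.query_id, set()).add(h.subject_id)
    return out


@dataclass
class VennCounts:
    """Exact region counts of a three-predictor Venn diagram.

    ``regions`` maps each non-empty predictor subset (frozenset) to the
    number of proteins called by exactly that subset; ``totals`` maps
    each predictor to its full set size.
    """

    regions: dict[frozenset, int]
    totals: dict[str, int]

    def region(self, *predictors: str) -> int:
        return self.regions.get(frozenset(predictors), 0)


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def venn_consensus(calls: Mapping[str, Iterable[str]]) -> tuple[VennCounts, dict]:
    """Aggregate per-protein predictor calls into Venn-region statistics.

    ``calls`` maps protein id to the subset of {pacrispr, acranker,
    acrcatalog} that called it. Returns the exact region counts plus
    derived statistics: the number of proteins called by at least two
    and by all three predictors, and for every ordered predictor pair
    (A, B) the share |A∩B| / |B| as a percentage rounded half-up to two
    decimals.
    """
    if not calls:
        raise ValueError("empty call map")
    regions: dict[frozenset, int] = {}
    sets: dict[str, set[str]] = {p: set() for p in PREDICTORS}
    for pid, preds in calls.items():
        pset = frozenset(preds)
        bad = pset - set(PREDICTORS)
        if bad:
            raise ValueError(f"unknown predictor name(s) {sorted(bad)} for protein {pid}")
        if not pset:
            continue
        regions[pset] = regions.get(pset, 0) + 1
        for p in pset:
            sets[p].add(pid)
    counts = VennCounts(regions=regions, totals={p: len(sets[p]) for p in PREDICTORS})
    n_at_least_two = sum(n for s, n in regions.items() if len(s) >= 2)
    n_all_three = regions.get(frozenset(PREDICTORS), 0)
    shares = {}
    for a in PREDICTORS:
        for b in PREDICTORS:
            if a == b or not sets[b]:
                continue
            shares[(a, b)] = _round2(100.0 * len(sets[a] & sets[b]) / len(sets[b]))
    stats = {
        "n_at_least_two": n_at_least_two,
        "n_all_three": n_all_three,
        "overlap_share_pct": shares,
    }
    return counts, stats


def calls_from_region_counts(region_counts: Mapping[tuple[str, ...], int]) -> dict[str, set[str]]:
    """Expand Venn-region sizes into a synthetic per-protein call map.

    Useful for reproducing published Venn arithmetic from printed region
    sizes alone: each region of size n contributes n distinct protein
    ids carrying exactly that predictor subset.
    """
    calls: dict[str, set[str]] = {}
    for preds, n in region_counts.items():
        pset = set(preds)
        bad = pset - set(PREDICTORS)
        if bad:
            raise ValueError(f"unknown predictor name(s): {sorted(bad)}")
        tag = "+".join(sorted(pset))
        for i in range(n):
            calls[f"{tag}:{i}"] = set(pset)
    return calls
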