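"""The per-gene synteny search: seed, score, filter, classify, recover.

For each query gene, the genes half a window up- and downstream form its
neighborhood. Every tandem-collapsed homolog of a neighborhood gene marks a
candidate location in a target genome; candidate locations on one target
chromosome are grouped by single-linkage clustering into candidate regions.
A region's synteny score is either its *density* (number of distinct
neighborhood genes with a match into it — any arrangement tolerated) or its
*colinearity* (longest strictly monotone chain of matches, so wholly
inverted blocks score fully). Regions at or above the minimum score are
reported, optionally truncated to a maximum syntenic depth.

Each surviving region is classified: **S** (syntelog) when the query gene
itself has a raw match inside the region — tandem matches removed before
seeding are recovered here from the raw pair set; otherwise the nearest
matching neighbors (flankers) stand proxy for the missing gene: **F** with
flankers on both sides, **G** with a flanker on one side only (typical near
rearrangement breakpoints and scaffold ends).
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Optional

from .genome_model import GeneModel, GenomeAnnotation, neighborhood
from .homology_io import HomologPair, HomologTable, PairSet

log = logging.getLogger(__name__)


@dataclass
class SynFindParams:
    """Tunable run parameters.

    window_size
        Neighborhood breadth in genes; ``window_size + 1`` genes are checked
        (the query plus half a window on each side). Default 40.
    min_score
        Minimum synteny score to call a region syntenic. Default 4, i.e. 4
        of the 41 checked genes must match — sensitive enough for heavily
        fractionated regions.
    scoring_mode
        ``density`` (any arrangement) or ``colinear`` (longest monotone
        chain).
    max_depth
        Report at most this many regions per query gene per target genome;
        ``None`` reports all regions found (the default). Depth 1 restricts
        the search to the single best (usually orthologous) region.
    tandem_gap
        Maximum rank distance linking tandem-array members. Default 10.
    cluster_gap
        Maximum target-rank gap within one candidate region (single
        linkage); defaults to half the window size, mirroring the query-side
        half-window.
    """

    window_size: int = 40
    min_score: int = 4
    scoring_mode: str = "density"
    max_depth: Optional[int] = None
    tandem_gap: int = 10
    cluster_gap: Optional[int] = None

    def __post_init__(self) -> None:
        if self.window_size < 2 or self.window_size % 2:
            raise ValueError(f"window_size must be an even integer >= 2, got {self.window_size}")
        if self.min_score < 1:
            raise ValueError(f"min_score must be positive, got {self.min_score}")
        if self.min_score > self.window_size + 1:
            raise ValueError(
                f"min_score ({self.min_score}) cannot exceed window_size+1 "
                f"({self.window_size + 1}): no region could ever qualify"
            )
        if self.scoring_mode not in ("density", "colinear"):
            raise ValueError(f"scoring_mode must be 'density' or 'colinear', got {self.scoring_mode!r}")
        if self.max_depth is not None and self.max_depth < 1:
            raise ValueError("max_depth must be positive or None (unlimited)")
        if self.tandem_gap < 1:
            raise ValueError("tandem_gap must be positive")
        if self.cluster_gap is None:
            self.cluster_gap = self.window_size // 2
        elif self.cluster_gap < 1:
            raise ValueError("cluster_gap must be positive")
        if self.min_score / self.window_size < 0.10:
            log.warning(
                "min_score %d is below 10%% of window_size %d; "
                "expect false positives from repeats and transposed genes",
                self.min_score,
                self.window_size,
            )


@dataclass
class CandidateRegion:
    """A single-linkage cluster of matches on one target chromosome."""

    target_genome: str
    target_chrom: str
    member_pairs: list[tuple[str, str]]  # (window gene, target gene)
    min_rank: int
    max_rank: int
    density_score: int = 0
    colinear_score: int = 0

    def score(self, scoring_mode: str) -> int:
        return self.density_score if scoring_mode == "density" else self.colinear_score


@dataclass
class SyntenyHit:
    """One reported (query gene -> target region) result."""

    query_gene: str
    region: CandidateRegion
    synteny_score: int
    syntelog_class: str  # S, F or G
    anchor_gene: str
    flanker_up: Optional[str] = None
    flanker_down: Optional[str] = None


def longest_monotone_run(seq: list[int]) -> int:
    """max(strict LIS, strict LDS) of *seq* via patience sorting."""
    return max(_strict_lis(seq), _strict_lis([-x for x in seq]))


def density_score(region: CandidateRegion) -> int:
    """Number of distinct window genes with at least one pair in the region."""
    return len({q for q, _ in region.member_pairs})


def _strict_lis(seq: list[int]) -> int:
    tails: list[int] = []
    for x in seq:
        i = bisect_left(tails, x)
        if i == len(tails):
            tails.append(x)
        else:
            tails[i] = x
    return len(tails)


def colinear_score(
    region: CandidateRegion,
    query_annotation: GenomeAnnotation,
    target_annotation: GenomeAnnotation,
) -> int:
    """Longest strictly monotone chain of member pairs.

    A chain uses each query gene at most once (query ranks strictly
    increase) while target ranks strictly increase or strictly decrease;
    the longer direction is returned, so a wholly inverted block is not
    penalized. Sorting target ranks descending within one query rank before
    the increasing-subsequence pass (and ascending for the decreasing pass)
    enforces the one-pair-per-query-gene rule; this also keeps the colinear
    score bounded by the density score.
    """
    ranked = [
        (query_annotation.gene(q).rank, target_annotation.gene(t).rank)
        for q, t in region.member_pairs
    ]
    inc = _strict_lis([t for _, t in sorted(ranked, key=lambda p: (p[0], -p[1]))])
    dec = _strict_lis([-t for _, t in sorted(ranked)])
    return max(inc, dec)


def _pairs_by_query(pairs: PairSet) -> dict[str, list[HomologPair]]:
    idx: dict[str, list[HomologPair]] = {}
    for p in pairs.values():
        idx.setdefault(p.query_gene, []).append(p)
    return idx


def seed_regions(
    query_gene: str,
    query_annotation: GenomeAnnotation,
    target_annotation: GenomeAnnotation,
    collapsed_pairs: PairSet,
    params: SynFindParams,
    _pair_index: Optional[dict[str, list[HomologPair]]] = None,
) -> list[CandidateRegion]:
    """Candidate regions for one query gene, both scores computed.

    Collects the collapsed pairs of every neighborhood gene, partitions the
    matched target genes by chromosome, and single-linkage clusters each
    chromosome's matches with rank gap <= ``cluster_gap``.
    """
    idx = _pair_index if _pair_index is not None else _pairs_by_query(collapsed_pairs)
    window = neighborhood(query_annotation, query_gene, params.window_size)
    # (target chrom, target rank, window gene, target gene) tuples
    hits: dict[str, list[tuple[int, str, str]]] = {}
    for wg in window:
        for p in idx.get(wg.gene_id, ()):
            tg = target_annotation.by_id.get(p.target_gene)
            if tg is None:
                continue
            hits.setdefault(tg.chrom, []).append((tg.rank, wg.gene_id, p.target_gene))
    regions: list[CandidateRegion] = []
    assert params.cluster_gap is not None
    for chrom in sorted(hits):
        chrom_hits = sorted(hits[chrom])
        cluster: list[tuple[int, str, str]] = []
        prev_rank: Optional[int] = None
        for h in chrom_hits + [(-1, "", "")]:  # sentinel flushes the last cluster
            if prev_rank is not None and (h[1] == "" or h[0] - prev_rank > params.cluster_gap):
                regions.append(
                    _make_region(
                        cluster, chrom, target_annotation.genome_id,
                        query_annotation, target_annotation,
                    )
                )
                cluster = []
            if h[1] != "":
                cluster.append(h)
                prev_rank = h[0]
    return regions


def _make_region(
    cluster: list[tuple[int, str, str]],
    chrom: str,
    target_genome: str,
    query_annotation: GenomeAnnotation,
    target_annotation: GenomeAnnotation,
) -> CandidateRegion:
    members = sorted({(q, t) for _, q, t in cluster})
    region = CandidateRegion(
        target_genome=target_genome,
        target_chrom=chrom,
        member_pairs=members,
        min_rank=min(r for r, _, _ in cluster),
        max_rank=max(r for r, _, _ in cluster),
    )
    region.density_score = density_score(region)
    region.colinear_score = colinear_score(region, query_annotation, target_annotation)
    return region


def filter_and_rank(
    regions: list[CandidateRegion],
    params: SynFindParams,
    query_gene: str,
) -> list[CandidateRegion]:
    """Drop sub-threshold regions, rank the rest, truncate to max_depth."""
    kept = [r for r in regions if r.score(params.scoring_mode) >= params.min_score]
    kept.sort(key=lambda r: (-r.score(params.scoring_mode), r.target_chrom, r.min_rank))
    if params.max_depth is not None:
        kept = kept[: params.max_depth]
    return kept


def recover_tandem_best(
    query_gene: str,
    region: CandidateRegion,
    raw_pairs: PairSet,
    query_tandems,
    target_annotation: GenomeAnnotation,
    _raw_index: Optional[dict[str, list[HomologPair]]] = None,
) -> Optional[str]:
    """Best raw match of the query gene (or its tandem array) inside the region.

    Tandem matches were reduced to a single copy before seeding; this checks
    the original pair set so genes inside arrays recover their own syntelog.
    Returns the target gene with the maximum raw score (tie: lowest target
    rank), or None when no raw pair falls inside the region.
    """
    raw_idx = _raw_index if _raw_index is not None else _pairs_by_query(raw_pairs)
    sources = [query_gene]
    for arr in query_tandems:
        if arr.representative == query_gene:
            sources = sorted(arr.members)
            break
    best: Optional[tuple[float, int, str]] = None
    for src in sources:
        for p in raw_idx.get(src, ()):
            tg = target_annotation.by_id.get(p.target_gene)
            if tg is None or tg.chrom != region.target_chrom:
                continue
            if not (region.min_rank <= tg.rank <= region.max_rank):
                continue
            cand = (-p.score, tg.rank, p.target_gene)
            if best is None or cand < best:
                best = cand
    return best[2] if best else None


def classify_hit(
    query_gene: str,
    region: CandidateRegion,
    table: HomologTable,
    query_annotation: GenomeAnnotation,
    target_annotation: GenomeAnnotation,
    params: SynFindParams,
    _raw_index: Optional[dict[str, list[HomologPair]]] = None,
) -> SyntenyHit:
    """Assign the syntelog class and anchor gene to a surviving region.

    S: the query gene has a raw match inside the region (the match is the
    anchor, recovered across its tandem array). F/G: the nearest matched
    window genes up- and downstream act as flankers; the nearer flanker's
    best match is the proxy anchor. Distance ties prefer the upstream
    flanker; score ties the lowest target rank.
    """
    if not region.member_pairs:
        raise RuntimeError("internal consistency error: region with zero member pairs")
    raw_idx = _raw_index if _raw_index is not None else _pairs_by_query(table.raw_pairs)
    score = region.score(params.scoring_mode)

    def own_raw_anchor() -> Optional[str]:
        best: Optional[tuple[float, int, str]] = None
        for p in raw_idx.get(query_gene, ()):
            tg = target_annotation.by_id.get(p.target_gene)
            if tg is None or tg.chrom != region.target_chrom:
                continue
            if region.min_rank <= tg.rank <= region.max_rank:
                cand = (-p.score, tg.rank, p.target_gene)
                if best is None or cand < best:
                    best = cand
        return best[2] if best else None

    if own_raw_anchor() is not None:
        anchor = recover_tandem_best(
            query_gene, region, table.raw_pairs, table.query_tandems,
            target_annotation, _raw_index=raw_idx,
        )
        assert anchor is not None
        return SyntenyHit(query_gene, region, score, "S", anchor)

    # flanker search, confined to the window
    qg = query_annotation.gene(query_gene)
    matched: dict[str, list[str]] = {}
    for wq, wt in region.member_pairs:
        matched.setdefault(wq, []).append(wt)
    up: Optional[GeneModel] = None
    down: Optional[GeneModel] = None
    for gid in matched:
        g = query_annotation.gene(gid)
        if g.rank < qg.rank and (up is None or g.rank > up.rank):
            up = g
        elif g.rank > qg.rank and (down is None or g.rank < down.rank):
            down = g

    if up is None and down is None:
        # Only the query gene itself matched, via a collapsed pair it
        # represents: recover the array's best raw match (class S).
        anchor = recover_tandem_best(
            query_gene, region, table.raw_pairs, table.query_tandems,
            target_annotation, _raw_index=raw_idx,
        )
        if anchor is not None:
            return SyntenyHit(query_gene, region, score, "S", anchor)
        raise RuntimeError(
            f"internal consistency error: region for {query_gene} has member "
            "pairs but neither a syntelog nor a flanker"
        )

    if up is not None and down is not None:
        cls = "F"
        flanker = up if (qg.rank - up.rank) <= (down.rank - qg.rank) else down
    else:
        cls = "G"
        flanker = up if up is not None else down
    assert flanker is not None

    def collapsed_score(q: str, t: str) -> float:
        p = table.collapsed_pairs.get((q, t))
        return p.score if p else 0.0

    anchor = min(
        matched[flanker.gene_id],
        key=lambda t: (-collapsed_score(flanker.gene_id, t), target_annotation.gene(t).rank),
    )
    return SyntenyHit(
        query_gene, region, score, cls, anchor,
        flanker_up=up.gene_id if up else None,
        flanker_down=down.gene_id if down else None,
    )


RunResults = dict[str, dict[str, list[SyntenyHit]]]


def run_synfind(
    query_annotation: GenomeAnnotation,
    target_annotations: list[GenomeAnnotation],
    pair_tables: list[HomologTable],
    params: SynFindParams,
) -> RunResults:
    """Search every target genome for syntenic regions of every query gene.

    Returns ``{query_gene: {target_genome: [SyntenyHit, ...]}}`` with query
    genes in (chromosome, rank) order and hits in score order; the output is
    deterministic given identical inputs.
    """
    tables = {t.target_genome: t for t in pair_tables}
    for ta in target_annotations:
        if ta.genome_id not in tables:
            raise ValueError(f"no pair table supplied for target genome {ta.genome_id!r}")

    per_target = []
    for ta in target_annotations:
        table = tables[ta.genome_id]
        per_target.append(
            (
                ta,
                table,
                _pairs_by_query(table.collapsed_pairs),
                _pairs_by_query(table.raw_pairs),
            )
        )

    ordered = sorted(query_annotation.genes, key=lambda g: (g.chrom, g.rank))
    results: RunResults = {}
    for qg in ordered:
        per_gene: dict[str, list[SyntenyHit]] = {}
        for ta, table, coll_idx, raw_idx in per_target:
            regions = seed_regions(
                qg.gene_id, query_annotation, ta, table.collapsed_pairs,
                params, _pair_index=coll_idx,
            )
            surviving = filter_and_rank(regions, params, qg.gene_id)
            per_gene[ta.genome_id] = [
                classify_hit(
                    qg.gene_id, r, table, query_annotation, ta, params,
                    _raw_index=raw_idx,
                )
                for r in surviving
            ]
        results[qg.gene_id] = per_gene
    return results
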