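"""Homologous gene-pair input, HSP deduplication and tandem-array collapse.

Putative homologs come from a similarity search (BLAST/LAST/LASTZ) run
outside this package, either as 12-column tabular output (outfmt 6) or as a
minimal 3-column (query, target, score) file. Tandem arrays — clusters of
homologous genes adjacent in one genome — are collapsed to a single
representative before seeding, because matches among array members would
otherwise seed a spurious synteny block inside the array. The raw pair set
is retained: the classifier later recovers each array member's own best
match from it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

from .genome_model import GenomeAnnotation

log = logging.getLogger(__name__)


class HomologPair(NamedTuple):
    query_gene: str
    target_gene: str
    score: float
    evalue: Optional[float] = None


# Pair sets are keyed by (query_gene, target_gene) so deduplication and
# membership tests are O(1).
PairSet = dict[tuple[str, str], HomologPair]


@dataclass(frozen=True)
class TandemArray:
    """A single-linkage chain of same-chromosome homologs within tandem_gap ranks."""

    genome_id: str
    chrom: str
    members: frozenset[str]
    representative: str


@dataclass
class HomologTable:
    """All pair data for one query-target genome comparison."""

    query_genome: str
    target_genome: str
    raw_pairs: PairSet
    collapsed_pairs: PairSet
    query_tandems: list[TandemArray] = field(default_factory=list)
    target_tandems: list[TandemArray] = field(default_factory=list)


def load_pairs(
    path: str,
    format: str,
    query_annotation: GenomeAnnotation,
    target_annotation: GenomeAnnotation,
    evalue_cutoff: Optional[float] = None,
) -> PairSet:
    """Parse a pairs file into a deduplicated :data:`PairSet`.

    Keeps the maximum score across multiple HSPs of the same gene pair.
    Self-pairs are removed when query and target are the same genome. Pairs
    naming genes absent from either annotation are dropped with a logged
    count; more than 50% unresolvable ids raises, since that indicates the
    pairs file does not belong to these annotations.
    """
    if format not in ("blast6", "pairs3"):
        raise ValueError(f"unknown pairs format {format!r} (expected 'blast6' or 'pairs3')")
    same_genome = query_annotation.genome_id == target_annotation.genome_id
    pairs: PairSet = {}
    total = 0
    unresolved = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            try:
                if format == "blast6":
                    if len(cols) < 12:
                        raise ValueError("expected 12 columns")
                    q, t = cols[0], cols[1]
                    evalue: Optional[float] = float(cols[10])
                    score = float(cols[11])
                else:
                    if len(cols) < 3:
                        raise ValueError("expected 3 columns")
                    q, t = cols[0], cols[1]
                    score = float(cols[2])
                    evalue = None
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed {format} line: {exc}") from None
            total += 1
            if q not in query_annotation.by_id or t not in target_annotation.by_id:
                unresolved += 1
                continue
            if same_genome and q == t:
                continue
            if evalue_cutoff is not None and evalue is not None and evalue > evalue_cutoff:
                continue
            key = (q, t)
            prev = pairs.get(key)
            if prev is None or score > prev.score:
                pairs[key] = HomologPair(q, t, score, evalue)
    if unresolved:
        log.warning("%s: dropped %d/%d pair(s) with unresolvable gene ids", path, unresolved, total)
    if total and unresolved > total / 2:
        raise ValueError(
            f"annotation/pairs mismatch: {unresolved}/{total} gene ids in {path} "
            "do not resolve in the supplied annotations"
        )
    return pairs


def detect_tandems(
    pairs: PairSet,
    annotation: GenomeAnnotation,
    side: str,
    tandem_gap: int = 10,
) -> list[TandemArray]:
    """Find tandem arrays on one side of the comparison.

    Two same-genome genes are linked when they sit on one chromosome within
    ``tandem_gap`` ranks of each other and either share a homolog on the
    other side or are paired to each other directly (self-comparison).
    Arrays are connected components of this relation; the representative is
    the member with the greatest summed pair score (tie: lowest rank).
    """
    if side not in ("query", "target"):
        raise ValueError(f"side must be 'query' or 'target', got {side!r}")
    if tandem_gap < 1:
        raise ValueError("tandem_gap must be positive")
    qi, ti = (0, 1) if side == "query" else (1, 0)

    homologs: dict[str, set[str]] = {}
    summed: dict[str, float] = {}
    for key, p in pairs.items():
        g, other = key[qi], key[ti]
        homologs.setdefault(g, set()).add(other)
        summed[g] = summed.get(g, 0.0) + p.score

    # union-find over genes that carry at least one pair
    parent: dict[str, str] = {g: g for g in homologs}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: str, b: str) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[rb] = ra

    by_chrom: dict[str, list] = {}
    for g in homologs:
        gm = annotation.by_id.get(g)
        if gm is None:
            continue
        by_chrom.setdefault(gm.chrom, []).append(gm)
    for chrom, genes in by_chrom.items():
        genes.sort(key=lambda g: g.rank)
        for i, a in enumerate(genes):
            for b in genes[i + 1 :]:
                if b.rank - a.rank > tandem_gap:
                    break
                linked = bool(homologs[a.gene_id] & homologs[b.gene_id])
                if not linked:
                    # direct pairing between the two genes (self-comparison)
                    linked = (a.gene_id, b.gene_id) in pairs or (b.gene_id, a.gene_id) in pairs
                if linked:
                    union(a.gene_id, b.gene_id)

    components: dict[str, set[str]] = {}
    for g in parent:
        components.setdefault(find(g), set()).add(g)
    arrays = []
    for members in components.values():
        if len(members) < 2:
            continue
        chrom = annotation.gene(next(iter(members))).chrom
        rep = min(members, key=lambda g: (-summed[g], annotation.gene(g).rank))
        arrays.append(
            TandemArray(annotation.genome_id, chrom, frozenset(members), rep)
        )
    arrays.sort(key=lambda a: (a.chrom, annotation.gene(a.representative).rank))
    return arrays


def collapse_tandems(
    pairs: PairSet,
    query_tandems: list[TandemArray],
    target_tandems: list[TandemArray],
) -> PairSet:
    """Rewrite array-member endpoints to their representatives, merging by max score."""
    q_rep = {m: a.representative for a in query_tandems for m in a.members}
    t_rep = {m: a.representative for a in target_tandems for m in a.members}
    out: PairSet = {}
    for p in pairs.values():
        q = q_rep.get(p.query_gene, p.query_gene)
        t = t_rep.get(p.target_gene, p.target_gene)
        key = (q, t)
        prev = out.get(key)
        if prev is None or p.score > prev.score:
            out[key] = HomologPair(q, t, p.score, p.evalue)
    return out


def build_homolog_table(
    path: str,
    format: str,
    query_annotation: GenomeAnnotation,
    target_annotation: GenomeAnnotation,
    tandem_gap: int = 10,
    evalue_cutoff: Optional[float] = None,
) -> HomologTable:
    """Load, deduplicate, detect tandems on both sides and collapse — one call."""
    raw = load_pairs(path, format, query_annotation, target_annotation, evalue_cutoff)
    q_arrays = detect_tandems(raw, query_annotation, "query", tandem_gap)
    t_arrays = detect_tandems(raw, target_annotation, "target", tandem_gap)
    collapsed = collapse_tandems(raw, q_arrays, t_arrays)
    return HomologTable(
        query_genome=query_annotation.genome_id,
        target_genome=target_annotation.genome_id,
        raw_pairs=raw,
        collapsed_pairs=collapsed,
        query_tandems=q_arrays,
        target_tandems=t_arrays,
    )
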