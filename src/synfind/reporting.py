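"""Genome-wide outputs: master table, depth histograms, presence-absence, unique genes.

The master syntenic-pairs table holds one row per query gene with the
syntenic gene sets found in every target genome; the per-target syntenic
depth histogram summarises how many query genes are covered 0-, 1-, 2- ..
x-fold (modal depth > 1 signals paleopolyploidy; the fraction at depth >= 1
tracks assembly completeness); the presence-absence matrix and the
genome-unique gene list support pan-genome style contrasts such as strain-
specific insertions.
"""

from __future__ import annotations

from dataclasses import dataclass

from .core import RunResults, SyntenyHit
from .genome_model import GenomeAnnotation

CLASS_ORDER = {"S": 0, "F": 1, "G": 2}
EMPTY = "."


@dataclass
class DepthHistogram:
    target_genome: str
    counts: dict[int, int]
    total_query_genes: int


def depth_histogram(results: RunResults, target_genome: str) -> DepthHistogram:
    """Tally query genes by number of surviving regions in one target genome."""
    counts: dict[int, int] = {}
    total = 0
    for per_gene in results.values():
        if target_genome not in per_gene:
            raise KeyError(f"no results for target genome {target_genome!r}")
        d = len(per_gene[target_genome])
        counts[d] = counts.get(d, 0) + 1
        total += 1
    return DepthHistogram(target_genome, dict(sorted(counts.items())), total)


def _cell(hits: list[SyntenyHit]) -> str:
    if not hits:
        return EMPTY
    return "|".join(f"{h.anchor_gene}({h.syntelog_class},{h.synteny_score})" for h in hits)


def write_master_table(
    results: RunResults,
    query_annotation: GenomeAnnotation,
    target_order: list[str],
    out_path: str,
) -> None:
    """Write the tab-delimited master table, one row per query gene.

    Cells read ``anchor(class,score)``, multiple regions joined by ``|``,
    empty cells ``.``; rows follow query (chromosome, rank) order so repeat
    runs are byte-identical.
    """
    with open(out_path, "w", newline="\n") as fh:
        fh.write("\t".join(["query_gene", "chrom", "rank"] + list(target_order)) + "\n")
        for gid in _ordered_gene_ids(results, query_annotation):
            g = query_annotation.gene(gid)
            cells = [_cell(results[gid].get(t, [])) for t in target_order]
            fh.write("\t".join([gid, g.chrom, str(g.rank)] + cells) + "\n")


def _ordered_gene_ids(results: RunResults, annotation: GenomeAnnotation) -> list[str]:
    return sorted(results, key=lambda gid: (annotation.gene(gid).chrom, annotation.gene(gid).rank))


def presence_absence(
    results: RunResults,
    query_annotation: GenomeAnnotation,
    targets: list[str],
) -> dict[str, dict[str, str]]:
    """Best syntelog class per (query gene, target genome): S > F > G > absent.

    "Best" is the class of the top-ranked hit — a found syntelog dominates a
    proxy only through the score ranking that put it first.
    """
    matrix: dict[str, dict[str, str]] = {}
    for gid in _ordered_gene_ids(results, query_annotation):
        row = {}
        for t in targets:
            hits = results[gid].get(t, [])
            row[t] = hits[0].syntelog_class if hits else EMPTY
        matrix[gid] = row
    return matrix


def unique_genes(results: RunResults, query_annotation: GenomeAnnotation) -> list[str]:
    """Query genes with zero surviving regions in every target genome.

    Candidate lineage-specific genes or insertions; a G-class proxy region
    still counts as a matching region, so only genes for which not even an
    expected location exists are listed.
    """
    out = []
    for gid in _ordered_gene_ids(results, query_annotation):
        if all(len(hits) == 0 for hits in results[gid].values()):
            out.append(gid)
    return out


def write_depth_histogram(hist: DepthHistogram, out_path: str) -> None:
    with open(out_path, "w", newline="\n") as fh:
        fh.write("depth\tgene_count\n")
        for depth, n in sorted(hist.counts.items()):
            fh.write(f"{depth}\t{n}\n")


def write_presence_absence(
    matrix: dict[str, dict[str, str]], targets: list[str], out_path: str
) -> None:
    with open(out_path, "w", newline="\n") as fh:
        fh.write("\t".join(["query_gene"] + list(targets)) + "\n")
        for gid, row in matrix.items():
            fh.write("\t".join([gid] + [row[t] for t in targets]) + "\n")


def write_unique_genes(genes: list[str], out_path: str) -> None:
    with open(out_path, "w", newline="\n") as fh:
        for gid in genes:
            fh.write(gid + "\n")


def evaluate_against_truth(
    predicted: set[tuple[str, str]], truth: set[tuple[str, str]]
) -> tuple[float, float]:
    """Sensitivity and purity of a predicted syntenic pair set.

    Sn = |common| / |truth|; Pu = |common| / |predicted|. An empty truth set
    leaves sensitivity undefined and raises.
    """
    if not truth:
        raise ValueError("empty truth set: sensitivity is undefined")
    common = len(predicted & truth)
    sn = common / len(truth)
    pu = common / len(predicted) if predicted else 0.0
    return sn, pu
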