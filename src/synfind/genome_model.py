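"""Gene annotation loading and the per-chromosome gene rank index.

Synteny search operates on gene *order*, not base-pair coordinates: every
gene gets a dense 0-based rank within its chromosome, and all windowing,
clustering and flanker logic downstream runs on those ranks. Coordinates are
normalised to 0-based half-open on load (BED is native; GFF3 is converted
from 1-based closed) so a single convention holds everywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

log = logging.getLogger(__name__)

VALID_STRANDS = {"+", "-", "."}


@dataclass
class GeneModel:
    """One gene: location plus its ordinal position on the chromosome.

    ``rank`` is assigned by :func:`assign_ranks` and is dense within each
    (genome, chromosome): 0 .. n_genes_on_chrom - 1.
    """

    gene_id: str
    chrom: str
    start: int  # 0-based, half-open
    end: int
    strand: str = "."
    rank: int = -1

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"gene {self.gene_id}: invalid strand {self.strand!r}")


@dataclass
class GenomeAnnotation:
    """Ordered gene models of one genome, indexed by id and by (chrom, rank)."""

    genome_id: str
    genes: list[GeneModel] = field(default_factory=list)
    by_id: dict[str, GeneModel] = field(default_factory=dict)
    by_chrom_rank: dict[tuple[str, int], GeneModel] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def chrom_size(self, chrom: str) -> int:
        """Number of genes on *chrom*."""
        return sum(1 for g in self.genes if g.chrom == chrom)

    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for g in self.genes:
            seen.setdefault(g.chrom, None)
        return list(seen)

    def gene(self, gene_id: str) -> GeneModel:
        try:
            return self.by_id[gene_id]
        except KeyError:
            raise KeyError(
                f"gene {gene_id!r} not found in genome {self.genome_id!r}"
            ) from None


def assign_ranks(annotation: GenomeAnnotation) -> GenomeAnnotation:
    """Assign dense per-chromosome ranks ordered by (start, end, gene_id).

    Idempotent: the ordering key does not depend on any existing rank. The
    tie-break on (end, gene_id) makes the ordering of overlapping or nested
    gene models deterministic across platforms. Rebuilds the lookup tables
    in place and returns the annotation.
    """
    per_chrom: dict[str, list[GeneModel]] = {}
    for g in annotation.genes:
        per_chrom.setdefault(g.chrom, []).append(g)
    annotation.by_chrom_rank.clear()
    annotation.by_id.clear()
    for chrom, genes in per_chrom.items():
        genes.sort(key=lambda g: (g.start, g.end, g.gene_id))
        for rank, g in enumerate(genes):
            g.rank = rank
            annotation.by_chrom_rank[(chrom, rank)] = g
    for g in annotation.genes:
        annotation.by_id[g.gene_id] = g
    return annotation


def neighborhood(
    annotation: GenomeAnnotation, gene_id: str, window_size: int
) -> list[GeneModel]:
    """Genes within half a window up- and downstream of *gene_id*, inclusive.

    With ``window_size=40`` an interior gene yields 41 genes: itself plus 20
    on each side. The window is truncated at chromosome ends (no wrap, no
    extension onto other scaffolds) and genes are returned in rank order.
    """
    if window_size < 0 or window_size % 2:
        raise ValueError(f"window_size must be an even non-negative integer, got {window_size}")
    g = annotation.gene(gene_id)
    half = window_size // 2
    out = []
    for r in range(g.rank - half, g.rank + half + 1):
        hit = annotation.by_chrom_rank.get((g.chrom, r))
        if hit is not None:
            out.append(hit)
    return out


def _parse_bed(path: str) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            cols = line.split("\t")
            if len(cols) < 3:
                raise ValueError(f"{path}:{lineno}: BED line has fewer than 3 columns")
            chrom, start, end = cols[0], int(cols[1]), int(cols[2])
            name = cols[3] if len(cols) > 3 and cols[3] not in ("", ".") else f"{chrom}:{start}-{end}"
            strand = cols[5] if len(cols) > 5 and cols[5] in VALID_STRANDS else "."
            genes.append(GeneModel(name, chrom, start, end, strand))
    return genes


def _parse_gff3(path: str) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        path,
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
    )
    feature_type = "gene"
    if not any(True for _ in db.features_of_type("gene")):
        feature_type = "mRNA"
    genes = []
    for feat in db.features_of_type(feature_type):
        gene_id = feat.attributes.get("ID", [feat.id])[0]
        strand = feat.strand if feat.strand in VALID_STRANDS else "."
        # GFF3 is 1-based closed; convert to 0-based half-open.
        genes.append(GeneModel(gene_id, feat.seqid, feat.start - 1, feat.end, strand))
    return genes


def load_annotation(path: str, format: str, genome_id: str) -> GenomeAnnotation:
    """Load gene models from a GFF3 or BED file and build the rank index.

    For GFF3, features of type ``gene`` are used, falling back to ``mRNA``
    when the file has none. Duplicate gene ids collapse to the record with
    the widest span. Raises ``ValueError`` on an empty annotation and
    propagates I/O errors for unreadable files.
    """
    if format == "bed":
        genes = _parse_bed(path)
    elif format == "gff3":
        genes = _parse_gff3(path)
    else:
        raise ValueError(f"unknown annotation format {format!r} (expected 'gff3' or 'bed')")
    if not genes:
        raise ValueError(f"empty annotation: no gene features found in {path}")
    # collapse duplicate ids to the widest span
    widest: dict[str, GeneModel] = {}
    dropped = 0
    for g in genes:
        prev = widest.get(g.gene_id)
        if prev is None or (g.end - g.start) > (prev.end - prev.start):
            if prev is not None:
                dropped += 1
            widest[g.gene_id] = g
        else:
            dropped += 1
    if dropped:
        log.warning("%s: collapsed %d duplicate gene id record(s)", path, dropped)
    ann = GenomeAnnotation(genome_id=genome_id, genes=list(widest.values()))
    return assign_ranks(ann)
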