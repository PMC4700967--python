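"""Simulated genome pairs with known synteny ground truth.

The generator emulates the evolutionary scenarios the synteny search is
built to resolve: whole-genome duplication (the target carries ``wgd_copies``
copies of the ancestral gene order), fractionation (post-WGD gene loss from
the duplicated copies), segmental inversions, single-gene transpositions and
tandem duplications. The query genome is the unchanged ancestor, so the
expected syntelog class of every (query gene, copy) combination is
computable in closed form and emitted as a truth table.

Truth semantics mirror the S/F/G classifier: a gene whose copy-c ortholog
survived in place is S; a deleted (or transposed) gene is F when surviving
in-place neighbors exist on both sides within half a window, G with one side
only, absent otherwise. Under inversions or transpositions the neighbor rule
is evaluated on the ancestral order, so truth is exact only for
rearrangement-free configurations and approximate near breakpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .genome_model import GeneModel, GenomeAnnotation, assign_ranks
from .homology_io import HomologPair, PairSet

GENE_SPACING = 1000  # bp between simulated gene starts
GENE_LENGTH = 600


@dataclass
class SimConfig:
    """Scenario parameters; defaults describe a fractionating paleotetraploid.

    The target holds ``wgd_copies`` copies of the ancestor; copy 0 keeps
    every gene while copies 1.. lose each gene independently with
    probability ``fractionation_p``. Rearrangements and tandem duplications
    are off by default so the truth table is exact.
    """

    n_genes: int = 1000
    n_chroms: int = 2
    wgd_copies: int = 2
    fractionation_p: float = 0.3
    n_inversions: int = 0
    inversion_span: tuple[int, int] = (3, 10)
    n_transpositions: int = 0
    tandem_p: float = 0.0
    score_noise: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("fractionation_p", "tandem_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.n_chroms < 1 or self.n_genes < self.n_chroms:
            raise ValueError("need n_genes >= n_chroms >= 1")
        if self.wgd_copies < 1:
            raise ValueError("wgd_copies must be >= 1")
        if self.score_noise < 0:
            raise ValueError("score_noise must be non-negative")
        if self.n_inversions > 0:
            lo, hi = self.inversion_span
            min_chrom = self.n_genes // self.n_chroms
            if not (2 <= lo <= hi):
                raise ValueError(f"invalid inversion_span {self.inversion_span}")
            if hi > min_chrom:
                raise ValueError(
                    f"inversion_span upper bound {hi} exceeds the smallest "
                    f"chromosome ({min_chrom} genes)"
                )


@dataclass
class TruthRecord:
    query_gene: str
    copy: int
    expected_class: str  # S, F, G or absent
    expected_anchor: Optional[str]


@dataclass
class SimResult:
    query: GenomeAnnotation
    target: GenomeAnnotation
    pairs: PairSet
    truth: list[TruthRecord]
    surviving_per_copy: list[int] = field(default_factory=list)
    n_tandem_dups: int = 0


def _ancestral_chroms(cfg: SimConfig) -> list[list[str]]:
    per = [cfg.n_genes // cfg.n_chroms] * cfg.n_chroms
    for i in range(cfg.n_genes % cfg.n_chroms):
        per[i] += 1
    chroms, gi = [], 0
    for n in per:
        chroms.append([f"g{gi + j:05d}" for j in range(n)])
        gi += n
    return chroms


def simulate(cfg: SimConfig, window_size: int = 40) -> SimResult:
    """Run one simulation; fully reproducible from ``cfg.seed``.

    ``window_size`` enters only the truth table (the half-window used by the
    F/G neighbor rule) and matches the search default.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestry = _ancestral_chroms(cfg)

    query_genes = []
    for ci, chrom_genes in enumerate(ancestry):
        for j, gid in enumerate(chrom_genes):
            query_genes.append(
                GeneModel(gid, f"qchr{ci + 1}", j * GENE_SPACING, j * GENE_SPACING + GENE_LENGTH, "+")
            )
    query = assign_ranks(GenomeAnnotation("query", query_genes))

    # evolve each WGD copy
    target_layout: dict[str, list[tuple[str, str, str]]] = {}  # chrom -> [(tid, qid, strand)]
    surviving: list[set[str]] = []
    moved: list[set[str]] = [set() for _ in range(cfg.wgd_copies)]
    for c in range(cfg.wgd_copies):
        kept: set[str] = set()
        for ci, chrom_genes in enumerate(ancestry):
            order = []
            for gid in chrom_genes:
                if c > 0 and rng.random() < cfg.fractionation_p:
                    continue
                kept.add(gid)
                order.append((f"{gid}_c{c}", gid, "+"))
            target_layout[f"tchr{ci + 1}_{c}"] = order
        surviving.append(kept)

    def copy_chroms(c: int) -> list[str]:
        return [f"tchr{ci + 1}_{c}" for ci in range(cfg.n_chroms)]

    for _ in range(cfg.n_inversions):
        c = int(rng.integers(cfg.wgd_copies))
        chrom = copy_chroms(c)[int(rng.integers(cfg.n_chroms))]
        order = target_layout[chrom]
        span = int(rng.integers(cfg.inversion_span[0], cfg.inversion_span[1] + 1))
        if len(order) <= span:
            continue
        start = int(rng.integers(0, len(order) - span + 1))
        seg = [(tid, qid, "-" if s == "+" else "+") for tid, qid, s in order[start : start + span]]
        target_layout[chrom] = order[:start] + seg[::-1] + order[start + span :]

    for _ in range(cfg.n_transpositions):
        c = int(rng.integers(cfg.wgd_copies))
        chroms = copy_chroms(c)
        src = target_layout[chroms[int(rng.integers(cfg.n_chroms))]]
        if not src:
            continue
        i = int(rng.integers(len(src)))
        gene = src.pop(i)
        dst = target_layout[chroms[int(rng.integers(cfg.n_chroms))]]
        dst.insert(int(rng.integers(len(dst) + 1)), gene)
        moved[c].add(gene[1])

    n_dups = 0
    if cfg.tandem_p > 0:
        for chrom, order in target_layout.items():
            out = []
            for tid, qid, s in order:
                out.append((tid, qid, s))
                if rng.random() < cfg.tandem_p:
                    out.append((f"{tid}.t1", qid, s))
                    n_dups += 1
            target_layout[chrom] = out

    target_genes = []
    pairs: PairSet = {}
    for chrom in sorted(target_layout):
        for j, (tid, qid, strand) in enumerate(target_layout[chrom]):
            target_genes.append(
                GeneModel(tid, chrom, j * GENE_SPACING, j * GENE_SPACING + GENE_LENGTH, strand)
            )
            score = max(1.0, 100.0 * (1.0 + rng.normal(0.0, cfg.score_noise)))
            pairs[(qid, tid)] = HomologPair(qid, tid, round(score, 4))
    target = assign_ranks(GenomeAnnotation("target", target_genes))

    truth = _truth_table(cfg, query, surviving, moved, window_size)
    return SimResult(
        query, target, pairs, truth,
        surviving_per_copy=[len(s) for s in surviving],
        n_tandem_dups=n_dups,
    )


def _truth_table(
    cfg: SimConfig,
    query: GenomeAnnotation,
    surviving: list[set[str]],
    moved: list[set[str]],
    window_size: int,
) -> list[TruthRecord]:
    half = window_size // 2
    records = []
    for g in sorted(query.genes, key=lambda g: (g.chrom, g.rank)):
        for c in range(cfg.wgd_copies):
            in_place = surviving[c] - moved[c]
            if g.gene_id in in_place:
                records.append(TruthRecord(g.gene_id, c, "S", f"{g.gene_id}_c{c}"))
                continue
            up = down = None
            for d in range(1, half + 1):
                if up is None:
                    n = query.by_chrom_rank.get((g.chrom, g.rank - d))
                    if n is not None and n.gene_id in in_place:
                        up = (d, n.gene_id)
                if down is None:
                    n = query.by_chrom_rank.get((g.chrom, g.rank + d))
                    if n is not None and n.gene_id in in_place:
                        down = (d, n.gene_id)
            if up and down:
                cls = "F"
                flank = up[1] if up[0] <= down[0] else down[1]
            elif up or down:
                cls = "G"
                flank = (up or down)[1]  # type: ignore[index]
            else:
                records.append(TruthRecord(g.gene_id, c, "absent", None))
                continue
            records.append(TruthRecord(g.gene_id, c, cls, f"{flank}_c{c}"))
    return records


def write_fixture(cfg: SimConfig, outdir: str, window_size: int = 40) -> SimResult:
    """Simulate and write query.bed, target.bed, pairs.tsv and truth.tsv.

    Output is byte-identical for identical configurations.
    """
    res = simulate(cfg, window_size=window_size)
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _write_bed(res.query, out / "query.bed")
    _write_bed(res.target, out / "target.bed")
    with open(out / "pairs.tsv", "w", newline="\n") as fh:
        for key in sorted(res.pairs):
            p = res.pairs[key]
            fh.write(f"{p.query_gene}\t{p.target_gene}\t{p.score:.4f}\n")
    with open(out / "truth.tsv", "w", newline="\n") as fh:
        fh.write("query_gene\tcopy\texpected_class\texpected_anchor\n")
        for r in res.truth:
            fh.write(f"{r.query_gene}\t{r.copy}\t{r.expected_class}\t{r.expected_anchor or '.'}\n")
    return res


def _write_bed(ann: GenomeAnnotation, path: Path) -> None:
    genes = sorted(ann.genes, key=lambda g: (g.chrom, g.rank))
    with open(path, "w", newline="\n") as fh:
        for g in genes:
            fh.write(f"{g.chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t{g.strand}\n")
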