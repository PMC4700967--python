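# synfind

Per-gene synteny search across multiple target genomes.

Given structural gene annotations (GFF3/BED) and precomputed homologous
gene pairs (BLAST tabular or a minimal 3-column file), `synfind` identifies,
for **every gene in a query genome**, all syntenic regions in any set of
target genomes. When the gene itself has a homolog inside a region it is
reported as a *syntelog* (class **S**); when it is missing — fractionated
after a polyploidy event, or moved — the nearest matching neighbors stand
proxy for the expected location (class **F** with flankers on both sides,
**G** with one, the latter typical near rearrangement breakpoints and
scaffold ends). The per-gene results roll up into genome-wide readouts: a
master syntenic-pairs table, syntenic-depth histograms (the
paleopolyploidy / assembly-completeness signal), a presence–absence matrix
and genome-unique gene lists — useful for anything from tracing homeologs
after whole-genome duplication to finding strain-specific phage insertions
in bacteria.

It is aimed at comparative genomicists who already have annotations and an
all-vs-all homology search and want gene-level synteny calls without running
a full chaining/visualization pipeline.

## The algorithm

All positions are **gene ranks**: the ordinal of a gene on its chromosome,
which makes the search robust to gene-density and intergenic-length
variation between species.

1. **Tandem collapse.** Homologous genes clustered within `tandem_gap`
   (default 10) ranks form tandem arrays; each array is reduced to one
   representative before seeding, so a block is never seeded inside an
   array. The raw pair set is kept.
2. **Seeding.** For query gene *q* with window size *w* (default 40), the
   *w*+1 genes at ranks *r(q)* ± *w*/2 are collected. Every collapsed pair
   from a window gene marks a candidate position in the target; positions on
   one target chromosome are grouped by single-linkage clustering with rank
   gap ≤ `cluster_gap` (default *w*/2) into candidate regions.
3. **Scoring.** The synteny score of a region is either its **density** —
   the number of distinct window genes with a match into it, any arrangement
   tolerated — or its **colinearity** — the longest chain of pairs with
   strictly increasing query ranks and strictly monotone target ranks
   (longest-increasing-subsequence chaining; a wholly inverted block scores
   fully). Regions scoring below `min_score` (default 4, i.e. 4 of the 41
   genes checked) are dropped; `max_depth` optionally keeps only the top *N*
   regions (depth 1 ≈ orthologous region only).
4. **Classification and recovery.** A surviving region is class S when *q*
   has a raw pair into it — checked against the *raw* pairs, so genes whose
   matches were collapsed with their tandem array recover their own best
   syntelog. Otherwise the nearest matched window genes up- and downstream
   become flankers (F/G) and the nearer flanker's best match anchors the
   proxy location.

The number of regions a gene receives is its **syntenic depth**; the modal
depth against a related genome counts retained whole-genome-duplication
copies, and the fraction of genes at depth ≥ 1 tracks assembly completeness.

## Worked example

The package ships a genome-evolution simulator, so a complete run needs no
downloads. Simulate a 400-gene ancestor (the query) and a tetraploid target
— two whole-genome copies, one of which then lost ~30% of its genes:

```sh
synfind simulate --seed 11 --n-genes 400 --n-chroms 1 -o demo/
synfind run --query demo/query.bed --target demo/target.bed:demo/pairs.tsv -o out/
```

`out/` now holds `master_table.tsv`, `depth_hist.target.tsv`,
`presence_absence.tsv`, `unique_genes.txt` and a `manifest.json` recording
parameters and input checksums (re-running from the same inputs reproduces
every file byte for byte). The depth histogram reads

```
depth	gene_count
2	400
```

— every query gene is covered by exactly two regions, the expected depth for
one round of whole-genome duplication. The master table reports what each
region contains, e.g.

```
query_gene	chrom	rank	target
g00000	qchr1	0	g00000_c0(S,21)|g00001_c1(G,14)
g00001	qchr1	1	g00001_c0(S,22)|g00001_c1(S,14)
```

`g00001` kept both copies (two S cells, anchored on its copy-0 and copy-1
homologs, with synteny scores 22 and 14), while `g00000` lost its copy-1
gene: the second cell is a G-class proxy anchored on its neighbor's
surviving copy. A single gene can be inspected directly:

```sh
synfind report-gene --query demo/query.bed --target demo/target.bed:demo/pairs.tsv g00120
```

```
target	tchr1_0	100-140	41	S	g00120_c0	syntelog
target	tchr1_1	62-86	25	F	g00118_c1	proxy for region
```

(columns: target genome, chromosome, target rank span, synteny score, class,
anchor gene). `g00120` sits at full window occupancy (score 41) in the
intact copy and is fractionated from the second copy, where both flankers
are present, hence the F-class proxy. Predicted pairs can be scored against
the simulator's truth table with `synfind evaluate --master-table
out/master_table.tsv --truth demo/truth.tsv`, which prints sensitivity (Sn)
and purity (Pu).

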