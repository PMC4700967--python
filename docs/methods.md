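# Methods

## Model and assumptions

The search treats a genome as ordered lists of gene models. Every gene gets
a dense 0-based rank within its chromosome, ordered by (start, end,
gene_id); overlapping or nested models receive distinct ranks, with the
(end, gene_id) tie-break making the order deterministic across platforms.
Working in rank space assumes that gene *order*, not physical spacing,
carries the synteny signal — the standard assumption for annotation-based
microsynteny, and the reason the method transfers between genomes with very
different intergenic lengths. Coordinates are normalised to 0-based
half-open on load (BED is native, GFF3 is converted from 1-based closed);
strand is stored and reported but never enters scoring, since match counts
are orientation-free.

Homology is taken as given: the caller supplies gene pairs from any
similarity search. Multiple HSPs of one pair are reduced to the best score;
self-pairs are removed in self-comparisons. No e-value or score prefilter is
applied by default (`--evalue-cutoff` exists but is off), because the
synteny window itself is the specificity filter.

## Tandem arrays

Two same-genome genes are linked when they lie on one chromosome within
`tandem_gap` ranks of each other and either share a homolog on the other
side of the comparison or are directly paired with each other (the latter
only arises in self-comparisons). Arrays are the connected components of
this relation — single linkage, so an array can span more than `tandem_gap`
ranks end to end. The representative is the member with the largest summed
pair score (ties: lowest rank), biasing toward the best-supported copy.
Collapse rewrites array members to representatives and merges duplicates by
maximum score; it is idempotent. `tandem_gap` defaults to 10 ranks, the
conventional neighborhood used by this family of synteny tools.

Classification later consults the *raw* pair set, so collapsing costs no
sensitivity for genes inside arrays: each query gene recovers its own best
raw match within a region, and a representative inherits its array's best
match (ties: lowest target rank).

## Windowing, clustering, scoring

`window_size` w (even, default 40) defines a neighborhood of w+1 genes —
the query plus w/2 on each side, truncated at chromosome ends with no
wrap-around. Candidate regions are single-linkage clusters (rank gap ≤
`cluster_gap`, default w/2 — the target-side mirror of the query half-window)
of the target positions matched by neighborhood genes, computed per target
chromosome by a sorted sweep.

Density score = number of *distinct* window genes with ≥ 1 pair into the
region. Counting distinct genes rather than pairs keeps the score robust to
residual many-to-one matches.

Colinear score = longest chain of member pairs whose query ranks strictly
increase while target ranks strictly increase **or** strictly decrease
(computed by patience sorting after ordering pairs by (query rank, −target
rank) for the increasing pass and (query rank, target rank) for the
decreasing pass). Taking the better direction means a wholly inverted block
is not penalized — inversions are routine at these scales. Using each query
gene at most once keeps colinear ≤ density, so switching scoring modes can
only tighten, never loosen, the filter. Ties between equal ranks cannot
arise (chains are strict in both coordinates).

Regions scoring below `min_score` (default 4) are discarded; survivors are
ordered by (score desc, target chromosome asc, minimum rank asc) — the
trailing keys exist purely for determinism — and truncated to `max_depth`
when set (default: report everything). A configured `min_score` below 10% of
the window size logs a warning: thresholds that low admit false positives
from repeats and transposed genes. The default 4-of-41 sits exactly at that
boundary and does not warn.

## Classification

Class S requires a raw pair from the query gene itself to a target gene
within the region's rank bounds. Failing that, flankers are sought among the
window genes with member pairs in the region: nearest matched gene upstream
and downstream of the query. Both present → F; one → G; the nearer flanker
(distance ties: upstream) contributes the proxy anchor — its best-scoring
match in the region (score ties: lowest target rank). One degenerate case is
handled explicitly: a region whose only member pairs come from the query
gene acting as a tandem representative for another member's match has no
flankers and no own raw pair; it is classed S via the array's best raw
match, which is precisely the tandem-recovery semantics.

## Synthetic data

`synfind.synthetic.simulate` builds a query genome (the unchanged ancestor)
and a target genome carrying `wgd_copies` copies of it, then emits the pair
set and a closed-form truth table. Defaults describe a fractionating
tetraploid: 1000 genes on 2 chromosomes, 2 copies, per-gene loss probability
0.3 applied to the duplicated copies (copy 0 is kept intact so every gene
retains one in-place ortholog), no rearrangements, no tandem duplications,
score noise 0.1 (pair scores are 100·(1+N(0, σ)) truncated at 1 — enough
spread to exercise score-based tie-breaks without reordering biology).
Inversions (segment reversals with strand flips), single-gene transpositions
and tandem duplications are available per scenario.

Truth classes mirror the classifier: a gene whose copy-c ortholog survived
in place is S; a deleted or transposed gene is F when surviving in-place
query-side neighbors exist within half a window on both sides, G with one
side, absent with none. Because the rule is evaluated on the ancestral gene
order, the table is exact for rearrangement-free configurations and only
approximate within half a window of an inversion or transposition
breakpoint — which is why the rearrangement rates default to zero and the
classification-recovery checks run on rearrangement-free scenarios. What
the simulator does **not** emulate: paralogy noise from unrelated gene
families, annotation errors (missing/merged/split models), assembly gaps,
and realistic score distributions; passing recovery tests therefore
demonstrates correctness of the algorithmic machinery under the stated
evolutionary model, not expected accuracy on real annotations.

## Verification

Unit and property tests (seeded Hypothesis) cover each stage; the
region/score pipeline is additionally checked for exact agreement against
an independent brute-force oracle — pairwise-gap graph clustering via
networkx plus an O(n²) pair-chain DP, with full 2ⁿ subsequence enumeration
at tiny n — on random genomes of ≤ 50 genes. Problem sizes in the test and
acceptance runs (hundreds of instances of ≤ 50 genes; simulations of
300–1000 genes) were chosen as the smallest scales at which every behavior
of interest — WGD depth, fractionation classes, window truncation, tandem
recovery — is exercised with comfortable margins; runtimes are seconds.

`scripts/acceptance.py --seed N --out f.json` recomputes from scratch:
window occupancy (41 genes at window 40), the smallest shared-pair count
that yields a reported region (the default minimum score, 4), oracle
agreement, self-synteny identity (every gene S on itself at its window
occupancy), tetraploid depth recovery with and without `max_depth=1`, F/G
precision and recall against the simulator truth table, depth-histogram
conservation, and byte-identical reruns.

## Known limitations

- Synteny is annotation-based only: unannotated conserved sequence is
  invisible, and annotation quality bounds attainable accuracy.
- Regions are seeded per query gene and never merged into genome-wide
  chains; block boundaries are window-local.
- The depth cap is a simple top-N truncation, not a quota assignment across
  overlapping regions.
- Truth-table semantics near simulated rearrangement breakpoints are
  approximate (see above).
- `pairs3` input carries no e-value, so `--evalue-cutoff` only affects
  BLAST tabular input.
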