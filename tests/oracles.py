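"""Independent brute-force reference implementations used only by tests.

These deliberately share no code with the package: clustering goes through a
pairwise networkx graph instead of a sorted sweep, and the monotone-chain
length is computed by quadratic dynamic programming or, at tiny n, by full
subsequence enumeration.
"""

from itertools import combinations

import networkx as nx

from synfind.genome_model import neighborhood


def monotone_dp(seq):
    """max(strict LIS, strict LDS) by O(n^2) DP."""
    if not seq:
        return 0

    def lis(s):
        best = [1] * len(s)
        for i in range(len(s)):
            for j in range(i):
                if s[j] < s[i]:
                    best[i] = max(best[i], best[j] + 1)
        return max(best)

    return max(lis(seq), lis([-x for x in seq]))


def monotone_exhaustive(seq):
    """max strictly monotone subsequence by enumerating all 2^n subsequences (n <= 15)."""
    assert len(seq) <= 15
    best = 0
    for k in range(1, len(seq) + 1):
        for idx in combinations(range(len(seq)), k):
            sub = [seq[i] for i in idx]
            inc = all(a < b for a, b in zip(sub, sub[1:]))
            dec = all(a > b for a, b in zip(sub, sub[1:]))
            if inc or dec:
                best = max(best, k)
    return best


def pair_chain_dp(ranked_pairs):
    """Longest pair chain with strictly increasing query ranks and strictly
    monotone target ranks, by O(n^2) DP over the pairs themselves."""
    pts = sorted(set(ranked_pairs))
    best = 0
    for sign in (1, -1):
        dp = [1] * len(pts)
        for i, (qi, ti) in enumerate(pts):
            for j, (qj, tj) in enumerate(pts[:i]):
                if qj < qi and sign * tj < sign * ti:
                    dp[i] = max(dp[i], dp[j] + 1)
        best = max(best, max(dp, default=0))
    return best


def brute_force_regions(query_gene, query_ann, target_ann, pairs, params):
    """Enumerate window x target-chromosome clusters independently.

    Returns {(chrom, min_rank, max_rank): (density, colinear)} where clusters
    are connected components of the pairwise rank-gap graph.
    """
    window = {g.gene_id for g in neighborhood(query_ann, query_gene, params.window_size)}
    hits = []  # (chrom, target rank, window gene, target gene)
    for p in pairs.values():
        if p.query_gene in window and p.target_gene in target_ann.by_id:
            tg = target_ann.gene(p.target_gene)
            hits.append((tg.chrom, tg.rank, p.query_gene, p.target_gene))
    out = {}
    for chrom in {h[0] for h in hits}:
        ch = [h for h in hits if h[0] == chrom]
        g = nx.Graph()
        g.add_nodes_from(range(len(ch)))
        for i, j in combinations(range(len(ch)), 2):
            if abs(ch[i][1] - ch[j][1]) <= params.cluster_gap:
                g.add_edge(i, j)
        for comp in nx.connected_components(g):
            members = [ch[i] for i in comp]
            ranks = [m[1] for m in members]
            density = len({m[2] for m in members})
            colinear = pair_chain_dp([(query_ann.gene(m[2]).rank, m[1]) for m in members])
            out[(chrom, min(ranks), max(ranks))] = (density, colinear)
    return out
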