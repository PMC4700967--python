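import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synfind.core import (
    CandidateRegion,
    SynFindParams,
    classify_hit,
    colinear_score,
    density_score,
    filter_and_rank,
    longest_monotone_run,
    recover_tandem_best,
    run_synfind,
    seed_regions,
)
from synfind.homology_io import HomologTable, TandemArray

from conftest import linear_annotation, make_annotation, make_pairs
from oracles import brute_force_regions, monotone_dp, monotone_exhaustive


def make_table(q_ann, t_ann, raw, collapsed=None, q_tandems=(), t_tandems=()):
    return HomologTable(
        q_ann.genome_id,
        t_ann.genome_id,
        raw,
        collapsed if collapsed is not None else dict(raw),
        list(q_tandems),
        list(t_tandems),
    )


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"window_size": 0},
            {"window_size": 7},
            {"window_size": 2, "min_score": 4},
            {"min_score": 0},
            {"scoring_mode": "fast"},
            {"max_depth": 0},
            {"tandem_gap": 0},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SynFindParams(**kwargs)

    def test_cluster_gap_defaults_to_half_window(self):
        assert SynFindParams(window_size=40).cluster_gap == 20
        assert SynFindParams(window_size=10, min_score=2).cluster_gap == 5


class TestSeedRegions:
    def test_single_linkage_splits_distant_clusters(self):
        q = linear_annotation("q", 50, prefix="q")
        t = linear_annotation("t", 250, chrom="chrT", prefix="t")
        pairs = make_pairs(
            [
                ("q10", "t10", 100),
                ("q11", "t12", 100),
                ("q12", "t15", 100),
                ("q13", "t200", 100),
                ("q14", "t203", 100),
            ]
        )
        params = SynFindParams(window_size=40, cluster_gap=20)
        regions = seed_regions("q12", q, t, pairs, params)
        assert sorted(r.density_score for r in regions) == [2, 3]
        spans = {(r.min_rank, r.max_rank) for r in regions}
        assert spans == {(10, 15), (200, 203)}

    def test_no_pairs_yields_empty_list(self):
        q = linear_annotation("q", 10, prefix="q")
        t = linear_annotation("t", 10, prefix="t")
        assert seed_regions("q5", q, t, {}, SynFindParams(window_size=4, min_score=1)) == []

    def test_chromosome_partition_precedes_clustering(self):
        q = linear_annotation("q", 10, prefix="q")
        t = make_annotation(
            "t", [("ta", "chrA", 0, 10), ("tb", "chrB", 0, 10)]
        )
        pairs = make_pairs([("q4", "ta", 10), ("q5", "tb", 10)])
        regions = seed_regions("q5", q, t, pairs, SynFindParams(window_size=4, min_score=1))
        assert len(regions) == 2
        assert {r.target_chrom for r in regions} == {"chrA", "chrB"}


class TestScores:
    def test_density_counts_distinct_window_genes(self):
        r = CandidateRegion("t", "c", [("q1", "t1"), ("q2", "t2"), ("q3", "t3"), ("q4", "t4")], 1, 4)
        assert density_score(r) == 4
        r2 = CandidateRegion("t", "c", [("q1", "t1"), ("q1", "t2")], 1, 2)
        assert density_score(r2) == 1
        assert density_score(CandidateRegion("t", "c", [], 0, 0)) == 0

    def test_colinear_example_matches_exhaustive_oracle(self):
        q = linear_annotation("q", 4, prefix="q")
        t = linear_annotation("t", 6, prefix="t")
        # target rank sequence 3,1,2,5 in query order
        r = CandidateRegion("t", "chr1", [("q0", "t3"), ("q1", "t1"), ("q2", "t2"), ("q3", "t5")], 1, 5)
        assert colinear_score(r, q, t) == 3
        assert monotone_exhaustive([3, 1, 2, 5]) == 3

    @pytest.mark.parametrize("n", [1, 2, 5, 9])
    def test_monotone_sequences_score_fully(self, n):
        assert longest_monotone_run(list(range(n))) == n
        assert longest_monotone_run(list(range(n, 0, -1))) == n

    @given(seq=st.lists(st.integers(0, 50), min_size=0, max_size=60))
    @settings(deadline=None, max_examples=150)
    def test_patience_sort_agrees_with_dp(self, seq):
        assert longest_monotone_run(seq) == monotone_dp(seq)

    @given(seq=st.lists(st.integers(0, 20), min_size=1, max_size=9))
    @settings(deadline=None, max_examples=50)
    def test_dp_agrees_with_exhaustive_at_tiny_n(self, seq):
        assert monotone_dp(seq) == monotone_exhaustive(seq)


class TestFilterAndRank:
    def make_regions(self, scores):
        return [
            CandidateRegion("t", "c", [(f"q{i}", f"t{i}")], i * 10, i * 10 + 1, density_score=s, colinear_score=s)
            for i, s in enumerate(scores)
        ]

    def test_min_score_threshold(self):
        kept = filter_and_rank(self.make_regions([5, 4, 3]), SynFindParams(), "q")
        assert [r.density_score for r in kept] == [5, 4]

    def test_max_depth_truncates(self):
        kept = filter_and_rank(self.make_regions([6, 5, 5]), SynFindParams(max_depth=1), "q")
        assert len(kept) == 1 and kept[0].density_score == 6

    def test_all_below_threshold_gives_depth_zero(self):
        assert filter_and_rank(self.make_regions([1, 2, 3]), SynFindParams(), "q") == []

    def test_tie_break_is_deterministic(self):
        regions = self.make_regions([5, 5])
        regions[0].target_chrom, regions[1].target_chrom = "cB", "cA"
        kept = filter_and_rank(regions, SynFindParams(), "q")
        assert [r.target_chrom for r in kept] == ["cA", "cB"]


class TestClassify:
    def setup_method(self):
        self.q = linear_annotation("q", 12, prefix="q")
        self.t = linear_annotation("t", 12, chrom="tchr", prefix="t")
        self.params = SynFindParams(window_size=8, min_score=2)

    def run_one(self, pairs, gene):
        table = make_table(self.q, self.t, pairs)
        regions = seed_regions(gene, self.q, self.t, table.collapsed_pairs, self.params)
        kept = filter_and_rank(regions, self.params, gene)
        assert len(kept) == 1
        return classify_hit(gene, kept[0], table, self.q, self.t, self.params)

    def test_own_match_gives_class_s(self):
        pairs = make_pairs([("q4", "t4", 100), ("q5", "t5", 100), ("q6", "t6", 100)])
        hit = self.run_one(pairs, "q5")
        assert hit.syntelog_class == "S"
        assert hit.anchor_gene == "t5"

    def test_missing_gene_with_both_flankers_is_f_anchored_on_nearer(self):
        # matched window genes at ranks r-2 and r+1: nearer downstream flanker wins
        pairs = make_pairs([("q3", "t3", 100), ("q6", "t6", 100)])
        hit = self.run_one(pairs, "q5")
        assert hit.syntelog_class == "F"
        assert hit.anchor_gene == "t6"
        assert (hit.flanker_up, hit.flanker_down) == ("q3", "q6")

    def test_flanker_distance_tie_prefers_upstream(self):
        pairs = make_pairs([("q4", "t4", 100), ("q6", "t6", 100)])
        hit = self.run_one(pairs, "q5")
        assert hit.syntelog_class == "F"
        assert hit.anchor_gene == "t4"

    def test_scaffold_end_gives_class_g(self):
        pairs = make_pairs([("q1", "t1", 100), ("q2", "t2", 100)])
        hit = self.run_one(pairs, "q0")
        assert hit.syntelog_class == "G"
        assert hit.anchor_gene == "t1"
        assert hit.flanker_up is None

    def test_tandem_member_recovers_own_syntelog_from_raw_pairs(self):
        # q5/q6 form an array collapsed to q5; q6's own raw match must be recovered
        raw = make_pairs(
            [("q5", "t5", 100), ("q6", "t5", 90), ("q6", "t6", 95), ("q4", "t4", 100), ("q7", "t7", 100)]
        )
        collapsed = make_pairs([("q5", "t5", 100), ("q5", "t6", 95), ("q4", "t4", 100), ("q7", "t7", 100)])
        arr = TandemArray("q", "chr1", frozenset({"q5", "q6"}), "q5")
        table = make_table(self.q, self.t, raw, collapsed, q_tandems=[arr])
        regions = seed_regions("q6", self.q, self.t, table.collapsed_pairs, self.params)
        kept = filter_and_rank(regions, self.params, "q6")
        hit = classify_hit("q6", kept[0], table, self.q, self.t, self.params)
        assert hit.syntelog_class == "S"
        assert hit.anchor_gene == "t6"  # its own best raw match, not the rep's


class TestRecoverTandemBest:
    def setup_method(self):
        self.t = linear_annotation("t", 12, chrom="tchr", prefix="t")
        self.region = CandidateRegion("t", "tchr", [("q", "t7")], 5, 10)

    def test_max_raw_score_wins(self):
        raw = make_pairs([("q", "t7", 120), ("q", "t8", 200)])
        assert recover_tandem_best("q", self.region, raw, [], self.t) == "t8"

    def test_single_pair(self):
        raw = make_pairs([("q", "t7", 120)])
        assert recover_tandem_best("q", self.region, raw, [], self.t) == "t7"

    def test_score_tie_breaks_to_lowest_target_rank(self):
        raw = make_pairs([("q", "t9", 150), ("q", "t7", 150)])
        assert recover_tandem_best("q", self.region, raw, [], self.t) == "t7"

    def test_pairs_outside_region_bounds_ignored(self):
        raw = make_pairs([("q", "t2", 500), ("q", "t7", 10)])
        assert recover_tandem_best("q", self.region, raw, [], self.t) == "t7"


class TestRunSynfind:
    def test_self_synteny_all_class_s_anchored_on_self(self):
        ann = linear_annotation("g", 60)
        identity = make_pairs([(g.gene_id, g.gene_id, 100) for g in ann.genes])
        table = make_table(ann, ann, identity)
        params = SynFindParams()
        results = run_synfind(ann, [ann], [table], params)
        for g in ann.genes:
            hits = results[g.gene_id]["g"]
            assert len(hits) == 1
            h = hits[0]
            assert h.syntelog_class == "S" and h.anchor_gene == g.gene_id
            # score equals window occupancy
            occupancy = min(g.rank, 20) + min(len(ann) - 1 - g.rank, 20) + 1
            assert h.synteny_score == occupancy

    def test_empty_pair_table_yields_no_hits(self):
        q = linear_annotation("q", 10, prefix="q")
        t = linear_annotation("t", 10, prefix="t")
        results = run_synfind(q, [t], [make_table(q, t, {})], SynFindParams(window_size=4, min_score=1))
        assert all(hits == [] for per in results.values() for hits in per.values())

    def test_missing_pair_table_is_configuration_error(self):
        q = linear_annotation("q", 10, prefix="q")
        t = linear_annotation("t", 10, prefix="t")
        with pytest.raises(ValueError, match="pair table"):
            run_synfind(q, [t], [], SynFindParams(window_size=4, min_score=1))

    def test_two_targets_are_independent(self):
        q = linear_annotation("q", 10, prefix="q")
        t1 = linear_annotation("t1", 10, prefix="a")
        t2 = linear_annotation("t2", 10, prefix="b")
        pairs1 = make_pairs([(f"q{i}", f"a{i}", 100) for i in range(10)])
        params = SynFindParams(window_size=4, min_score=2)
        both = run_synfind(q, [t1, t2], [make_table(q, t1, pairs1), make_table(q, t2, {})], params)
        solo = run_synfind(q, [t1], [make_table(q, t1, pairs1)], params)
        for gid in both:
            assert [h.anchor_gene for h in both[gid]["t1"]] == [h.anchor_gene for h in solo[gid]["t1"]]
            assert both[gid]["t2"] == []


def random_instance(rng):
    n_q = int(rng.integers(5, 51))
    n_t = int(rng.integers(5, 51))
    q = linear_annotation("q", n_q, prefix="q")
    chroms = ["tc1", "tc2"]
    t = make_annotation(
        "t",
        [(f"t{i}", chroms[i % 2], (i // 2) * 100, (i // 2) * 100 + 50) for i in range(n_t)],
    )
    n_pairs = int(rng.integers(1, 80))
    pairs = {}
    for _ in range(n_pairs):
        qi, ti = int(rng.integers(n_q)), int(rng.integers(n_t))
        key = (f"q{qi}", f"t{ti}")
        pairs[key] = make_pairs([(key[0], key[1], float(rng.integers(1, 300)))])[key]
    w = int(rng.choice([4, 8, 20, 40]))
    params = SynFindParams(window_size=w, min_score=1)
    return q, t, pairs, params


def test_regions_and_scores_match_brute_force_oracle():
    rng = np.random.default_rng(2024)
    for _ in range(30):
        q, t, pairs, params = random_instance(rng)
        for g in q.genes:
            got = {
                (r.target_chrom, r.min_rank, r.max_rank): (r.density_score, r.colinear_score)
                for r in seed_regions(g.gene_id, q, t, pairs, params)
            }
            expected = brute_force_regions(g.gene_id, q, t, pairs, params)
            assert got == expected


def test_density_score_monotone_in_window_size():
    rng = np.random.default_rng(7)
    for _ in range(10):
        q, t, pairs, _ = random_instance(rng)
        for w1, w2 in [(4, 8), (8, 20), (20, 40)]:
            p1 = SynFindParams(window_size=w1, min_score=1)
            p2 = SynFindParams(window_size=w2, min_score=1, cluster_gap=p1.cluster_gap)
            for g in q.genes:
                best1 = max(
                    (r.density_score for r in seed_regions(g.gene_id, q, t, pairs, p1)),
                    default=0,
                )
                best2 = max(
                    (r.density_score for r in seed_regions(g.gene_id, q, t, pairs, p2)),
                    default=0,
                )
                assert best2 >= best1


def test_colinear_never_exceeds_density():
    rng = np.random.default_rng(11)
    for _ in range(15):
        q, t, pairs, params = random_instance(rng)
        for g in q.genes:
            for r in seed_regions(g.gene_id, q, t, pairs, params):
                assert r.colinear_score <= r.density_score
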