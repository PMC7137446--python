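import numpy as np
import pytest

from dmcpg.clusters import (
    cluster_score_summary, clusters_to_table, find_clusters, find_isolated,
)

from conftest import (
    brute_force_clusters, clusters_as_set, make_probe_table, random_instance,
)


class TestFindClusters:
    def test_seed_plus_one_neighbour_scores_two(self):
        # the minimal cluster: one selecting CpG and one DM CpG 500 bp away
        diff, man = make_probe_table(
            positions=[10_000, 10_500, 50_000],
            p_values=[5e-5, 4e-3, 0.5],
            directions=["hyper", "hyper", "hyper"])
        cls = find_clusters(diff, man)
        assert len(cls) == 1
        assert cls[0].score == 2
        assert cls[0].member_probes == {"p0", "p1"}
        assert cls[0].selecting_probes == {"p0"}
        assert (cls[0].start, cls[0].end) == (10_000, 10_500)

    def test_lone_seed_routed_to_isolated(self):
        diff, man = make_probe_table(
            positions=[10_000, 20_000],
            p_values=[5e-5, 0.5],
            directions=["hyper", "hyper"])
        cls = find_clusters(diff, man)
        assert cls == []
        iso = find_isolated(diff, man, cls)
        assert list(iso["probe_id"]) == ["p0"]

    def test_transitive_merge_of_chained_seeds(self):
        # three seeds 1200 bp apart sharing members merge into one cluster
        diff, man = make_probe_table(
            positions=[1_000, 1_500, 2_200, 2_800, 3_400],
            p_values=[1e-5, 5e-3, 1e-5, 5e-3, 1e-5],
            directions=["hyper"] * 5)
        cls = find_clusters(diff, man)
        assert len(cls) == 1
        assert cls[0].score == 5
        assert cls[0].selecting_probes == {"p0", "p2", "p4"}
        assert clusters_as_set(cls) == brute_force_clusters(diff, man)

    def test_window_boundary_inclusive_at_1500(self):
        diff, man = make_probe_table(
            positions=[10_000, 11_500, 30_000, 31_501],
            p_values=[1e-5, 5e-3, 1e-5, 5e-3],
            directions=["hyper"] * 4)
        cls = find_clusters(diff, man)
        assert len(cls) == 1                       # 1500 in, 1501 out
        assert cls[0].member_probes == {"p0", "p1"}

    def test_discordant_neighbour_not_a_member(self):
        diff, man = make_probe_table(
            positions=[10_000, 10_400, 10_800],
            p_values=[1e-5, 4e-3, 4e-3],
            directions=["hyper", "hypo", "hyper"])
        cls = find_clusters(diff, man)
        assert len(cls) == 1
        assert cls[0].member_probes == {"p0", "p2"}

    def test_direction_any_mode_ignores_sign(self):
        diff, man = make_probe_table(
            positions=[10_000, 10_400],
            p_values=[1e-5, 4e-3],
            directions=["hyper", "hypo"])
        assert find_clusters(diff, man) == []
        cls = find_clusters(diff, man, direction_mode="any")
        assert len(cls) == 1 and cls[0].score == 2

    def test_probes_on_other_chromosome_never_join(self):
        diff, man = make_probe_table(
            positions=[10_000, 10_400],
            p_values=[1e-5, 4e-3],
            directions=["hyper", "hyper"])
        man.loc[1, "chrom"] = "chr2"
        assert find_clusters(diff, man) == []

    def test_invalid_parameters_rejected(self):
        diff, man = make_probe_table([100], [0.5], ["hyper"])
        with pytest.raises(ValueError):
            find_clusters(diff, man, window=0)
        with pytest.raises(ValueError):
            find_clusters(diff, man, p_select=1e-2, p_member=1e-4)

    def test_empty_input_gives_empty_list(self):
        diff, man = make_probe_table([], [], [])
        assert find_clusters(diff, man) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        diff, man = random_instance(rng, n_probes=150)
        assert clusters_as_set(find_clusters(diff, man)) == \
            brute_force_clusters(diff, man)

    def test_window_growth_never_shrinks_scores(self):
        rng = np.random.default_rng(42)
        diff, man = random_instance(rng, n_probes=300, spike_rate=0.05)
        prev_best = {}
        prev_seeds = None
        for window in (500, 1500, 4000, 10_000):
            cls = find_clusters(diff, man, window=window)
            best = {}
            for cl in cls:
                for pid in cl.selecting_probes:
                    best[pid] = max(best.get(pid, 0), cl.score)
            # a seed's cluster score never decreases as the window grows
            for pid, s in prev_best.items():
                assert best.get(pid, 0) >= s
            # seeds clustered at the smaller window only ever merge further:
            # the number of clusters over that fixed seed set cannot grow
            if prev_seeds is not None:
                n_over_prev = len({cl.selecting_probes for cl in cls
                                   if cl.selecting_probes & prev_seeds})
                assert n_over_prev <= prev_n
            prev_best = best
            prev_seeds = set().union(*(cl.selecting_probes for cl in cls)) \
                if cls else set()
            prev_n = len(cls)

    def test_same_direction_clusters_disjoint(self):
        rng = np.random.default_rng(7)
        diff, man = random_instance(rng, n_probes=400, spike_rate=0.08)
        cls = find_clusters(diff, man)
        seen = {}
        for cl in cls:
            key = (cl.chrom, cl.direction)
            for pid in cl.member_probes:
                assert (key, pid) not in seen
                seen[(key, pid)] = True

    def test_members_within_window_of_some_seed(self):
        rng = np.random.default_rng(11)
        diff, man = random_instance(rng, n_probes=300, spike_rate=0.05)
        pos = man.set_index("probe_id")["pos"]
        for cl in find_clusters(diff, man):
            for pid in cl.member_probes:
                assert any(abs(pos[pid] - pos[s]) <= 1500
                           for s in cl.selecting_probes)


class TestFindIsolated:
    def test_distant_dm_probe_is_isolated(self):
        diff, man = make_probe_table(
            positions=[10_000, 15_000],
            p_values=[5e-4, 0.5],
            directions=["hypo", "hypo"])
        iso = find_isolated(diff, man, [])
        assert list(iso["probe_id"]) == ["p0"]
        assert iso["island_relation"].iloc[0] == "open_sea"

    def test_cluster_members_excluded(self):
        diff, man = make_probe_table(
            positions=[10_000, 10_500],
            p_values=[5e-5, 5e-4],
            directions=["hyper", "hyper"])
        cls = find_clusters(diff, man)
        iso = find_isolated(diff, man, cls)
        assert len(iso) == 0

    def test_ranked_by_ascending_p(self):
        diff, man = make_probe_table(
            positions=[10_000, 50_000],
            p_values=[9e-4, 1e-4],
            directions=["hyper", "hyper"])
        iso = find_isolated(diff, man, [])
        assert list(iso["probe_id"]) == ["p1", "p0"]

    def test_threshold_is_stricter_than_dm(self):
        diff, man = make_probe_table(
            positions=[10_000], p_values=[5e-3], directions=["hyper"])
        iso = find_isolated(diff, man, [])
        assert len(iso) == 0           # DM at 0.01 but not isolated at 0.001


class TestScoreSummary:
    def _make(self, scores, direction):
        diff, man = make_probe_table([], [], [])
        out = []
        pos = 0
        from dmcpg.clusters import Cluster
        for s in scores:
            out.append(Cluster(
                chrom="chr1", start=pos, end=pos + 100, direction=direction,
                member_probes=frozenset(f"q{pos}_{i}" for i in range(s)),
                selecting_probes=frozenset([f"q{pos}_0"])))
            pos += 1000
        return out

    def test_counts_median_and_range(self):
        cls = self._make([2, 2, 3, 4, 9], "hyper")
        s = cluster_score_summary(cls)
        assert s["hyper"]["n_score_2"] == 2
        assert s["hyper"]["n_score_ge3"] == 3
        assert s["hyper"]["median_score_ge3"] == 4
        assert s["hyper"]["score_range_ge3"] == (3, 9)
        assert s["hypo"]["n_score_ge3"] == 0

    def test_empty_is_na(self):
        s = cluster_score_summary([])
        assert s["hyper"]["median_score_ge3"] is None
        assert s["hyper"]["score_range_ge3"] is None

    def test_two_threes(self):
        s = cluster_score_summary(self._make([3, 3], "hypo"))
        assert s["hypo"]["median_score_ge3"] == 3
        assert s["hypo"]["score_range_ge3"] == (3, 3)

    def test_member_table_row_per_member(self):
        cls = self._make([2, 3], "hyper")
        tab = clusters_to_table(cls)
        assert len(tab) == 5
        assert set(tab["score"]) == {2, 3}
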