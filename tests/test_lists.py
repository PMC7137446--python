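import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from dmcpg.lists import (
    build_list2, build_list3, compute_tail_cutoffs, intersect_lists,
    nearest_tss,
)

from conftest import make_probe_table


def _diff_frame(delta, p=None, genes=None, tss=None):
    n = len(delta)
    diff = pd.DataFrame({
        "delta_beta": list(delta),
        "p_value": list(p) if p is not None else [0.5] * n,
    }, index=pd.Index([f"p{i}" for i in range(n)], name="probe_id"))
    diff["direction"] = np.where(diff["delta_beta"] > 0, "hyper", "hypo")
    manifest = pd.DataFrame({
        "probe_id": diff.index,
        "chrom": "chr1",
        "pos": np.arange(1, n + 1) * 1000,
        "island_relation": "core",
        "gene_symbol": genes if genes is not None else ["G"] * n,
        "tss_distance": tss if tss is not None else [10] * n,
        "flag_snp": False,
        "flag_crossreactive": False,
    })
    return diff, manifest


def sort_quantile_oracle(values, q):
    """Independent linear-interpolation quantile from first principles."""
    v = sorted(values)
    h = (len(v) - 1) * q
    lo = int(np.floor(h))
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


class TestTailCutoffs:
    def test_analytic_uniform_grid(self):
        delta = np.linspace(-1, 1, 10_001)
        diff, _ = _diff_frame(delta)
        cuts = compute_tail_cutoffs(diff)
        assert cuts.q_low == pytest.approx(-0.95)
        assert cuts.q_high == pytest.approx(0.95)

    def test_recommended_cutoff_rounds_up_to_next_cent(self):
        # quantiles like -0.04612 / +0.04432 recommend a 0.05 working cutoff
        rng = np.random.default_rng(0)
        delta = rng.normal(0, 0.02, 5000)
        diff, _ = _diff_frame(delta)
        cuts = compute_tail_cutoffs(diff)
        expect = np.ceil(round(max(abs(cuts.q_low), abs(cuts.q_high)) * 100,
                               9)) / 100
        assert cuts.recommended_symmetric == expect
        assert cuts.recommended_symmetric >= max(abs(cuts.q_low),
                                                 abs(cuts.q_high))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sort_oracle(self, seed):
        rng = np.random.default_rng(seed)
        delta = rng.normal(0, 0.05, 140)
        diff, _ = _diff_frame(delta)
        cuts = compute_tail_cutoffs(diff)
        assert cuts.q_low == pytest.approx(
            sort_quantile_oracle(delta, 0.025), abs=1e-12)
        assert cuts.q_high == pytest.approx(
            sort_quantile_oracle(delta, 0.975), abs=1e-12)

    def test_too_few_probes_rejected(self):
        diff, _ = _diff_frame(np.zeros(99))
        with pytest.raises(ValueError, match="100"):
            compute_tail_cutoffs(diff)


class TestBuildList2:
    def test_selection_rule(self):
        diff, man = _diff_frame(
            delta=[0.06, 0.06, 0.02],
            p=[5e-4, 5e-3, 5e-4],
            genes=["A", "B", "C"])
        gl = build_list2(diff, man, cutoff=0.05, p_max=1e-3)
        assert gl.symbols == {"A"}           # B fails p, C fails delta
        assert gl.entries.iloc[0]["direction"] == "hyper"

    def test_per_gene_dedup_keeps_min_p_max_delta(self):
        diff, man = _diff_frame(
            delta=[-0.07, -0.12],
            p=[1e-4, 1e-5],
            genes=["B", "B"])
        gl = build_list2(diff, man, cutoff=0.05)
        assert len(gl.entries) == 1
        row = gl.entries.iloc[0]
        assert row["best_p"] == 1e-5
        assert row["max_abs_delta_beta"] == pytest.approx(0.12)
        assert row["n_supporting_probes"] == 2
        assert row["direction"] == "hypo"

    def test_mixed_direction_gene_takes_largest_effect_and_flag(self):
        diff, man = _diff_frame(
            delta=[0.06, -0.11],
            p=[1e-4, 1e-4],
            genes=["X", "X"])
        gl = build_list2(diff, man, cutoff=0.05)
        row = gl.entries.iloc[0]
        assert row["direction"] == "hypo"
        assert row["mixed_direction"]

    def test_unassigned_probes_collected(self):
        diff, man = _diff_frame(
            delta=[0.08, 0.08],
            p=[1e-4, 1e-4],
            genes=["A", ""])
        gl = build_list2(diff, man, cutoff=0.05)
        assert gl.symbols == {"A"}
        assert list(gl.unassigned["probe_id"]) == ["p1"]

    def test_distant_tss_goes_unassigned(self):
        diff, man = _diff_frame(
            delta=[0.08], p=[1e-4], genes=["FAR"], tss=[250_000])
        gl = build_list2(diff, man, cutoff=0.05)
        assert gl.symbols == set()
        assert len(gl.unassigned) == 1

    def test_dedup_conserves_probe_count(self):
        rng = np.random.default_rng(2)
        n = 300
        diff, man = _diff_frame(
            delta=rng.normal(0, 0.08, n),
            p=rng.uniform(0, 2e-3, n),
            genes=[f"G{i % 40}" for i in range(n)])
        gl = build_list2(diff, man, cutoff=0.05)
        selected = ((diff["delta_beta"].abs() >= 0.05)
                    & (diff["p_value"] <= 1e-3)).sum()
        assert gl.entries["n_supporting_probes"].sum() == selected

    def test_monotone_in_cutoff_and_pmax(self):
        rng = np.random.default_rng(3)
        n = 400
        diff, man = _diff_frame(
            delta=rng.normal(0, 0.08, n),
            p=rng.uniform(0, 5e-3, n),
            genes=[f"G{i % 60}" for i in range(n)])
        base = build_list2(diff, man, cutoff=0.05, p_max=1e-3).symbols
        assert build_list2(diff, man, cutoff=0.08, p_max=1e-3).symbols <= base
        assert build_list2(diff, man, cutoff=0.05, p_max=1e-4).symbols <= base


class TestBuildList3:
    def _list2(self):
        diff, man = _diff_frame(
            delta=[0.12, -0.09, 0.25, 0.06],
            p=[1e-4] * 4,
            genes=["A", "B", "C", "D"])
        return build_list2(diff, man, cutoff=0.05)

    def test_threshold_on_max_abs_delta(self):
        l3 = build_list3(self._list2())
        assert l3.symbols == {"A", "C"}      # 0.12 and 0.25 in, 0.09/0.06 out

    def test_subset_of_list2(self):
        l2 = self._list2()
        l3 = build_list3(l2)
        assert l3.symbols <= l2.symbols


class TestIntersect:
    def test_basic_overlap(self):
        overlap, counts = intersect_lists({"A", "B", "C"}, {"B", "C", "D"})
        assert overlap == {"B", "C"}
        assert counts == {"n_a": 3, "n_b": 3, "n_overlap": 2}

    def test_disjoint_and_identity(self):
        assert intersect_lists({"A"}, {"B"})[1]["n_overlap"] == 0
        s = {"A", "B"}
        assert intersect_lists(s, s)[0] == s

    def test_case_normalized(self):
        overlap, _ = intersect_lists({"Tnf", "il6"}, {"TNF", "IL6R"})
        assert overlap == {"TNF"}

    def test_accepts_genelists(self):
        diff, man = _diff_frame([0.2], [1e-5], genes=["TNF"])
        gl = build_list2(diff, man, cutoff=0.05)
        overlap, counts = intersect_lists(gl, ["tnf", "IL6"])
        assert overlap == {"TNF"} and counts["n_overlap"] == 1


class TestNearestTss:
    TSS = pd.DataFrame({
        "gene_symbol": ["A", "B"],
        "chrom": ["chr1", "chr1"],
        "tss": [1_100, 6_000],
    })

    def test_nearest_wins(self):
        assert nearest_tss(1_000, "chr1", self.TSS) == "A"

    def test_tie_breaks_lexicographically(self):
        tss = pd.DataFrame({"gene_symbol": ["B1", "A2"],
                            "chrom": ["chr1", "chr1"],
                            "tss": [900, 1_100]})
        assert nearest_tss(1_000, "chr1", tss) == "A2"

    def test_distance_cap(self):
        assert nearest_tss(260_000, "chr1", self.TSS) == ""
        assert nearest_tss(260_000, "chr1", self.TSS,
                           max_distance=300_000) == "B"


@given(st.lists(st.floats(-0.5, 0.5), min_size=100, max_size=160))
@settings(derandomize=True, max_examples=50)
def test_quantiles_match_oracle_property(values):
    diff = pd.DataFrame({
        "delta_beta": values, "p_value": 0.5,
        "direction": "hyper",
    }, index=pd.Index([f"p{i}" for i in range(len(values))], name="probe_id"))
    cuts = compute_tail_cutoffs(diff)
    assert cuts.q_low == pytest.approx(
        sort_quantile_oracle(values, 0.025), abs=1e-9)
    assert cuts.q_high == pytest.approx(
        sort_quantile_oracle(values, 0.975), abs=1e-9)
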