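"""Informativeness, filtering, two-point LOD, grouping, ordering, map
functions, merging and map statistics."""

import numpy as np
import pandas as pd
import pytest

import oracles
from esoxsynt.linkage import (GroupingResult, LinkageMap, TwoPointAnalysis,
                              build_parent_map, classify_informativeness,
                              group_markers, lod_score, map_distance,
                              map_stats, merge_maps, missing_filter,
                              order_group, transmitted_allele, two_point)
from esoxsynt.simdata import FamilyConfig, GenotypeTable, make_marker_map, \
    simulate_half_sib_family


class TestInformativeness:
    @pytest.mark.parametrize("m,f,want", [
        ("a/b", "a/a", "mother_only"),
        ("a/b", "c/d", "both"),
        ("a/a", "a/a", "neither"),
        ("a/a", "a/b", "father_only"),
        ("a/b", "a/b", "both"),
    ])
    def test_rules(self, m, f, want):
        assert classify_informativeness(m, f) == want

    def test_malformed_genotype_rejected(self):
        with pytest.raises(ValueError):
            classify_informativeness("ab", "a/a")

    def test_transmitted_allele_resolution(self):
        assert transmitted_allele("a/c", "a/b", "c/c") == "a"
        # both assignments possible -> ambiguous
        assert transmitted_allele("a/b", "a/b", "a/b") is None
        # Mendelian inconsistency -> None (treated as missing)
        assert transmitted_allele("x/y", "a/b", "c/d") is None


def _table(rows, progeny_per_father=(2, 2)):
    """Tiny hand-built GenotypeTable; rows: marker -> list of calls."""
    fathers = [f"father{k+1}" for k in range(len(progeny_per_father))]
    progeny = [f"father{k+1}_o{i+1:03d}"
               for k, n in enumerate(progeny_per_father) for i in range(n)]
    cols = ["mother"] + fathers + progeny
    data = pd.DataFrame(rows, index=cols).T
    pf = {p: p.split("_")[0] for p in progeny}
    return GenotypeTable(data=data, mother="mother", fathers=fathers,
                         progeny_father=pf)


class TestMissingFilter:
    def _big_table(self, n_missing):
        fathers = ["father1"]
        progeny = [f"father1_o{i+1:03d}" for i in range(92)]
        calls = ["-"] * n_missing + ["a/c"] * (92 - n_missing)
        row = ["a/b", "c/c"] + calls
        data = pd.DataFrame({c: [v] for c, v in
                             zip(["mother"] + fathers + progeny, row)},
                            index=["m1"])
        return GenotypeTable(data=data, mother="mother", fathers=fathers,
                             progeny_father={p: "father1" for p in progeny})

    def test_boundary_15_percent(self):
        # 14/92 = 15.2% -> dropped; 13/92 = 14.1% -> kept
        assert missing_filter(self._big_table(14)).markers == []
        assert missing_filter(self._big_table(13)).markers == ["m1"]

    def test_keep_list_overrides(self):
        t = missing_filter(self._big_table(20), keep_list=["m1"])
        assert t.markers == ["m1"]

    def test_marker_order_independent(self, rng):
        tmap = make_marker_map(2, 6, 5.0)
        table = simulate_half_sib_family(tmap, FamilyConfig(missing_rate=0.2),
                                         rng)
        f1 = missing_filter(table, 0.15)
        shuffled = GenotypeTable(data=table.data.iloc[::-1],
                                 mother=table.mother, fathers=table.fathers,
                                 progeny_father=table.progeny_father)
        f2 = missing_filter(shuffled, 0.15)
        assert sorted(f1.markers) == sorted(f2.markers)


class TestTwoPoint:
    def _phase_table(self, n, recombinants):
        """Mother a/b x father c/c; progeny phase pattern with x switches."""
        rows = {}
        m1 = ["a/b", "c/c"]
        m2 = ["a/b", "c/c"]
        for i in range(n):
            a1 = "a" if i < n else "b"
            m1.append(f"{a1}/c")
            a2 = a1 if i >= recombinants else ("b" if a1 == "a" else "a")
            m2.append(f"{a2}/c")
        rows["m1"], rows["m2"] = m1, m2
        return _table(rows, progeny_per_father=(n,))

    @pytest.mark.parametrize("n,r,want", [(20, 0, 6.02), (20, 10, 0.0)])
    def test_closed_form_examples(self, n, r, want):
        t = self._phase_table(n, r)
        st = two_point(t, "m1", "m2", "mother")
        assert st.n == n and st.r == r
        assert st.lod == pytest.approx(want, abs=0.01)

    def test_n100_r20_matches_binomial_oracle(self):
        t = self._phase_table(100, 20)
        st = two_point(t, "m1", "m2", "mother")
        assert st.lod == pytest.approx(8.37, abs=0.01)
        assert st.lod == pytest.approx(oracles.binomial_lod(20, 100), abs=1e-9)

    def test_lod_decreasing_in_r_and_zero_at_half(self):
        n = 60
        vals = [lod_score(r, n) for r in range(0, n // 2 + 1)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[-1] == pytest.approx(0.0, abs=1e-12)

    def test_progeny_missing_at_either_marker_excluded(self):
        t = self._phase_table(10, 0)
        t.data.loc["m1", "father1_o001"] = "-"
        st = two_point(t, "m1", "m2", "mother")
        assert st.n == 9


class _FakeAnalysis:
    """Minimal stand-in exposing the attributes group_markers reads."""

    def __init__(self, per_parent):
        self.parents = list(per_parent)
        self.markers_by_parent = {}
        self.lod = {}
        self.rhat = {}
        self.n = {}
        for parent, (markers, lod) in per_parent.items():
            self.markers_by_parent[parent] = markers
            arr = np.asarray(lod, dtype=float)
            self.lod[parent] = arr
            self.rhat[parent] = np.where(arr >= 3, 0.1, 0.45)
            self.n[parent] = np.full_like(arr, 50)


class TestGrouping:
    def test_single_linkage_transitivity(self):
        lod = [[np.nan, 5.0, 0.1], [5.0, np.nan, 5.0], [0.1, 5.0, np.nan]]
        an = _FakeAnalysis({"mother": (["a", "b", "c"], lod)})
        g = group_markers(an)
        assert g.groups == [["a", "b", "c"]]
        assert g.unlinked == []

    def test_weak_bridge_needs_cross_parent_support(self):
        # a-b at 3.4 in mother; father links the same pair at 4.2
        lod_m = [[np.nan, 3.4], [3.4, np.nan]]
        lod_f = [[np.nan, 4.2], [4.2, np.nan]]
        an = _FakeAnalysis({"mother": (["a", "b"], lod_m),
                            "father1": (["a", "b"], lod_f)})
        g = group_markers(an)
        assert g.groups == [["a", "b"]]
        assert g.per_parent["mother"] == [["a", "b"]]
        # without the supporting parent the bridge is not taken
        an2 = _FakeAnalysis({"mother": (["a", "b"], lod_m)})
        g2 = group_markers(an2)
        assert g2.groups == []
        assert g2.unlinked == ["a", "b"]

    def test_simulated_groups_recover_chromosomes(self, rng):
        tmap = make_marker_map(6, 10, 4.0)
        table = simulate_half_sib_family(tmap, FamilyConfig(missing_rate=0.0,
                                                            mother_het=1.0,
                                                            father_het=1.0),
                                         rng)
        an = TwoPointAnalysis(table)
        g = group_markers(an)
        assert len(g.groups) == 6
        truth_lg = tmap.set_index("marker")["lg"]
        for grp in g.groups:
            assert truth_lg[grp].nunique() == 1


class TestOrdering:
    def test_three_marker_chain(self):
        rh = np.array([[np.nan, 0.05, 0.10],
                       [0.05, np.nan, 0.05],
                       [0.10, 0.05, np.nan]])
        an = _FakeAnalysis({"mother": (["A", "B", "C"],
                                       np.where(np.isnan(rh), np.nan, 5.0))})
        an.rhat["mother"] = rh
        assert order_group(["A", "B", "C"], an, "mother") == ["A", "B", "C"]

    def test_two_markers_trivial(self):
        an = _FakeAnalysis({"mother": (["B", "A"],
                                       [[np.nan, 4.0], [4.0, np.nan]])})
        assert order_group(["B", "A"], an, "mother") == ["A", "B"]

    def test_simulated_order_recovered(self, rng):
        tmap = make_marker_map(1, 8, 6.0)
        fam = FamilyConfig(n_progeny_per_father=[250, 250], missing_rate=0.0,
                           mother_het=1.0, father_het=0.0)
        table = simulate_half_sib_family(tmap, fam, rng)
        an = TwoPointAnalysis(table)
        g = group_markers(an)
        chain = order_group(g.groups[0], an, "mother")
        truth = tmap["marker"].tolist()
        assert chain == truth or chain == truth[::-1]


class TestMapDistance:
    def test_closed_forms(self):
        assert map_distance(0.1, "haldane") == pytest.approx(11.157, abs=1e-3)
        assert map_distance(0.1, "kosambi") == pytest.approx(10.137, abs=1e-3)
        assert map_distance(0.0, "haldane") == 0.0
        assert map_distance(0.0, "kosambi") == 0.0

    def test_half_rejected(self):
        with pytest.raises(ValueError):
            map_distance(0.5)


def _map(sex, groups):
    return LinkageMap(sex=sex, groups={
        g: pd.DataFrame({"marker": mk, "pos_cM": pos})
        for g, (mk, pos) in groups.items()})


class TestMergeAndStats:
    def test_identical_maps_merge_to_same(self):
        f = _map("female", {"LG01": (["a", "b", "c"], [0.0, 5.0, 12.0])})
        m = _map("male", {"LG01": (["a", "b", "c"], [0.0, 5.0, 12.0])})
        merged, report = merge_maps(f, m)
        out = merged.groups["LG01"]
        assert out["marker"].tolist() == ["a", "b", "c"]
        assert out["pos_cM"].tolist() == [0.0, 5.0, 12.0]

    def test_private_markers_interpolated(self):
        f = _map("female", {"LG01": (["a", "c"], [0.0, 10.0])})
        m = _map("male", {"LG01": (["a", "b", "c"], [0.0, 4.0, 8.0])})
        merged, _ = merge_maps(f, m)
        out = merged.groups["LG01"].set_index("marker")["pos_cM"]
        assert out["b"] == pytest.approx(5.0)  # proportional placement

    def test_reversed_male_group_is_reoriented(self):
        f = _map("female", {"LG01": (["a", "b", "c"], [0.0, 5.0, 10.0])})
        m = _map("male", {"LG01": (["c", "x", "a"], [0.0, 2.5, 5.0])})
        merged, _ = merge_maps(f, m)
        out = merged.groups["LG01"].set_index("marker")["pos_cM"]
        assert out["a"] < out["x"] < out["c"]

    def test_group_without_shared_markers_reported_unmerged(self):
        f = _map("female", {"LG01": (["a", "b"], [0.0, 5.0])})
        m = _map("male", {"LGx": (["y", "z"], [0.0, 5.0])})
        merged, _ = merge_maps(f, m)
        assert merged.unmerged == ["male:LGx"]

    def test_published_ratio_arithmetic(self):
        f = _map("female", {"LG01": (["a", "b"], [0.0, 1245.4])})
        m = _map("male", {"LG01": (["a", "b"], [0.0, 1166.0])})
        stats = map_stats({"female": f, "male": m})
        assert stats["female_male_ratio"] == 1.07

    def test_identical_maps_ratio_one(self):
        f = _map("female", {"LG01": (["a", "b"], [0.0, 50.0])})
        stats = map_stats({"female": f, "male": f})
        assert stats["female_male_ratio"] == 1.00

    def test_expansion_recovered_at_scale(self, rng):
        tmap = make_marker_map(8, 10, 5.0)
        fam = FamilyConfig(n_progeny_per_father=[250, 250], missing_rate=0.05,
                           female_map_expansion=1.5)
        table = simulate_half_sib_family(tmap, fam, rng)
        an = TwoPointAnalysis(table)
        g = group_markers(an)
        female = build_parent_map(an, g, "mother", "haldane", sex="female")
        males = [build_parent_map(an, g, f, "haldane", sex=f"male{k}")
                 for k, f in enumerate(table.fathers)]
        from esoxsynt.pipeline import merge_males
        male, _ = merge_males(males)
        stats = map_stats({"female": female, "male": male})
        assert abs(stats["female_male_ratio"] - 1.5) <= 0.1
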