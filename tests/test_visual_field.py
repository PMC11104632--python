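import numpy as np
import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import random_vf
from noisefield.errors import InputError
from noisefield.visual_field import (GRID_STEP_DEG, LAYOUT, GHTResult,
                                     Laterality, PDCategory, Stage, VFResult,
                                     anderson_patella, estimate_axial_length,
                                     find_qualifying_clusters,
                                     hemifield_abnormal, reliability_ok,
                                     stage_classify, vf_from_dict, vf_to_dict)

LT5, LT1, LT05 = PDCategory.LT5, PDCategory.LT1, PDCategory.LT0_5


def make_vf(categories, laterality=Laterality.OD, **kwargs):
    kwargs.setdefault("md_db", -3.0)
    return VFResult.from_categories(laterality, categories, **kwargs)


class TestLayout:
    def test_canonical_30_2_shape(self):
        assert len(LAYOUT) == 76
        assert sum(p.edge for p in LAYOUT) == 24
        assert sum(p.nasal_edge for p in LAYOUT) == 4
        assert {(p.x_deg, p.y_deg) for p in LAYOUT if p.blind_spot} == \
            {(15, 3), (15, -3)}

    def test_coordinates_on_offset_6_degree_lattice(self):
        for p in LAYOUT:
            assert abs(p.x_deg) % 6 == 3 and abs(p.y_deg) % 6 == 3
            assert abs(p.x_deg) <= 27 and abs(p.y_deg) <= 27

    def test_nasal_edge_points_are_rim_points(self):
        for p in LAYOUT:
            if p.nasal_edge:
                assert p.edge and p.x_deg == -27


class TestReliability:
    @pytest.mark.parametrize("fp,fn,ok", [
        (0.10, 0.20, True),
        (0.15, 0.00, False),   # false positives at the 15% cutoff
        (0.00, 0.33, False),   # false negatives at the 33% cutoff
        (0.149, 0.329, True),
        (None, None, True),
    ])
    def test_cutoffs(self, fp, fn, ok):
        assert reliability_ok(fp, fn) is ok

    def test_rate_outside_unit_interval_rejected(self):
        with pytest.raises(InputError):
            reliability_ok(1.2, 0.0)


class TestClusters:
    def test_three_adjacent_nonedge_points_qualify(self):
        vf = make_vf({(-3, 3): LT1, (3, 3): LT5, (-3, 9): LT5})
        clusters = find_qualifying_clusters(vf)
        assert len(clusters) == 1
        assert clusters[0].hemifield == "superior"
        assert clusters[0].n_counted == 3

    def test_two_points_do_not_qualify_however_deep(self):
        vf = make_vf({(-3, 3): LT05, (3, 3): LT05})
        assert find_qualifying_clusters(vf) == []

    def test_cluster_without_lt1_point_does_not_qualify(self):
        vf = make_vf({(-3, 3): LT5, (3, 3): LT5, (-3, 9): LT5})
        assert find_qualifying_clusters(vf) == []

    def test_two_nasal_edge_points_count_toward_size(self):
        vf = make_vf({(-27, 3): LT5, (-27, 9): LT5, (-21, 3): LT1})
        clusters = find_qualifying_clusters(vf)
        assert len(clusters) == 1 and clusters[0].n_counted == 3

    def test_other_edge_points_never_count(self):
        # (27, 3) is a temporal rim point: connected but not counted
        vf = make_vf({(27, 3): LT1, (21, 3): LT5, (21, 9): LT5})
        assert find_qualifying_clusters(vf) == []

    def test_blind_spot_points_excluded(self):
        vf = make_vf({(15, 3): LT1, (9, 3): LT1, (9, 9): LT5})
        assert find_qualifying_clusters(vf) == []

    def test_no_adjacency_across_horizontal_meridian(self):
        vf = make_vf({(-3, 3): LT1, (-3, -3): LT1, (3, -3): LT5,
                      (-9, -3): LT5})
        clusters = find_qualifying_clusters(vf)
        assert [c.hemifield for c in clusters] == ["inferior"]
        assert clusters[0].n_counted == 3

    def test_diagonal_contiguity_joins_points(self):
        vf = make_vf({(-3, 3): LT1, (3, 9): LT5, (-9, 9): LT5})
        clusters = find_qualifying_clusters(vf)
        assert len(clusters) == 1 and clusters[0].n_counted == 3

    def test_pd_map_hidden_raises(self):
        vf = make_vf({}, pd_map_shown=False)
        with pytest.raises(InputError):
            find_qualifying_clusters(vf)


class TestAndersonPatella:
    def test_psd_alone_is_abnormal(self):
        vf = make_vf({}, psd_p_lt_5pct=True)
        assert anderson_patella(vf) == (True, frozenset({"psd"}))

    def test_ght_alone_is_abnormal(self):
        vf = make_vf({}, ght=GHTResult.OUTSIDE_NORMAL_LIMITS)
        assert anderson_patella(vf) == (True, frozenset({"ght"}))

    def test_all_normal_is_normal(self):
        vf = make_vf({})
        assert anderson_patella(vf) == (False, frozenset())

    def test_cluster_criterion_fires(self):
        vf = make_vf({(-3, 3): LT1, (3, 3): LT5, (-3, 9): LT5})
        abnormal, met = anderson_patella(vf)
        assert abnormal and met == frozenset({"cluster"})

    def test_hidden_pd_map_falls_back_to_global_indices(self):
        vf = make_vf({}, psd_p_lt_5pct=True, pd_map_shown=False)
        abnormal, met = anderson_patella(vf)
        assert abnormal and met == frozenset({"psd"})


class TestHemifield:
    def test_two_inferior_clusters_flag_inferior_only(self):
        # inferior nasal 6-point cluster + inferior temporal 3-point
        # cluster, superior hemifield clean
        nasal = {(-3, -3): LT1, (-9, -3): LT5, (-15, -3): LT5,
                 (-3, -9): LT5, (-9, -9): LT5, (-15, -9): LT5}
        temporal = {(9, -15): LT1, (15, -15): LT5, (9, -21): LT5}
        vf = make_vf({**nasal, **temporal})
        clusters = find_qualifying_clusters(vf)
        assert sorted(len(c.member_indices) for c in clusters) == [3, 6]
        assert hemifield_abnormal(vf) == {"superior": False, "inferior": True}

    def test_all_normal_map_flags_nothing(self):
        assert hemifield_abnormal(make_vf({})) == \
            {"superior": False, "inferior": False}

    def test_clusters_in_both_hemifields(self):
        vf = make_vf({(-3, 3): LT1, (3, 3): LT5, (-3, 9): LT5,
                      (-3, -3): LT1, (3, -3): LT5, (-3, -9): LT5})
        assert hemifield_abnormal(vf) == {"superior": True, "inferior": True}


class TestStaging:
    @pytest.mark.parametrize("md,pd_shown,stage", [
        (-5.9, True, Stage.M1),
        (-6.0, True, Stage.M2),    # boundary belongs to moderate
        (-12.0, True, Stage.M2),
        (-12.001, True, Stage.M3),
        (-21.0, False, Stage.M4),  # PD map withheld
        (-3.0, False, Stage.M4),
    ])
    def test_examples(self, md, pd_shown, stage):
        assert stage_classify(md, pd_shown) is stage

    @given(md=st.floats(min_value=-35, max_value=5, allow_nan=False),
           pd_shown=st.booleans())
    @settings(max_examples=100, deadline=None)
    def test_partition(self, md, pd_shown):
        assert stage_classify(md, pd_shown) in set(Stage)

    def test_nonfinite_md_rejected(self):
        with pytest.raises(InputError):
            stage_classify(float("nan"), True)


class TestAxialLength:
    @pytest.mark.parametrize("es,mm", [
        (0.0, 24.0), (-6.0, 25.998), (3.0, 24.999),
    ])
    def test_conversion(self, es, mm):
        assert estimate_axial_length(es) == pytest.approx(mm)


class TestLateralitySymmetry:
    def test_mirrored_chart_with_swapped_laterality_is_invariant(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            vf_od = random_vf(rng)
            doc = vf_to_dict(vf_od)
            doc["laterality"] = "OS"
            for p in doc["points"]:
                p["x"] = -p["x"]   # mirror about the vertical meridian
            vf_os = vf_from_dict(doc)
            assert hemifield_abnormal(vf_od) == hemifield_abnormal(vf_os)
            assert anderson_patella(vf_od) == anderson_patella(vf_os)

    def test_json_round_trip(self):
        rng = np.random.default_rng(9)
        vf = random_vf(rng)
        back = vf_from_dict(vf_to_dict(vf))
        assert back.points == vf.points


def _oracle_clusters(vf):
    """Independent qualifying-cluster oracle via networkx components."""
    found = []
    for sign in (1, -1):
        nodes = [i for i, p in enumerate(vf.points)
                 if p.pd_category.significant and not p.is_blind_spot
                 and (p.y_deg > 0) == (sign > 0)]
        g = nx.Graph()
        g.add_nodes_from(nodes)
        for i in nodes:
            for j in nodes:
                if i < j:
                    a, b = vf.points[i], vf.points[j]
                    if (abs(a.x_deg - b.x_deg) <= GRID_STEP_DEG
                            and abs(a.y_deg - b.y_deg) <= GRID_STEP_DEG):
                        g.add_edge(i, j)
        for comp in nx.connected_components(g):
            non_edge = sum(1 for i in comp if not vf.points[i].is_edge)
            nasal = sum(1 for i in comp if vf.points[i].is_nasal_edge)
            has_lt1 = any(vf.points[i].pd_category >= PDCategory.LT1
                          for i in comp)
            if non_edge + min(2, nasal) >= 3 and has_lt1:
                found.append(frozenset(comp))
    return set(found)


def test_cluster_detection_matches_connected_components_oracle():
    rng = np.random.default_rng(12345)
    for _ in range(1000):
        vf = random_vf(rng, p_sig=float(rng.uniform(0.05, 0.5)))
        ours = {frozenset(c.member_indices)
                for c in find_qualifying_clusters(vf)}
        assert ours == _oracle_clusters(vf)


def test_deepening_a_point_never_removes_a_qualifying_cluster():
    rng = np.random.default_rng(99)
    for _ in range(200):
        vf = random_vf(rng, p_sig=0.2)
        before = [set((vf.points[i].x_deg, vf.points[i].y_deg)
                      for i in c.member_indices)
                  for c in find_qualifying_clusters(vf)]
        i = int(rng.integers(len(LAYOUT)))
        p = vf.points[i]
        if p.pd_category is PDCategory.LT0_5:
            continue
        cats = {(q.x_deg, q.y_deg): q.pd_category
                for q in vf.points if q.pd_category.significant}
        cats[(p.x_deg, p.y_deg)] = PDCategory(p.pd_category + 1)
        vf2 = make_vf(cats)
        after = [set((vf2.points[i].x_deg, vf2.points[i].y_deg)
                     for i in c.member_indices)
                 for c in find_qualifying_clusters(vf2)]
        for old in before:
            assert any(old <= new for new in after)
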