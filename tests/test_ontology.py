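import numpy as np
import pandas as pd
import pytest

from seazit.ontology import (
    GroupCall,
    OntologyMap,
    collapse_group,
    collapse_substance_calls,
    endpoint_to_recording,
    load_example_map,
    map_recording,
    mapping_stats,
    overlap,
    sankey_edges,
)
from seazit.specificity import SubstanceCall


def toy_map(rows):
    return OntologyMap(
        pd.DataFrame(
            rows,
            columns=[
                "lab",
                "recording",
                "ontology_id",
                "term_label",
                "granular_group",
                "general_group",
            ],
        )
    )


@pytest.fixture(scope="module")
def example_map():
    return load_example_map()


class TestMapRecording:
    def test_composite_recording_maps_to_two_terms(self, example_map):
        terms = map_recording("EDEM", example_map, lab="Lab-B")
        assert terms == ["heart edematous, abnormal", "yolk edematous, abnormal"]

    def test_yolk_opacity_term(self, example_map):
        assert map_recording("Yolk_opacity", example_map) == ["yolk opaque, abnormal"]
        row = example_map.table[example_map.table["recording"] == "Yolk_opacity"]
        assert row["ontology_id"].iloc[0] == "ZP:0002198"

    def test_unknown_recording_errors_by_name(self, example_map):
        with pytest.raises(KeyError, match="no_such_recording"):
            map_recording("no_such_recording", example_map)


class TestMappingStats:
    def test_one_to_one_mapping_averages_one(self):
        m = toy_map(
            [("L", f"r{i}", "", f"t{i}", "g", "G") for i in range(4)]
        )
        n_rec, n_terms, mean = mapping_stats(m, "L")
        assert (n_rec, n_terms) == (4, 4)
        assert mean == pytest.approx(1.0)

    def test_multi_term_ratio_exact(self):
        # 11 recordings carrying 19 distinct terms -> ratio 19/11
        rows = []
        t = 0
        for i in range(11):
            k = 2 if i < 8 else 1  # 8*2 + 3*1 = 19 terms
            for _ in range(k):
                rows.append(("L", f"r{i}", "", f"t{t}", "", ""))
                t += 1
        n_rec, n_terms, mean = mapping_stats(toy_map(rows), "L")
        assert (n_rec, n_terms) == (11, 19)
        assert mean == pytest.approx(19 / 11)
        assert round(mean, 2) == 1.73

    def test_empty_lab_warns(self, example_map):
        with pytest.warns(UserWarning):
            assert mapping_stats(example_map, "Lab-Z") == (0, 0, None)


class TestOverlap:
    def test_hand_counted_shared_terms(self):
        # 5 terms; t1 and t2 recorded by all 3 labs
        rows = []
        for lab in ("A", "B", "C"):
            rows.append((lab, f"{lab}_r1", "", "t1", "", ""))
            rows.append((lab, f"{lab}_r2", "", "t2", "", ""))
        rows += [("A", "A_r3", "", "t3", "", ""), ("B", "B_r4", "", "t4", "", ""),
                 ("C", "C_r5", "", "t5", "", "")]
        ov = overlap(toy_map(rows))
        assert ov.fully_shared("term") == 2

    def test_single_shared_term(self):
        rows = [("A", "a", "", "t1", "", ""), ("B", "b", "", "t1", "", "")]
        assert overlap(toy_map(rows)).fully_shared("term") == 1

    def test_disjoint_maps_share_nothing(self):
        rows = [("A", "a", "", "t1", "", ""), ("B", "b", "", "t2", "", "")]
        assert overlap(toy_map(rows)).fully_shared("term") == 0

    def test_invariant_to_lab_order_and_renaming(self):
        rows = [
            ("A", "a", "", "t1", "g1", "G1"),
            ("B", "b", "", "t1", "g1", "G1"),
            ("B", "c", "", "t2", "g2", "G2"),
        ]
        ov1 = overlap(toy_map(rows), labs=["A", "B"])
        ov2 = overlap(toy_map(rows), labs=["B", "A"])
        assert ov1.fully_shared("term") == ov2.fully_shared("term")
        renamed = [(l, r + "_x", o, t, g, G) for l, r, o, t, g, G in rows]
        assert overlap(toy_map(renamed)).fully_shared("term") == ov1.fully_shared("term")

    def test_example_map_fully_shared_groups(self, example_map):
        ov = overlap(example_map)
        # every general group in the fixture is recorded by all three labs
        # except yolk opacity-only additions
        assert ov.fully_shared("general") >= 4


def sc(sub, ep, cls, bmc, score=0.5):
    return SubstanceCall(
        substance_id=sub,
        endpoint=ep,
        cls=cls,
        bmc_summary=bmc,
        score_summary=score,
        n_plates=3,
    )


class TestCollapseGroup:
    def test_specific_wins_and_most_potent_bmc_breaks_tie(self):
        calls = [
            sc("S1", "a+Mort@120", "specific", -4.5),
            sc("S1", "b+Mort@120", "specific", -5.0),
            sc("S1", "c+Mort@120", "non-specific", -6.0),
        ]
        g = collapse_group(calls, "head defects")
        assert g.cls == "specific"
        assert g.bmc == pytest.approx(-5.0)

    def test_precedence_order(self):
        calls = [
            sc("S1", "a+Mort@120", "non-specific", -5.0),
            sc("S1", "b+Mort@120", "inconclusive", -6.0),
        ]
        assert collapse_group(calls, "g").cls == "non-specific"
        calls = [
            sc("S1", "a+Mort@120", "inconclusive", -5.0),
            sc("S1", "b+Mort@120", "non-toxic", None),
        ]
        assert collapse_group(calls, "g").cls == "inconclusive"

    def test_all_non_toxic(self):
        g = collapse_group([sc("S1", "a+Mort@120", "non-toxic", None, None)], "g")
        assert g.cls == "non-toxic" and g.bmc is None

    def test_idempotent(self):
        """Collapsing an already-collapsed group changes nothing."""
        calls = [
            sc("S1", "a+Mort@120", "specific", -4.5),
            sc("S1", "b+Mort@120", "non-specific", -6.0),
        ]
        g1 = collapse_group(calls, "g")
        again = collapse_group(
            [sc("S1", "a+Mort@120", g1.cls, g1.bmc, g1.score)], "g"
        )
        assert (again.cls, again.bmc) == (g1.cls, g1.bmc)

    def test_mixed_substances_rejected(self):
        with pytest.raises(ValueError):
            collapse_group(
                [sc("S1", "a", "specific", -4.0), sc("S2", "b", "specific", -4.0)],
                "g",
            )


class TestCollapseSubstanceCalls:
    MAP_ROWS = [
        ("L", "edema", "", "heart edematous, abnormal", "heart edema", "heart defects"),
        ("L", "edema", "", "yolk edematous, abnormal", "yolk edema", "yolk defects"),
        ("L", "axis", "", "axis curved, abnormal", "axis defects", "torso defects"),
        ("L", "dead", "", "whole organism dead, abnormal", "", ""),
    ]

    def test_endpoint_traced_through_hierarchy(self):
        calls = [
            sc("S1", "edema+Mort@120", "specific", -5.0),
            sc("S1", "axis+Mort@120", "non-specific", -4.0),
        ]
        out = collapse_substance_calls(calls, toy_map(self.MAP_ROWS), "L", "general")
        groups = {g.group: g for g in out}
        assert set(groups) == {"heart defects", "yolk defects", "torso defects"}
        assert groups["heart defects"].cls == "specific"
        assert groups["torso defects"].cls == "non-specific"

    def test_general_class_dominates_granular_members(self):
        """The general-level call never ranks below any granular call it
        covers (precedence can only improve when groups merge)."""
        calls = [
            sc("S1", "edema+Mort@120", "specific", -5.0),
            sc("S1", "axis+Mort@120", "non-specific", -4.0),
        ]
        m = toy_map(self.MAP_ROWS)
        gran = {g.group: g for g in collapse_substance_calls(calls, m, "L", "granular")}
        gen = {g.group: g for g in collapse_substance_calls(calls, m, "L", "general")}
        prec = {"specific": 0, "non-specific": 1, "inconclusive": 2, "non-toxic": 3}
        pairs = m.table[(m.table["granular_group"] != "")]
        for _, row in pairs.iterrows():
            if row["granular_group"] in gran and row["general_group"] in gen:
                assert (
                    prec[gen[row["general_group"]].cls]
                    <= prec[gran[row["granular_group"]].cls]
                )

    def test_terms_without_group_are_skipped(self):
        calls = [sc("S1", "dead+Mort@120", "specific", -5.0)]
        assert collapse_substance_calls(calls, toy_map(self.MAP_ROWS), "L") == []

    def test_endpoint_to_recording_strips_suffix(self):
        assert endpoint_to_recording("Presence_of_head_Edema+Mort@120") == (
            "Presence_of_head_Edema"
        )


class TestSankey:
    def test_single_recording_chain(self):
        m = toy_map([("L", "r1", "", "t1", "g1", "G1")])
        out = sankey_edges(m)
        kinds = [e["kind"] for e in out["edges"]]
        assert kinds == ["recording->term", "term->granular", "granular->general"]

    def test_term_lab_count_annotation(self, example_map):
        out = sankey_edges(example_map)
        node = out["nodes"]["heart edematous, abnormal"]
        assert node["n_labs"] == 3

    def test_ungrouped_terms_have_no_outgoing_group_edge(self, example_map):
        out = sankey_edges(example_map)
        sources = {e["source"] for e in out["edges"] if e["kind"] == "term->granular"}
        assert "whole organism dead, abnormal" not in sources

    def test_group_recording_counts(self):
        rows = [
            ("A", "r1", "", "t1", "g1", "G1"),
            ("B", "r2", "", "t1", "g1", "G1"),
            ("B", "r3", "", "t2", "g1", "G1"),
        ]
        out = sankey_edges(toy_map(rows))
        assert out["nodes"]["g1"]["n_recordings"] == 3


class TestMapValidation:
    def test_term_with_two_granular_groups_rejected(self):
        with pytest.raises(ValueError):
            toy_map(
                [
                    ("A", "r1", "", "t1", "g1", "G1"),
                    ("B", "r2", "", "t1", "g2", "G1"),
                ]
            )

    def test_granular_in_two_generals_rejected(self):
        with pytest.raises(ValueError):
            toy_map(
                [
                    ("A", "r1", "", "t1", "g1", "G1"),
                    ("B", "r2", "", "t2", "g1", "G2"),
                ]
            )
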