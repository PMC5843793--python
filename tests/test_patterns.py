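"""Pattern grammar, the built-in registry, and template instantiation."""

import pytest

from teocde import (
    CDERecord,
    VARIABLE,
    builtin_templates,
    instantiate,
    parse_pattern_string,
    pattern_frequency,
)
from teocde.cadsr import AnnotationCategory, AnnotationRecord
from teocde.errors import (
    BindingError,
    IncompleteBindingError,
    PatternSyntaxError,
    VocabularyError,
)
from teocde.patterns import required_slots, slot_paths
from teocde.teo import DATE_OF_CDE, Duration, TEOEvent, TimeInstant, TimeInterval


def generic_bindings(template):
    """Fill every static slot of a template with a plausible value."""
    values = {
        "label": "Sample Event Label",
        "relation": "before",
        "hasOrigTime": "06 APR 2017",
        "hasNormalizedTime": "2017-04-28",
        "hasDurationPattern": "7 days",
        "hasValue": 7,
        "hasUnit": "day",
        "hasGranularity": "day",
        "hasModality": "possible",
        "hasRepeatTime": 3,
    }
    return {path: values[path.rsplit(".", 1)[-1]] for path in required_slots(template)}


class TestParsePatternString:
    def test_nested_template(self):
        t = parse_pattern_string(
            "[Event (hasValidTime=[TimeInstant (hasGranularity, hasOrigTime*)])]"
        )
        (event,) = t.nodes
        assert event.cls == "Event" and not event.variable
        (valid_time,) = event.slots
        assert valid_time.name == "hasValidTime"
        instant = valid_time.child
        assert instant.cls == "TimeInstant"
        assert [(s.name, s.variable) for s in instant.slots] == [
            ("hasGranularity", False),
            ("hasOrigTime", True),
        ]

    def test_relation_sequence(self):
        t = parse_pattern_string("[Event*] [TemporalRelation] [Event]")
        assert [n.cls for n in t.nodes] == ["Event", "TemporalRelation", "Event"]
        assert [n.variable for n in t.nodes] == [True, False, False]

    def test_single_bare_node(self):
        t = parse_pattern_string("[Event]")
        assert len(t.nodes) == 1 and t.nodes[0].slots == ()

    @pytest.mark.parametrize(
        "bad",
        [
            "",
            "[Event",
            "[Event (hasValidTime=[TimeInstant)]",
            "[TemporalRelation]",
            "[Event] [TemporalRelation]",
        ],
    )
    def test_syntax_errors(self, bad):
        with pytest.raises(PatternSyntaxError):
            parse_pattern_string(bad)

    def test_unknown_class_rejected(self):
        with pytest.raises(PatternSyntaxError, match="Episode"):
            parse_pattern_string("[Episode]")

    def test_unknown_property_rejected(self):
        with pytest.raises(PatternSyntaxError, match="hasColour"):
            parse_pattern_string("[Event (hasColour)]")

    def test_property_class_compatibility_enforced(self):
        with pytest.raises(PatternSyntaxError):
            parse_pattern_string("[Duration (hasOrigTime)]")


class TestBuiltinRegistry:
    def test_ten_templates_in_rank_order(self, registry):
        assert list(registry) == [f"P{i}" for i in range(1, 11)]

    def test_rank4_source(self, registry):
        assert registry["P4"].source == "[Event*] [TemporalRelation] [Event]"

    def test_every_entry_reparses_canonically(self, registry):
        for template in registry.values():
            reparsed = parse_pattern_string(template.render())
            assert reparsed.nodes == template.nodes
            # canonical rendering is a fixed point
            assert parse_pattern_string(reparsed.render()).render() == template.render()


class TestInstantiate:
    def test_relation_pattern_structure(self, registry):
        cde = CDERecord(num=44077, public_id="44077",
                        long_name="Treatment Given Prior To Surgical Procedure Type")
        inst = instantiate(registry["P4"], cde, {
            "node1.event_type": "Treatment",
            "relation": "before",
            "node3.label": "Surgical Procedure Type",
        })
        e1, e2 = inst.graph.nodes
        assert e1.node_id == "event1" and e2.node_id == "event2"
        assert e1.event_type == "Treatment"
        assert e1.label is VARIABLE
        assert e2.label == "Surgical Procedure Type"
        (stmt,) = inst.graph.relations
        assert (stmt.subject, stmt.relation, stmt.object) == (e1, "before", e2)

    def test_date_pattern_with_variable_slots(self, registry):
        cde = CDERecord(num=1, public_id="4614514",
                        long_name="Stage IV disease progression date")
        inst = instantiate(registry["P1"], cde, {
            "node1.label": "Stage IV Disease Progression Platinum-Based Chemotherapy",
            "node1.hasValidTime.label": "Date",
            "node1.hasValidTime.hasGranularity": "*",
        })
        event, instant = inst.graph.nodes
        assert isinstance(event, TEOEvent) and isinstance(instant, TimeInstant)
        assert event.valid_time is instant
        assert instant.granularity is VARIABLE
        assert instant.orig_time is VARIABLE  # asterisked slot defaults

    def test_past_week_pattern_with_symbolic_reference(self, registry):
        cde = CDERecord(num=2, public_id="3191975",
                        long_name="Patient reported outcome past week score")
        inst = instantiate(registry["P2"], cde, {
            "node1.hasValidTime.hasEndTime.hasOrigTime": "date_of_CDE",
            "node1.hasValidTime.hasDuration.hasDurationPattern": "1 week",
        })
        event, interval, end, duration = inst.graph.nodes
        assert isinstance(interval, TimeInterval)
        assert interval.end is end and interval.duration is duration
        assert end.orig_time == DATE_OF_CDE
        assert duration.duration_pattern == "1 week"
        assert event.label is VARIABLE  # [Event*]

    def test_value_unit_duration_form(self, registry):
        inst = instantiate(registry["P8"], None, generic_bindings(registry["P8"]))
        duration = [n for n in inst.graph.nodes if isinstance(n, Duration)][0]
        assert duration.resolved_components() == ((7, __import__("teocde").Granularity.DAY),)

    def test_unknown_binding_path_rejected(self, registry):
        with pytest.raises(BindingError):
            instantiate(registry["P1"], None, {
                **generic_bindings(registry["P1"]), "node1.hasColour": "red"})

    def test_missing_static_slot_rejected(self, registry):
        with pytest.raises(IncompleteBindingError):
            instantiate(registry["P1"], None, {})

    def test_unknown_relation_name_rejected(self, registry):
        bindings = generic_bindings(registry["P4"])
        bindings["node2.relation"] = "nearby"
        with pytest.raises(VocabularyError):
            instantiate(registry["P4"], None, bindings)

    def test_template_not_mutated_and_instances_isomorphic(self, registry):
        from teocde import isomorphic

        for template in registry.values():
            before = template.nodes
            bindings = generic_bindings(template)
            a = instantiate(template, None, bindings)
            b = instantiate(template, None, bindings)
            assert template.nodes == before
            assert a.graph is not b.graph
            assert isomorphic(a, b)


class TestPatternFrequency:
    @staticmethod
    def records(annotator, counts):
        out = []
        i = 0
        for pattern_id, n in counts.items():
            for _ in range(n):
                out.append(AnnotationRecord(
                    str(i), annotator, AnnotationCategory.EXISTING_PATTERN, pattern_id))
                i += 1
        return out

    def test_single_annotator_single_pattern(self):
        table = pattern_frequency(self.records("A1", {"P1": 3}))
        assert table == [("P1", 3, 100.0)]

    def test_top_pattern_share(self):
        # 186 of 600 assignments -> 31.0%
        table = pattern_frequency(
            self.records("A1", {"P1": 186, "P2": 414})
        )
        (p1_row,) = [row for row in table if row[0] == "P1"]
        assert p1_row == ("P1", 186, 31.0)

    def test_counts_averaged_over_annotators(self):
        recs = self.records("A1", {"P1": 10}) + self.records("A2", {"P1": 12})
        table = pattern_frequency(recs)
        assert table[0][0] == "P1" and table[0][1] == 11

    def test_percentages_sum_to_100(self):
        table = pattern_frequency(
            self.records("A1", {"P1": 7, "P2": 5, "P3": 3, "P4": 2}))
        assert abs(sum(pct for _, _, pct in table) - 100.0) < 0.3

    def test_non_pattern_categories_excluded(self):
        recs = self.records("A1", {"P1": 2})
        recs.append(AnnotationRecord("x", "A1", AnnotationCategory.NOT_TIME_RELATED))
        assert pattern_frequency(recs) == [("P1", 2, 100.0)]


class TestSlotPaths:
    def test_static_vs_variable_partition(self, registry):
        paths = slot_paths(registry["P1"])
        assert paths["node1.label"] is True
        assert paths["node1.hasValidTime.hasGranularity"] is True
        assert paths["node1.hasValidTime.hasOrigTime"] is False

    def test_relation_slot_required(self, registry):
        assert "node2.relation" in required_slots(registry["P4"])
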