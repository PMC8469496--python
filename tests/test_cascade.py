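import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpdscreen.cascade import (
    CascadeClassifier,
    apply_rule,
    cascade_classify,
    composite_score,
    reactive_discriminant,
    subtype_flags,
)
from cpdscreen.cohort import CPDRecord
from cpdscreen.parameters import parse_parameter
from cpdscreen.rules import (
    REACTIVE_RULE,
    SUBTYPE_RULES,
    RulesRegistry,
    single_rule,
)

SDVNE = parse_parameter("SD-V-NE")
MNUMALSLY = parse_parameter("MN-UMALS-LY")
SDAL2MO = parse_parameter("SD-AL2-MO")
MNCNE = parse_parameter("MN-C-NE")
MNAL2NE = parse_parameter("MN-AL2-NE")


def make_record(sdvne, mnumalsly, sdal2mo, mncne, sample_id="s", **extra):
    values = {SDVNE: sdvne, MNUMALSLY: mnumalsly, SDAL2MO: sdal2mo, MNCNE: mncne}
    for name, v in extra.items():
        values[parse_parameter(name.replace("_", "-"))] = v
    return CPDRecord(sample_id, values)


class TestCompositeScore:
    def test_identity_inputs(self):
        assert composite_score(make_record(1, 1, 1, 1)) == 1.0

    def test_hand_arithmetic(self):
        # 25 * 70 * 20 / 140
        assert composite_score(make_record(25.0, 70.0, 20.0, 140.0)) == 250.0

    def test_score_250_is_neoplastic_at_published_cutoff(self):
        res = cascade_classify(make_record(25.0, 70.0, 20.0, 140.0, MN_AL2_NE=140.0))
        assert res.composite_score == 250.0
        assert res.stage1_label == "neoplastic"

    @settings(deadline=None, max_examples=200)
    @given(
        st.floats(0.01, 1e3), st.floats(0.01, 1e3),
        st.floats(0.01, 1e3), st.floats(0.01, 1e3),
        st.floats(0.01, 100),
    )
    def test_homogeneity_under_scaling(self, a, b, c, d, k):
        base = composite_score(make_record(a, b, c, d))
        assert composite_score(make_record(a * k, b, c, d)) == pytest.approx(k * base)
        assert composite_score(make_record(a, b, c, d * k)) == pytest.approx(base / k)


class TestApplyRule:
    def test_high_side_positive(self):
        rule = single_rule("SD-V-NE", 18.95, "high_is_positive",
                           "neoplastic", "non-neoplastic")
        label, entry = apply_rule(CPDRecord("s", {SDVNE: 20.0}), rule)
        assert label == "neoplastic"
        assert entry.score == 20.0 and entry.outcome == "neoplastic"

    def test_low_side_negative(self):
        rule = single_rule("MN-C-NE", 148.50, "low_is_positive",
                           "neoplastic", "non-neoplastic")
        label, _ = apply_rule(CPDRecord("s", {MNCNE: 150.0}), rule)
        assert label == "non-neoplastic"

    def test_boundary_is_negative(self):
        rule = single_rule("SD-V-NE", 18.95, "high_is_positive", "pos", "neg")
        label, _ = apply_rule(CPDRecord("s", {SDVNE: 18.95}), rule)
        assert label == "neg"


class TestReactiveDiscriminant:
    def test_boundary_negative_under_both_orientations(self):
        rec = CPDRecord("s", {MNAL2NE: 147.5})
        for orient in ("high_is_positive", "low_is_positive"):
            label, _ = reactive_discriminant(rec, REACTIVE_RULE.with_orientation(orient))
            assert label == "reactive"

    def test_low_orientation_sides(self):
        assert reactive_discriminant(CPDRecord("s", {MNAL2NE: 140.0}))[0] == "neoplastic"
        assert reactive_discriminant(CPDRecord("s", {MNAL2NE: 155.0}))[0] == "reactive"


class TestSubtypeFlags:
    def test_missing_input_yields_not_evaluated(self):
        rec = make_record(25, 70, 20, 140)  # none of the subtype params
        summary, per_rule, trail = subtype_flags(rec, SUBTYPE_RULES)
        assert summary == {"AML": None, "APL": None, "ALL": None, "CLL": None}
        assert all(v is None for v in per_rule.values())
        assert trail == []

    def test_all_seven_rules_emit_audit_entries(self):
        rec = make_record(
            25, 70, 20, 140,
            SD_MALS_NE=20.0, SD_UMALS_NE=20.0, MN_V_NE=165.0, SD_V_MO=40.0,
            MN_MALS_NE=140.0, MN_LMALS_NE=130.0, SD_C_MO=13.0,
        )
        summary, per_rule, trail = subtype_flags(rec, SUBTYPE_RULES)
        assert len(trail) == 7
        assert summary == {"AML": True, "APL": True, "ALL": True, "CLL": True}

    def test_boundary_rule_negative(self):
        rec = make_record(25, 70, 20, 140, SD_MALS_NE=15.81, SD_UMALS_NE=10.0)
        summary, per_rule, _ = subtype_flags(rec, SUBTYPE_RULES)
        assert per_rule["SD-MALS-NE"] is False
        assert summary["AML"] is False


class TestCascade:
    def test_stage1_negative_short_circuits(self):
        rec = make_record(10.0, 50.0, 10.0, 155.0, MN_AL2_NE=140.0)
        res = cascade_classify(rec)
        assert res.stage1_label == "non-neoplastic"
        assert res.stage2_label is None
        assert res.subtype_flags == {}
        assert [e.rule for e in res.audit_trail] == ["composite-neoplastic"]
        assert res.final_label == "non-neoplastic"

    def test_reactive_at_stage2_stops_before_flags(self):
        rec = make_record(25, 70, 20, 140, MN_AL2_NE=155.0, SD_MALS_NE=20.0)
        res = cascade_classify(rec)
        assert res.stage1_label == "neoplastic"
        assert res.stage2_label == "reactive"
        assert res.subtype_flags == {}
        assert res.final_label == "reactive"

    def test_neoplastic_path_raises_aml_flag(self):
        rec = make_record(25, 70, 20, 140, MN_AL2_NE=140.0, SD_MALS_NE=20.0)
        res = cascade_classify(rec)
        assert res.stage2_label == "neoplastic"
        assert res.subtype_flags["AML"] is True
        assert res.subtype_flags["APL"] is None  # inputs absent

    def test_determinism_bit_for_bit(self):
        rec = make_record(25, 70, 20, 140, MN_AL2_NE=140.0, SD_MALS_NE=20.0)
        a, b = cascade_classify(rec), cascade_classify(rec)
        assert a == b
        assert a.audit_trail == b.audit_trail

    def test_stage_errors_are_identified(self):
        rec = CPDRecord("s", {SDVNE: 20.0})
        with pytest.raises(ValueError, match="stage 1"):
            cascade_classify(rec)


class TestCascadeClassifier:
    def test_sklearn_api(self, paper_like_frame):
        clf = CascadeClassifier()
        assert "registry" in clf.get_params()
        clf.fit(paper_like_frame)
        assert clf.n_features_in_ == 4
        pred = clf.predict(paper_like_frame)
        assert set(pred) <= {"neoplastic", "non-neoplastic"}
        scores = clf.decision_function(paper_like_frame)
        reg = RulesRegistry()
        np.testing.assert_array_equal(
            pred == "neoplastic", scores > reg.composite.cutoff
        )

    def test_results_frame_consistent_with_classify(self, paper_like_frame):
        clf = CascadeClassifier().fit(paper_like_frame)
        sub = paper_like_frame.iloc[:25]
        frame = clf.results_frame(sub)
        results = clf.classify(sub)
        assert list(frame["final_label"]) == [r.final_label for r in results]
        # stage-2 / flags populated only for stage-1 positives
        for r in results:
            if r.stage1_label == "non-neoplastic":
                assert r.stage2_label is None and r.subtype_flags == {}

    def test_missing_columns_rejected(self, paper_like_frame):
        with pytest.raises(ValueError, match="missing required"):
            CascadeClassifier().fit(paper_like_frame[["SD-V-NE"]])
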