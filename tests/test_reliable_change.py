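import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_wide
from dualchange import reliable_change as rc
from dualchange import scales as sc
from dualchange.errors import ConfigError, DegenerateStatisticsError, InputError


def result(pid, outcome, value, threshold=1.96):
    return rc.RCIResult(
        participant_id=pid, outcome=outcome, pre_score=0.0, post_score=0.0,
        diff=0.0, se_diff=1.0, rci_value=value,
        classification=rc.classify_reliable(value, threshold),
    )


class TestSEDiff:
    def test_printed_formula_hand_value(self):
        assert rc.se_diff(10, 0.75).value == pytest.approx(5.0)

    def test_r_equal_one_degenerate(self):
        out = rc.se_diff(10, 1.0)
        assert out.value == 0.0 and out.degenerate

    def test_zero_sd_degenerate(self):
        assert rc.se_diff(0, 0).degenerate

    def test_r_above_one_rejected(self):
        with pytest.raises(InputError):
            rc.se_diff(10, 1.01)

    def test_baseline_variant(self):
        # sd_pre * sqrt(2 (1 - r))
        assert rc.se_diff_baseline(10, 0.5).value == pytest.approx(10.0)


class TestRCIScore:
    def test_no_change_is_zero(self):
        assert rc.rci_score(20, 20, 5, "lower_is_better") == 0.0

    def test_distress_improvement_positive(self):
        assert rc.rci_score(20, 10, 5, "lower_is_better") == pytest.approx(2.0)

    def test_wellbeing_improvement_positive(self):
        assert rc.rci_score(40, 50, 5, "higher_is_better") == pytest.approx(2.0)

    def test_degenerate_sediff_raises(self):
        with pytest.raises(DegenerateStatisticsError):
            rc.rci_score(20, 10, 0.0, "lower_is_better")

    @given(st.floats(-50, 50), st.floats(-50, 50), st.floats(0.1, 20))
    @settings(max_examples=60, deadline=None)
    def test_orientation_preserves_magnitude(self, pre, post, sediff):
        a = rc.rci_score(pre, post, sediff, "lower_is_better")
        b = rc.rci_score(pre, post, sediff, "higher_is_better")
        assert a == pytest.approx(-b)


class TestClassify:
    @pytest.mark.parametrize(
        "value,expected",
        [
            (1.96, rc.NO_RELIABLE_CHANGE),  # strict boundary
            (1.97, rc.RELIABLY_IMPROVED),
            (-1.96, rc.NO_RELIABLE_CHANGE),
            (-2.50, rc.RELIABLY_DETERIORATED),
            (0.0, rc.NO_RELIABLE_CHANGE),
        ],
    )
    def test_threshold_convention(self, value, expected):
        assert rc.classify_reliable(value) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(InputError):
            rc.classify_reliable(float("nan"))


class TestChangePattern:
    def test_both(self):
        results = [result("p", "overall_wellbeing", 2.5), result("p", "dass_depression", 2.5)]
        assert rc.change_pattern(results).pattern == "both"

    def test_wellbeing_only(self):
        results = [result("p", "life_satisfaction", 2.5), result("p", "dass_stress", 0.0)]
        assert rc.change_pattern(results).pattern == "wellbeing_only"

    def test_none(self):
        results = [result("p", "overall_wellbeing", 1.0)]
        assert rc.change_pattern(results).pattern == "none"

    def test_excluded_outcome_does_not_drive_pattern(self):
        results = [result("p", "resilience", 3.0), result("p", "dass_stress", 0.0)]
        assert rc.change_pattern(results).pattern == "none"

    def test_deterioration_is_not_improvement(self):
        results = [result("p", "dass_stress", -3.0)]
        assert rc.change_pattern(results).pattern == "none"

    def test_missing_grouping_entry_raises(self):
        with pytest.raises(ConfigError):
            rc.change_pattern([result("p", "overall_wellbeing", 0.0)], grouping={})

    def test_exhaustive_small_instances(self):
        # <=3 outcomes, enumerate all classifications against hand rule
        outcomes = ["overall_wellbeing", "dass_depression", "resilience"]
        for states in itertools.product([-3.0, 0.0, 3.0], repeat=3):
            results = [result("p", o, v) for o, v in zip(outcomes, states)]
            wb = states[0] > 1.96
            ds = states[1] > 1.96
            expected = {(True, True): "both", (True, False): "wellbeing_only",
                        (False, True): "distress_only", (False, False): "none"}[(wb, ds)]
            assert rc.change_pattern(results).pattern == expected


class TestPatternFrequencies:
    def make_patterns(self, both, wb, ds, none):
        pats = []
        spec = [("both", both, True, True), ("wellbeing_only", wb, True, False),
                ("distress_only", ds, False, True), ("none", none, False, False)]
        i = 0
        for name, count, w, d in spec:
            for _ in range(count):
                pats.append(rc.ChangePattern(f"p{i}", w, d, name))
                i += 1
        return pats

    def test_paper_counts_display(self):
        pats = self.make_patterns(42, 24, 17, 0)
        freq = rc.pattern_frequencies(pats)
        # counts printed against the paper's denominator of 82 give 51/29/20-21
        assert freq.counts["both"] == 42
        assert freq.improvement_denominator == 83
        assert round(100 * 42 / 82) == 51

    def test_all_none(self):
        freq = rc.pattern_frequencies(self.make_patterns(0, 0, 0, 5))
        assert freq.improvement_denominator == 0
        assert freq.percent_display["both"] == 0
        assert freq.fractions["none"] == 1.0

    def test_single_both_is_100(self):
        freq = rc.pattern_frequencies(self.make_patterns(1, 0, 0, 0))
        assert freq.percent_display["both"] == 100

    def test_counts_sum_to_participants(self):
        pats = self.make_patterns(3, 2, 4, 6)
        freq = rc.pattern_frequencies(pats)
        assert sum(freq.counts.values()) == freq.n_participants == 15

    def test_any_reliable_change_includes_deteriorations(self):
        pats = self.make_patterns(0, 0, 0, 2)
        results = [result("p0", "dass_stress", -2.5), result("p1", "dass_stress", 0.0)]
        freq = rc.pattern_frequencies(pats, results)
        assert freq.any_reliable_count == 1
        assert freq.any_reliable_percent_display == 50

    def test_empty_rejected(self):
        with pytest.raises(InputError):
            rc.pattern_frequencies([])


class TestSubgroups:
    def test_empty_subgroup_reports_zero_denominator(self):
        results = [result("p0", o, 3.0) for o in sc.OUTCOMES]
        flags = {"p0": {f"dass_{t}": False for t in ("depression", "anxiety", "stress")}}
        out = rc.subgroup_pattern_frequencies(results, flags, "depression")
        assert out.denominator == 0
        assert all(v == 0 for v in out.counts.values())

    def test_all_flagged_improved_both(self):
        results = []
        flags = {}
        for i in range(4):
            pid = f"p{i}"
            results += [result(pid, "overall_wellbeing", 2.5),
                        result(pid, "dass_anxiety", 2.5)]
            flags[pid] = {"dass_depression": False, "dass_anxiety": True,
                          "dass_stress": False}
        out = rc.subgroup_pattern_frequencies(results, flags, "anxiety")
        assert out.denominator == 4
        assert out.percent_display["both"] == 100

    def test_unknown_distress_type(self):
        with pytest.raises(ConfigError):
            rc.subgroup_pattern_frequencies([], {}, "anger")

    def test_restriction_excludes_other_subscales(self):
        # improvement on stress only must not count as distress improvement
        # in the depression subgroup breakdown
        results = [result("p0", "dass_stress", 2.5),
                   result("p0", "dass_depression", 0.0),
                   result("p0", "overall_wellbeing", 0.0)]
        flags = {"p0": {"dass_depression": True, "dass_anxiety": False,
                        "dass_stress": False}}
        out = rc.subgroup_pattern_frequencies(results, flags, "depression")
        assert out.denominator == 1  # improved somewhere, met threshold
        assert out.counts["none"] == 1  # but not on depression or well-being

    def test_brute_force_recount_on_synthetic_cohort(self, default_cohort_wide):
        tables = rc.compute_reliable_change(default_cohort_wide)
        flags = {}
        defs = sc.outcome_scales()
        for _, row in default_cohort_wide.iterrows():
            flags[row["participant_id"]] = {
                o: sc.severity_category(
                    min(max(row[f"pre_{o}"], defs[o].score_min), defs[o].score_max),
                    defs[o],
                )
                in defs[o].problematic_labels
                for o in sc.OUTCOMES
            }
        for dt in ("depression", "anxiety", "stress"):
            out = rc.subgroup_pattern_frequencies(tables.results, flags, dt)
            # independent per-participant recount
            target = f"dass_{dt}"
            by_pid = {}
            for r in tables.results:
                by_pid.setdefault(r.participant_id, {})[r.outcome] = r
            denom = 0
            counts = {p: 0 for p in rc.PATTERNS}
            for pid, rs in by_pid.items():
                if not flags[pid][target]:
                    continue
                if not any(x.classification == rc.RELIABLY_IMPROVED for x in rs.values()):
                    continue
                denom += 1
                wb = any(
                    rs[o].classification == rc.RELIABLY_IMPROVED
                    for o in ("overall_wellbeing", "life_satisfaction")
                )
                ds = rs[target].classification == rc.RELIABLY_IMPROVED
                key = {(True, True): "both", (True, False): "wellbeing_only",
                       (False, True): "distress_only", (False, False): "none"}[(wb, ds)]
                counts[key] += 1
            assert out.denominator == denom
            assert dict(out.counts) == counts


class TestComputeReliableChange:
    def test_null_calibration_rate(self):
        # zero true change, zero pre/post correlation: realized SEdiff is the
        # difference-score SD, so ~2.5% improve / ~5% change in each direction
        from conftest import null_config
        from dualchange.synthetic import generate_cohort
        from dualchange.pipeline import wide_from_long

        rates_imp, rates_any = [], []
        for seed in range(40):
            wide = wide_from_long(generate_cohort(null_config(n=250, seed=seed)).data)
            t = rc.compute_reliable_change(wide)
            cls = t.rci["classification"]
            rates_imp.append((cls == rc.RELIABLY_IMPROVED).mean())
            rates_any.append((cls != rc.NO_RELIABLE_CHANGE).mean())
        assert np.mean(rates_imp) == pytest.approx(0.025, abs=0.006)
        assert np.mean(rates_any) == pytest.approx(0.05, abs=0.01)

    def test_orientation_invariance(self, default_cohort_wide):
        # negating a lower_is_better outcome and flipping its direction
        # leaves all classifications unchanged
        flipped = default_cohort_wide.copy()
        flipped["pre_dass_stress"] = -flipped["pre_dass_stress"]
        flipped["post_dass_stress"] = -flipped["post_dass_stress"]
        directions = dict(sc.OUTCOME_DIRECTIONS)
        directions["dass_stress"] = "higher_is_better"
        a = rc.compute_reliable_change(default_cohort_wide)
        b = rc.compute_reliable_change(flipped, directions=directions)
        assert (a.rci["classification"] == b.rci["classification"]).all()
        assert np.allclose(a.rci["rci_value"], b.rci["rci_value"])

    def test_variant_labelled(self, default_cohort_wide):
        t = rc.compute_reliable_change(default_cohort_wide, variant="baseline")
        assert t.variant == "baseline"

    def test_degenerate_outcome_skipped(self):
        pre = {o: [1.0, 2.0, 3.0] for o in sc.OUTCOMES}
        post = {o: [2.0, 4.0, 3.0] for o in sc.OUTCOMES}  # varying diffs
        post["dass_stress"] = pre["dass_stress"]  # identical: sd_diff = 0
        wide = make_wide(pre, post)
        t = rc.compute_reliable_change(wide)
        assert "dass_stress" in t.degenerate_outcomes
        assert "dass_stress" not in set(t.rci["outcome"])
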