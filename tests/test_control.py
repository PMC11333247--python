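"""Single-indicator control scenarios and priority ranking."""

import numpy as np
import pytest

from epirisk.control import (
    apply_control,
    control_stage,
    evaluate_scenario,
    rank_controls,
    safety_score,
    scenario_table,
)
from epirisk.errors import InputDomainError
from epirisk.markov import StateDistribution, steady_state
from epirisk.membership import IndicatorAssessment, StageAssessment, membership_vector
from epirisk.transition import build_stm


def _a(ident, p_min, p_max, l_min=2, l_max=3):
    return IndicatorAssessment(ident, p_min, p_max, l_min, l_max)


class TestApplyControl:
    @pytest.mark.parametrize(
        "before,after",
        [((3, 4), (2, 3)), ((1, 3), (1, 2)), ((1, 1), (1, 1))],
    )
    def test_probability_decrement_with_floor(self, before, after):
        out = apply_control(_a("x", *before))
        assert (out.p_min, out.p_max) == after

    def test_loss_levels_untouched_by_default(self):
        out = apply_control(_a("x", 3, 4, 2, 5))
        assert (out.l_min, out.l_max) == (2, 5)

    def test_explicit_loss_decrement_option(self):
        out = apply_control(_a("x", 3, 4, 2, 5), decrement_loss=True)
        assert (out.l_min, out.l_max) == (1, 4)

    def test_never_increases_and_idempotent_at_floor(self):
        for p_min in range(1, 6):
            for p_max in range(p_min, 6):
                a = _a("x", p_min, p_max)
                out = apply_control(a)
                assert out.p_min <= a.p_min and out.p_max <= a.p_max
                assert out.p_min <= out.p_max
        floor = _a("x", 1, 1)
        assert apply_control(apply_control(floor)) == apply_control(floor) == floor

    def test_negative_decrement_rejected(self):
        with pytest.raises(InputDomainError, match=">= 0"):
            apply_control(_a("x", 2, 3), levels=-1)


class TestSafetyScore:
    def test_published_baseline_value(self):
        d = StateDistribution((0.142, 0.546, 0.219, 0.093))
        assert safety_score(d) == pytest.approx(0.688)

    def test_extremes(self):
        assert safety_score(StateDistribution((1.0, 0.0, 0.0, 0.0))) == 1.0
        assert safety_score(StateDistribution((0.0, 0.0, 0.0, 1.0))) == 0.0

    def test_n_safe_bounds_checked(self):
        with pytest.raises(InputDomainError):
            safety_score(StateDistribution.uniform(4), n_safe=5)


class TestEvaluateScenario:
    def test_baseline_equals_plain_pipeline(self, matrix, stages):
        r = evaluate_scenario(stages["t1"], None, matrix)
        direct = steady_state(build_stm(stages["t1"], matrix))
        assert r.stable_state.probs == direct.distribution.probs
        assert r.safety_score == pytest.approx(0.389, abs=1.1e-3)

    def test_published_a3_scenario(self, matrix, stages):
        r = evaluate_scenario(stages["t1"], "a3", matrix)
        assert r.stable_state.rounded(3)[0] == pytest.approx(0.085)

    def test_published_a2_scenario(self, matrix, stages):
        r = evaluate_scenario(stages["t1"], "a2", matrix)
        assert r.safety_score == pytest.approx(0.429, abs=1.1e-3)
        assert r.effective

    def test_unknown_indicator_rejected(self, matrix, stages):
        with pytest.raises(InputDomainError, match="a42"):
            evaluate_scenario(stages["t1"], "a42", matrix)

    def test_floor_bound_control_is_bitwise_noop(self, matrix):
        # both probability bounds already at the floor: stable state identical
        stage = StageAssessment(
            "s",
            (
                IndicatorAssessment("a1", 1, 1, 4, 5),
                IndicatorAssessment("a2", 2, 4, 1, 3),
            ),
        )
        base = evaluate_scenario(stage, None, matrix)
        ctrl = evaluate_scenario(stage, "a1", matrix)
        assert ctrl.stable_state.probs == base.stable_state.probs
        assert not ctrl.effective

    def test_t2_a5_control_leaves_membership_unchanged(self, matrix, stages):
        # (P 5..5, L 4..4) -> (4..4, 4..4): both cells are outbreak-state cells
        a5 = stages["t2"].get("a5")
        before = membership_vector(a5, matrix)
        after = membership_vector(apply_control(a5), matrix)
        assert before.mu.tolist() == after.mu.tolist() == [0, 0, 0, 1]


class TestRankControls:
    def test_published_effective_set_t1(self, matrix, stages):
        results = rank_controls(stages["t1"], matrix)
        effective = {r.controlled_indicator for r in results if r.effective}
        assert effective == {"a2", "a3", "a8", "a9"}

    def test_published_t1_table(self, matrix, stages, goldens):
        results = {
            r.controlled_indicator: r for r in rank_controls(stages["t1"], matrix)
        }
        for cid, expected in goldens["control_t1"].items():
            r = results[cid]
            assert np.allclose(
                r.stable_state.probs, expected["stable_state"], atol=1.1e-3
            ), cid
            assert r.safety_score == pytest.approx(expected["safety"], abs=1.1e-3)

    def test_top_ranked_t1_are_tied_a2_a8(self, matrix, stages):
        ranked = [r for r in rank_controls(stages["t1"], matrix) if r.rank]
        assert {ranked[0].controlled_indicator, ranked[1].controlled_indicator} == {
            "a2",
            "a8",
        }
        # tie broken by input order
        assert ranked[0].controlled_indicator == "a2"
        assert ranked[0].safety_score == pytest.approx(ranked[1].safety_score)

    def test_ranks_are_contiguous_and_descending(self, matrix, stages):
        ranked = [r for r in rank_controls(stages["t0"], matrix) if r.rank]
        assert [r.rank for r in ranked] == list(range(1, 10))
        scores = [r.safety_score for r in ranked]
        assert scores == sorted(scores, reverse=True)

    def test_all_floor_stage_has_no_effective_control(self, matrix):
        stage = StageAssessment(
            "floor",
            tuple(
                IndicatorAssessment(f"a{i}", 1, 1, i, i + 1) for i in range(1, 5)
            ),
        )
        results = rank_controls(stage, matrix)
        assert not any(r.effective for r in results)

    def test_multi_indicator_control_generalization(self, matrix, stages):
        double = control_stage(stages["t1"], ["a2", "a8"])
        assert double.get("a2").p_min == 2 and double.get("a8").p_max == 3
        single = control_stage(stages["t1"], [])
        assert single is stages["t1"]

    def test_scenario_table_layout(self, matrix, stages):
        frame = scenario_table(rank_controls(stages["t1"], matrix))
        assert list(frame.columns) == [
            "controlled_indicator",
            "P(S1)",
            "P(S2)",
            "P(S3)",
            "P(S4)",
            "safety_score",
            "effective",
            "rank",
        ]
        assert len(frame) == 10  # 9 scenarios + baseline
        assert (frame["controlled_indicator"] == "none").sum() == 1
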