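"""Invariance ladder, decision rules and the latent-mean effect size f."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from gbb8.invariance import (DELTA_CFI_THRESHOLD, LadderResult, LadderStep,
                             effect_size_f, evaluate_invariance,
                             invariance_ladder, latent_mean_equivalence)
from gbb8.simulate import GeneratorConfig, generate_dataset

TWO_GROUP = {"group_sizes": {"a": 600, "b": 600}, "group_var": "sex",
             "missing_rate": 0.0, "covariate_spec": (), "extra_labels": {}}


class TestEffectSize:
    def test_equal_means_give_zero(self):
        es = effect_size_f([0.3, 0.3, 0.3], [100, 200, 50], 1.0)
        assert es.f == 0.0
        assert es.r_squared == 0.0

    def test_two_group_hand_example(self):
        es = effect_size_f([0.0, 0.2], [300, 300], 1.0)
        assert es.f == pytest.approx(0.10, abs=1e-12)
        assert es.d == pytest.approx(0.20, abs=1e-12)

    def test_three_group_hand_example(self):
        es = effect_size_f([0.0, 0.1, 0.2], [100, 200, 100], 1.0)
        assert es.alpha_bar == pytest.approx(0.1)
        assert es.f == pytest.approx(np.sqrt(0.01 / 2), abs=1e-12)
        assert es.f == pytest.approx(0.0707, abs=1e-4)

    @given(st.floats(-2, 2), st.floats(-2, 2), st.integers(10, 1000),
           st.integers(10, 1000), st.floats(0.2, 3.0))
    def test_two_group_closed_form_identity(self, a1, a2, n1, n2, psi):
        # f = |a1-a2| sqrt(n1 n2) / (N psi) for every two-group input
        es = effect_size_f([a1, a2], [n1, n2], psi)
        closed = abs(a1 - a2) * np.sqrt(n1 * n2) / ((n1 + n2) * psi)
        assert es.f == pytest.approx(closed, abs=1e-10)

    @given(st.floats(-1, 1), st.floats(-1, 1), st.floats(-1, 1),
           st.floats(-3, 3), st.floats(0.3, 3.0))
    def test_shift_invariance_and_psi_scaling(self, a1, a2, a3, c, s):
        ns = [50, 80, 120]
        base = effect_size_f([a1, a2, a3], ns, 1.0)
        shifted = effect_size_f([a1 + c, a2 + c, a3 + c], ns, 1.0)
        scaled = effect_size_f([a1, a2, a3], ns, s)
        assert shifted.f == pytest.approx(base.f, abs=1e-9)
        assert scaled.f == pytest.approx(base.f / s, rel=1e-9, abs=1e-12)

    def test_d_only_defined_for_two_groups(self):
        with pytest.raises(ValueError):
            _ = effect_size_f([0, 0.1, 0.2], [10, 10, 10], 1.0).d

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            effect_size_f([0.0, 0.1], [10, 10], 0.0)
        with pytest.raises(ValueError):
            effect_size_f([0.0], [10], 1.0)


class TestDecisionRule:
    def _ladder(self, deltas):
        steps = [LadderStep(level="configural", results=None, indices=None)]
        for lv, (dc, dr) in zip(("weak1", "weak2"), deltas):
            steps.append(LadderStep(level=lv, results=None, indices=None,
                                    dcfi=dc, drmsea=dr))
        return LadderResult(grouping="g", groups=("a", "b"), steps=steps)

    def test_small_changes_pass(self):
        lad = evaluate_invariance(self._ladder([(0.003, 0.003)]))
        assert lad.steps[1].decision == "pass"

    def test_boundary_is_a_fail(self):
        # the rule is strictly "smaller than": 0.010 exactly fails
        lad = evaluate_invariance(self._ladder([(0.010, 0.0)]))
        assert lad.steps[1].decision == "fail"

    def test_conjunction_of_both_thresholds(self):
        lad = evaluate_invariance(self._ladder([(0.004, 0.020)]))
        assert lad.steps[1].decision == "fail"

    def test_configural_has_no_decision(self):
        lad = evaluate_invariance(self._ladder([(0.001, 0.001)]))
        assert lad.steps[0].decision == "n/a"

    def test_highest_level_stops_at_first_failure(self):
        lad = evaluate_invariance(self._ladder([(0.02, 0.02), (0.001, 0.001)]))
        assert lad.highest_level == "configural"


class TestLadderOnData:
    def test_df_sequence_and_monotone_chi2(self):
        data = generate_dataset(GeneratorConfig(seed=21, **TWO_GROUP))
        lad = invariance_ladder(data, "sex")
        assert lad.df_sequence == (32, 36, 39, 43, 46, 54, 58, 59)
        chi2 = [s.results.chi2 for s in lad.steps]
        assert all(b >= a - 1e-6 for a, b in zip(chi2, chi2[1:]))
        for s in lad.steps[1:]:
            assert 0 <= s.pvalue <= 1

    def test_four_group_configural_df(self):
        cfg = GeneratorConfig(group_sizes={c: 250 for c in "abcd"},
                              group_var="sex", missing_rate=0.0,
                              covariate_spec=(), extra_labels={}, seed=22)
        lad = invariance_ladder(generate_dataset(cfg), "sex",
                                levels=("configural", "weak1"))
        assert lad.steps[0].results.df == 64

    def test_mean_equivalence_ddf_is_groups_minus_one(self):
        data = generate_dataset(GeneratorConfig(seed=23, **TWO_GROUP))
        lad = invariance_ladder(data, "sex")
        assert lad.step("means").ddf == 1
        cfg = GeneratorConfig(group_sizes={c: 300 for c in "abcd"},
                              group_var="sex", missing_rate=0.0,
                              covariate_spec=(), extra_labels={}, seed=24)
        lad4 = invariance_ladder(generate_dataset(cfg), "sex")
        assert lad4.step("means").ddf == 3

    def test_invariant_data_passes_ladder(self):
        data = generate_dataset(GeneratorConfig(seed=25, **TWO_GROUP))
        lad = invariance_ladder(data, "sex")
        assert all(s.decision == "pass" for s in lad.steps[1:])

    def test_injected_loading_shift_fails_weak_step(self):
        # one loading lowered by 0.3 in one group: the metric step should
        # trip the change-in-fit decision rule
        fails = 0
        for seed in range(3):
            cfg = GeneratorConfig(
                noninvariance={"b": {"loadings": {"exhausted": 0.58}}},
                seed=400 + seed, **TWO_GROUP)
            lad = invariance_ladder(generate_dataset(cfg), "sex",
                                    levels=("configural", "weak1"))
            fails += lad.step("weak1").decision == "fail"
        assert fails >= 2

    def test_warm_and_cold_starts_agree(self):
        # constraint-path independence: each step refit from cold starts
        data = generate_dataset(GeneratorConfig(seed=26, **TWO_GROUP))
        warm = invariance_ladder(data, "sex", levels=("configural", "weak1",
                                                      "weak2", "strong1"))
        cold = invariance_ladder(data, "sex", levels=("configural", "weak1",
                                                      "weak2", "strong1"),
                                 warm_start=False)
        for a, b in zip(warm.steps, cold.steps):
            assert a.results.llf == pytest.approx(b.results.llf,
                                                  abs=1e-4 * abs(b.results.llf) ** 0)


class TestLatentMeans:
    def test_shift_detected_and_effect_size_direction(self, complete_two_group):
        test, es = latent_mean_equivalence(complete_two_group, "grp",
                                           require_strict=False)
        assert test.ddf == 1
        assert test.pvalue < 0.01
        assert es.alphas[1] > 0.25  # group b was shifted upward
        assert es.d > 0.3

    def test_null_shift_not_rejected_typically(self):
        data = generate_dataset(GeneratorConfig(seed=27, **TWO_GROUP))
        test, es = latent_mean_equivalence(data, "sex", require_strict=False)
        assert es.f < 0.15
        assert 0 <= test.pvalue <= 1
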