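"""Threshold procedures, session structure, detection statistics."""

import numpy as np
import pytest

from mupulse.behavior import (DeterministicObserver, LogisticObserver,
                              absolute_threshold, detection_stats,
                              staircase_50, target_intensities,
                              validate_catch_trials)
from mupulse.behavior_sim import (DESIGNS, detection_probability,
                                  simulate_behavior_session)
from mupulse.params import SubjectParams


class TestAbsoluteThreshold:
    def test_hard_threshold_hand_simulation(self):
        obs = DeterministicObserver(2.05)
        thr, sub = absolute_threshold(obs, i_start=1.0, step=0.1)
        assert thr == pytest.approx(2.1)
        assert sub == pytest.approx(1.785)

    def test_invalid_step_rejected(self):
        with pytest.raises(ValueError):
            absolute_threshold(DeterministicObserver(2.0), 1.0, step=0.0)

    def test_never_detecting_observer_errors(self):
        with pytest.raises(RuntimeError):
            absolute_threshold(lambda i: False, 1.0, max_steps=20)

    def test_stochastic_estimate_near_majority_point(self):
        """Mean estimate lands within one step of the majority-detection
        point of the logistic observer."""
        estimates = []
        for rep in range(300):
            obs = LogisticObserver(2.0, 8.0, seed=rep)
            thr, _ = absolute_threshold(obs, i_start=1.0, step=0.1)
            estimates.append(thr)
        assert abs(np.mean(estimates) - 2.0) <= 0.1


class TestStaircase:
    def test_deterministic_observer_converges(self):
        obs = DeterministicObserver(2.0)
        est = staircase_50(obs, i_start=1.0, step_initial=0.4,
                           n_reversals=8)
        assert abs(est - 2.0) <= 0.4 / 2**3

    def test_logistic_observer_mean_near_50_percent_point(self):
        ests = [staircase_50(LogisticObserver(2.0, 8.0, seed=r), 1.0, 0.4)
                for r in range(200)]
        assert abs(np.mean(ests) - 2.0) / 2.0 <= 0.05

    def test_zero_reversals_rejected(self):
        with pytest.raises(ValueError):
            staircase_50(DeterministicObserver(2.0), 1.0, 0.4,
                         n_reversals=0)

    def test_nonconvergence_reported(self):
        # alternating observer never accumulates enough reversals only if
        # capped; use a tiny trial cap to force the failure path
        with pytest.raises(RuntimeError, match="reversals"):
            staircase_50(DeterministicObserver(2.0), 1.0, 0.4,
                         n_reversals=8, max_trials=3)


class TestTargetIntensities:
    def test_default_band_around_two_ma(self):
        np.testing.assert_allclose(target_intensities(2.0),
                                   [1.8, 1.9, 2.0, 2.1, 2.2])

    def test_degenerate_band_warns(self):
        with pytest.warns(UserWarning):
            levels = target_intensities(2.0, band=(1.0, 1.0))
        assert np.allclose(levels, 2.0)

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            target_intensities(0.0)


class TestSessionStructure:
    def test_block_composition(self):
        s = simulate_behavior_session("A2", SubjectParams(), n_blocks=3,
                                      seed=1)
        for b in range(3):
            blk = s.block == b
            assert int((blk & s.is_catch).sum()) == 16
            for lvl in range(1, 6):
                sel = blk & (s.level == lvl)
                assert int(sel.sum()) == 32
                assert int((sel & (s.condition == "paired")).sum()) == 16
        # catch trials carry the subthreshold intensity only
        assert np.allclose(s.intensity[s.is_catch], s.sub_intensity)
        # paired trials all share the design delay
        paired = s.condition == "paired"
        assert set(s.delay_ms[paired]) == {DESIGNS["A2"][1]}

    def test_control_only_design(self):
        s = simulate_behavior_session("control_only", SubjectParams(),
                                      n_blocks=1, seed=0)
        assert int((~s.is_catch).sum()) == 160
        assert int(s.is_catch.sum()) == 16
        assert int((s.condition == "paired").sum()) == 0

    def test_saturated_intensities_all_detected(self):
        # target levels far above the observer's threshold
        p = SubjectParams(psychometric_threshold=0.1,
                          psychometric_slope=50.0)
        s = simulate_behavior_session("A2", p, n_blocks=1, seed=2,
                                      threshold_50=2.0)
        assert s.response[~s.is_catch].all()

    def test_unknown_design_rejected(self):
        with pytest.raises(ValueError, match="design"):
            simulate_behavior_session("C9", SubjectParams(), 1, 0)

    def test_determinism(self):
        a = simulate_behavior_session("B1", SubjectParams(), 2, seed=7)
        b = simulate_behavior_session("B1", SubjectParams(), 2, seed=7)
        assert np.array_equal(a.response, b.response)
        assert np.array_equal(a.intensity, b.intensity)

    def test_psychometric_calibration_at_threshold(self):
        """Detection rate at I = threshold converges to 0.5."""
        p = SubjectParams()
        rng = np.random.default_rng(0)
        n = 10_000
        resp = rng.random(n) < detection_probability(
            np.full(n, p.psychometric_threshold), p)
        assert resp.mean() == pytest.approx(0.5, abs=0.02)

    def test_tsv_roundtrip_columns(self, tmp_path):
        s = simulate_behavior_session("A1", SubjectParams(), 1, seed=3)
        path = tmp_path / "session.tsv"
        s.to_tsv(path)
        import pandas as pd
        df = pd.read_csv(path, sep="\t")
        assert list(df.columns) == ["block", "trial", "intensity_mA",
                                    "condition", "delay_ms", "is_catch",
                                    "response", "rt_s"]
        assert len(df) == len(s)


class TestCatchValidation:
    def _session_with_catch_responses(self, per_block):
        s = simulate_behavior_session("A2", SubjectParams(), len(per_block),
                                      seed=4)
        s.response[s.is_catch] = False
        for b, n in enumerate(per_block):
            idx = np.flatnonzero((s.block == b) & s.is_catch)[:n]
            s.response[idx] = True
        return s

    def test_zero_or_one_response_is_valid(self):
        s = self._session_with_catch_responses([0, 1])
        v = validate_catch_trials(s)
        assert v["per_block"][0]["valid"] and v["per_block"][1]["valid"]

    def test_two_responses_flag_the_block(self):
        s = self._session_with_catch_responses([0, 2])
        v = validate_catch_trials(s)
        assert v["per_block"][0]["valid"]
        assert not v["per_block"][1]["valid"]
        assert v["valid_blocks"] == [0]

    def test_all_blocks_flagged_excludes_subject(self):
        s = self._session_with_catch_responses([3, 2])
        v = validate_catch_trials(s)
        assert not v["subject_valid"]

    def test_missing_catch_trials_rejected(self):
        s = self._session_with_catch_responses([0])
        s.is_catch[:] = False
        with pytest.raises(ValueError):
            validate_catch_trials(s)


class TestDetectionStats:
    def _cohort(self, design, shift, n_subjects, seed):
        p = SubjectParams(effect_shift=shift)
        return [simulate_behavior_session(design, p, 3,
                                          seed=seed * 1000 + s)
                for s in range(n_subjects)]

    def test_equal_rates_give_zero_change_and_t0(self):
        sessions = self._cohort("A2", {}, 4, seed=1)
        for s in sessions:
            s.response[:] = False
            s.response[s.level >= 3] = True  # deterministic by intensity
        st = detection_stats(sessions)
        assert st.mean_relative_change == 0.0
        assert st.t == 0.0

    def test_relative_change_formula(self):
        # rates 0.639 (paired) vs 0.600 (control) -> +6.5 % relative
        assert ((0.639 - 0.600) / 0.600) == pytest.approx(0.065, abs=1e-3)
        sessions = self._cohort("A2", {"single_60ms": 0.2}, 6, seed=2)
        st = detection_stats(sessions)
        manual = np.mean((st.rate_paired - st.rate_control)
                        / st.rate_control)
        assert st.mean_relative_change == pytest.approx(manual)

    def test_injected_effect_recovered_in_mean(self):
        rels = []
        for c in range(60):
            st = detection_stats(self._cohort(
                "A2", {"single_60ms": 0.065}, 21, seed=c))
            rels.append(st.mean_relative_change)
        assert np.mean(rels) == pytest.approx(0.065, abs=0.01)

    def test_fewer_than_two_subjects_rejected(self):
        with pytest.raises(ValueError):
            detection_stats(self._cohort("A2", {}, 1, seed=3))
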