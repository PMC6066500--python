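"""Synthetic cohort generator: mixing model, tracking family, ground truth."""

import numpy as np
import pytest

from eegtrack.behavior import success_rate
from eegtrack.coherence import coherence_table
from eegtrack.preprocess import epoch_and_detrend
from eegtrack.simulate import (
    DEFAULT_ARTIFACT_AMPLITUDES,
    HIGH_BETA,
    SimulationConfig,
    analytic_band_coherence,
    expected_band_coherence,
    gamma_for_coherence,
    generate_cohort,
    generate_subject_eeg,
    generate_tracking_session,
    roi_weight_pattern,
)


class TestAnalyticCoherence:
    def test_single_pair_equal_band_power_gives_one_quarter(self):
        # flat per-bin check of the closed form: S = N at every in-band bin
        # gives (1/(1+1))^2 = 1/4 for unit weights
        from eegtrack.simulate import _pair_band_coherence

        s = np.full(11, 3.3)
        n = np.full(11, 3.3)
        val = _pair_band_coherence(np.ones(1), np.ones(1), s, n)
        assert val == pytest.approx(0.25, abs=1e-14)

    def test_zero_coupling_gives_zero(self):
        assert analytic_band_coherence(0.0) == 0.0

    def test_strictly_increasing_in_gamma(self):
        grid = np.linspace(0.0, 1.0, 21)
        vals = [analytic_band_coherence(g) for g in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(0.0 <= v <= 1.0 for v in vals)

    def test_gamma_inversion_round_trip(self):
        for target in (0.1, 0.25, 0.5, 0.8):
            g = gamma_for_coherence(target)
            assert analytic_band_coherence(g) == pytest.approx(target, abs=1e-9)
        with pytest.raises(ValueError, match="maximum"):
            gamma_for_coherence(0.95)

    def test_windowed_expectation_below_plain_value(self):
        # band-edge leakage dilutes the edge bins
        for g in (0.2, 0.5, 0.9):
            plain = analytic_band_coherence(g)
            windowed = expected_band_coherence(g, duration_s=60.0)
            assert 0.85 * plain < windowed < plain

    def test_weight_patterns_are_zero_sum(self):
        for n in (2, 6, 7, 21):
            w = roi_weight_pattern(n)
            assert w.sum() == pytest.approx(0.0, abs=1e-12)
            assert np.all(w != 0)


class TestSubjectEeg:
    CFG = SimulationConfig(rng_seed=0, n_rings=3, duration_s=20.0)

    def test_seeded_determinism(self, hex3, rois3):
        a, _ = generate_subject_eeg(self.CFG, 0.4, hex3, rois3, np.random.default_rng(5))
        b, _ = generate_subject_eeg(self.CFG, 0.4, hex3, rois3, np.random.default_rng(5))
        np.testing.assert_array_equal(a.data, b.data)

    def test_gamma_bounds_enforced(self, hex3, rois3):
        with pytest.raises(ValueError):
            generate_subject_eeg(self.CFG, 1.2, hex3, rois3, np.random.default_rng(0))

    def test_estimated_coherence_matches_ground_truth(self, hex3, rois3):
        cfg = SimulationConfig(rng_seed=0, n_rings=3, duration_s=60.0)
        g = gamma_for_coherence(0.5, n_seed=7, n_par=6)
        rec, truth = generate_subject_eeg(cfg, g, hex3, rois3, np.random.default_rng(3))
        ep = epoch_and_detrend(rec)
        est = coherence_table(ep, rois3, {"high_beta": HIGH_BETA}).value(("iM1", "iPAR"), "high_beta")
        assert est == pytest.approx(truth.coherence_expected, abs=0.04)

    def test_artifact_ground_truth_recorded(self, hex3, rois3):
        cfg = SimulationConfig(
            rng_seed=0, n_rings=3, duration_s=10.0,
            artifact_amplitudes=DEFAULT_ARTIFACT_AMPLITUDES,
        )
        rec, truth = generate_subject_eeg(cfg, 0.3, hex3, rois3, np.random.default_rng(1))
        assert set(truth.artifact_topographies) == {
            "blink", "eye_movement", "muscle", "cardiac", "spike",
        }
        sig = truth.artifact_signal()
        assert sig.shape == rec.data.shape
        kinds = {t.kind for t in truth.templates()}
        assert kinds == {"blink", "eye_movement", "cardiac"}


class TestTrackingFamily:
    def test_seeded_determinism(self):
        a = generate_tracking_session(400.0, 1.5, 10.0, np.random.default_rng(4))
        b = generate_tracking_session(400.0, 1.5, 10.0, np.random.default_rng(4))
        np.testing.assert_array_equal(a.cursor_xy, b.cursor_xy)

    def test_sr_monotone_in_skill(self):
        srs = [
            success_rate(generate_tracking_session(650.0, s, 60.0, np.random.default_rng(9)))
            for s in (0.5, 1.0, 1.5, 2.0, 3.0, 5.0)
        ]
        assert all(b >= a - 1.0 for a, b in zip(srs, srs[1:]))  # noisy but monotone
        assert srs[-1] >= srs[0] + 30

    def test_extreme_skill_is_perfect_pursuit(self):
        tr = generate_tracking_session(400.0, 30.0, 10.0, np.random.default_rng(0))
        assert success_rate(tr) == 100.0

    def test_invalid_arguments_error(self):
        with pytest.raises(ValueError):
            generate_tracking_session(-5.0, 1.0, 10.0, np.random.default_rng(0))
        with pytest.raises(ValueError):
            generate_tracking_session(100.0, 1.0, 0.0, np.random.default_rng(0))


def fast_cfg(**kw):
    base = dict(
        rng_seed=11, n_subjects=5, n_rings=4, duration_s=10.0,
        run_duration_s=20.0, calib_round_s=10.0, n_runs=1,
    )
    base.update(kw)
    return SimulationConfig(**base)


class TestCohort:
    def test_noiseless_link_is_rank_perfect(self):
        cohort = generate_cohort(fast_cfg(link_noise_sd=0.0), with_eeg=False, with_lesions=False)
        df = cohort.truth_frame().sort_values("gamma")
        assert df.delta_true.is_monotonic_increasing

    def test_null_cohort_has_flat_link(self):
        cohort = generate_cohort(
            fast_cfg(link_slope=0.0, link_noise_sd=0.0), with_eeg=False, with_lesions=False
        )
        df = cohort.truth_frame()
        assert df.delta_true.nunique() == 1

    def test_seeded_cohort_regenerates_identically(self):
        a = generate_cohort(fast_cfg(), with_lesions=False)
        b = generate_cohort(fast_cfg(), with_lesions=False)
        for sa, sb in zip(a.subjects, b.subjects):
            np.testing.assert_array_equal(sa.recording.data, sb.recording.data)
            np.testing.assert_array_equal(sa.pre_traces[0].cursor_xy, sb.pre_traces[0].cursor_xy)
            assert sa.truth.delta_true == sb.truth.delta_true

    def test_adding_a_subject_preserves_existing_streams(self):
        small = generate_cohort(fast_cfg(n_subjects=4), with_lesions=False)
        big = generate_cohort(fast_cfg(n_subjects=5), with_lesions=False)
        for sa, sb in zip(small.subjects, big.subjects):
            assert sa.truth.gamma == sb.truth.gamma
            np.testing.assert_array_equal(sa.recording.data, sb.recording.data)

    def test_infeasible_gains_are_clipped_and_flagged(self):
        cohort = generate_cohort(
            fast_cfg(link_intercept=500.0), with_eeg=False, with_lesions=False
        )
        df = cohort.truth_frame()
        assert df.delta_clipped.all()
        assert (df.sr_post_target <= 99.5 + 1e-9).all()

    def test_lesion_assignment_counts(self):
        cohort = generate_cohort(fast_cfg(n_lesioned=2), with_eeg=False)
        df = cohort.truth_frame()
        assert df.lesion_critical.sum() == 2
        assert cohort.roi_masks is not None
        flagged = [s for s in cohort.subjects if s.truth.lesion_critical]
        from eegtrack.lesion import injury_profile

        for sub in flagged:
            prof = injury_profile(sub.subject_id, sub.lesion, cohort.roi_masks)
            assert prof.excluded

    def test_minimum_cohort_size_enforced(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_subjects=2)

    def test_achieved_sr_gain_tracks_requested_link(self):
        cohort = generate_cohort(
            fast_cfg(n_subjects=6, run_duration_s=60.0, n_runs=3, link_noise_sd=0.0),
            with_eeg=False, with_lesions=False,
        )
        for sub in cohort.subjects:
            if sub.truth.delta_clipped:
                continue
            sr_pre = np.mean([success_rate(t) for t in sub.pre_traces])
            sr_post = np.mean([success_rate(t) for t in sub.post_traces])
            achieved = 100.0 * (sr_post - sr_pre) / sr_pre
            assert achieved == pytest.approx(sub.truth.delta_true, abs=6.0)
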