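"""Synthetic cohort generator: trajectories, waveforms, readings, features."""

import numpy as np
import pandas as pd
import pytest

from cuffless_bp import beats as bt
from cuffless_bp import synthetic as syn

from conftest import make_params


class TestTrajectory:
    def test_rest_only_zero_noise_is_exactly_baseline(self):
        params = make_params(amp=(0.0, 0.0, 0.0))
        protocol = syn.ProtocolSpec(
            sessions=(syn.SessionSpec("handgrip", 120.0),)
        )
        (tr,) = syn.simulate_bp_trajectory(params, protocol)
        assert np.all(tr.sbp == 120.0)
        assert np.all(tr.dbp == 80.0)
        np.testing.assert_allclose(tr.hr, 60.0, atol=1e-6)

    def test_seeded_runs_are_bit_identical(self):
        params = make_params(noise_sd=3.0, hr_noise_sd=1.5, seed=42)
        protocol = syn.default_protocol()
        a = syn.simulate_bp_trajectory(params, protocol)
        b = syn.simulate_bp_trajectory(params, protocol)
        for x, y in zip(a, b):
            np.testing.assert_array_equal(x.sbp, y.sbp)
            np.testing.assert_array_equal(x.t_start, y.t_start)

    def test_zero_duration_session_rejected(self):
        with pytest.raises(ValueError):
            syn.SessionSpec("handgrip", 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_map_strictly_between_dbp_and_sbp(self, seed):
        params = make_params(noise_sd=4.0, hr_noise_sd=2.0, seed=seed)
        for tr in syn.simulate_bp_trajectory(params, syn.default_protocol()):
            assert np.all(tr.dbp < tr.map)
            assert np.all(tr.map < tr.sbp)

    def test_handgrip_median_change_matches_calibration_target(self):
        """Cohort median within-subject SBP change for the handgrip session
        should land near 25.5 mmHg, the laboratory value the generator's
        response amplitudes are calibrated to."""
        cohort = syn.simulate_cohort(n_subjects=38, seed=1)
        changes = []
        for subj in cohort:
            sess = next(
                s for s in subj.sessions
                if s.activity == "handgrip" and s.day == 1
            )
            seg = bt.aggregate_segments(sess.truth, sess.spec.total_duration)
            changes.append(seg["sbp"].max() - seg["sbp"].min())
        med = float(np.median(changes))
        assert med == pytest.approx(25.5, abs=5.0)

    def test_median_change_monotone_in_amplitudes(self):
        def med_change(scale):
            cohort = syn.simulate_cohort(
                n_subjects=10, seed=3, amplitude_scale=scale
            )
            out = []
            for subj in cohort:
                sess = subj.sessions[0]
                seg = bt.aggregate_segments(
                    sess.truth, sess.spec.total_duration
                )
                out.append(seg["sbp"].max() - seg["sbp"].min())
            return float(np.median(out))

        assert med_change(1.5) > med_change(1.0) > med_change(0.5)


class TestWaveform:
    def test_single_beat_hits_sbp_and_dbp_exactly(self):
        beats = bt.BeatSeries([0.0], [1.0], [120.0], [80.0],
                              [80 + syn.MAP_FRACTION * 40], [60.0])
        rec = syn.simulate_waveform(beats, 125.0)
        assert rec.pressure.max() == pytest.approx(120.0, abs=1e-12)
        assert rec.pressure.min() == pytest.approx(80.0, abs=1e-12)

    def test_map_equals_trapezoid_oracle(self, clean_waveform):
        rec = clean_waveform
        windows = bt.segment_cycles(rec)
        dt = 1.0 / rec.fs
        for s, e in windows[:25]:
            cyc = rec.pressure[s:e]
            oracle = np.trapezoid(cyc, dx=dt) / ((cyc.size - 1) * dt)
            m = bt.compute_beat_bp(cyc, rec.fs)
            assert m.map == pytest.approx(oracle, abs=1e-12)

    def test_beat_extrema_invariant_to_sampling_rate(self, clean_truth):
        lo = syn.simulate_waveform(clean_truth, 500.0)
        hi = syn.simulate_waveform(clean_truth, 1000.0)
        b_lo = bt.process_record(lo)
        b_hi = bt.process_record(hi)
        assert np.abs(b_lo.sbp - b_hi.sbp).max() < 0.5
        assert np.abs(b_lo.dbp - b_hi.dbp).max() < 0.5

    def test_sampling_rate_floor_enforced(self, clean_truth):
        with pytest.raises(ValueError):
            syn.simulate_waveform(clean_truth, 50.0)


class TestBrachial:
    def test_noiseless_constant_truth_reproduces_baseline(self, clean_truth):
        tr = clean_truth  # rest window is constant 120/80 (zero noise)
        trip = syn.simulate_brachial_readings(tr, (0.0, 240.0), noise_sd=0.0)
        np.testing.assert_allclose(trip.sbp, 120.0, atol=1e-9)
        np.testing.assert_allclose(trip.dbp, 80.0, atol=1e-9)

    def test_readings_at_60s_spacing(self, clean_truth):
        trip = syn.simulate_brachial_readings(clean_truth, (0.0, 240.0))
        np.testing.assert_allclose(np.diff(trip.times), 60.0)

    def test_short_rest_window_rejected(self, clean_truth):
        with pytest.raises(ValueError):
            syn.simulate_brachial_readings(clean_truth, (0.0, 120.0))

    def test_seeded_noise_reproducible(self, clean_truth):
        a = syn.simulate_brachial_readings(
            clean_truth, rng=np.random.default_rng(7)
        )
        b = syn.simulate_brachial_readings(
            clean_truth, rng=np.random.default_rng(7)
        )
        np.testing.assert_array_equal(a.sbp, b.sbp)


class TestFeatures:
    def test_identity_coefficients_recover_segment_mean_sbp(self, clean_truth):
        coeffs = np.array([[1.0, 0.0, 0.0, 0.0]])
        feats = syn.simulate_ppg_features(
            clean_truth, 420.0, coeffs=coeffs, noise_sd=0.0
        )
        seg = bt.aggregate_segments(clean_truth, 420.0)
        np.testing.assert_allclose(
            feats["f1"].to_numpy(), seg["sbp"].to_numpy(), atol=1e-9
        )

    def test_dimension_mismatch_rejected(self, clean_truth):
        with pytest.raises(ValueError):
            syn.simulate_ppg_features(
                clean_truth, 420.0, coeffs=np.ones((3, 3))
            )
        with pytest.raises(ValueError):
            syn.simulate_ppg_features(
                clean_truth, 420.0, coeffs=np.ones((2, 4)),
                intercepts=np.zeros(3),
            )

    def test_fixed_seed_reproducible(self, clean_truth):
        a = syn.simulate_ppg_features(
            clean_truth, 420.0, noise_sd=0.1,
            rng=np.random.default_rng(3),
        )
        b = syn.simulate_ppg_features(
            clean_truth, 420.0, noise_sd=0.1,
            rng=np.random.default_rng(3),
        )
        pd.testing.assert_frame_equal(a, b)


class TestCohort:
    def test_default_day2_subset(self):
        cohort = syn.simulate_cohort(n_subjects=38, seed=0, sampling_rate=125)
        assert len(cohort) == 38
        assert sum(s.has_day2 for s in cohort) == 11
        days = {s.day for subj in cohort for s in subj.sessions}
        assert days == {1, 2}

    def test_single_subject_cohort(self):
        cohort = syn.simulate_cohort(n_subjects=1, seed=5)
        assert len(cohort) == 1
        assert {s.activity for s in cohort[0].sessions} == set(syn.ACTIVITIES)

    def test_zero_error_model_features_reflect_truth(self):
        cohort = syn.simulate_cohort(
            n_subjects=1, seed=2, error_model=syn.DeviceErrorModel.zero(),
            beat_noise_sd=0.0, hr_noise_sd=0.0, brachial_noise_sd=0.0,
            session_offset_sd=0.0,
        )
        sess = cohort[0].sessions[0]
        assert np.all(sess.device_error[["sbp", "dbp", "map"]].to_numpy() == 0)
        # segment_hr feature is the exact segment-mean HR in the zero-noise limit
        seg = bt.aggregate_segments(sess.truth, sess.spec.total_duration)
        np.testing.assert_allclose(
            sess.features["segment_hr"].to_numpy(), seg["hr"].to_numpy(),
            atol=1e-9,
        )


class TestArtifacts:
    def test_zero_fraction_is_identity(self, clean_waveform):
        out = syn.inject_artifacts(clean_waveform, 0.0)
        np.testing.assert_array_equal(out.pressure, clean_waveform.pressure)
        assert not out.artifact_truth.any()

    def test_ground_truth_positions_recorded(self, clean_waveform):
        out = syn.inject_artifacts(clean_waveform, 0.2, seed=1)
        frac = out.artifact_truth.mean()
        assert 0.18 <= frac <= 0.25
        changed = out.pressure != clean_waveform.pressure
        assert np.all(out.artifact_truth[changed])

    def test_masking_monotone_under_further_injection(self, clean_waveform):
        once = syn.inject_artifacts(clean_waveform, 0.15, seed=2)
        twice = syn.inject_artifacts(once, 0.35, seed=3)
        m1 = bt.filter_artifacts(once)
        m2 = bt.filter_artifacts(twice)
        assert np.all(m2[m1])  # nothing previously masked becomes unmasked
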