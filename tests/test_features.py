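import numpy as np
import pytest

from snatchlab import SubjectInfo, process_trial
from snatchlab.features import (
    EventDetectionError,
    PhaseEvents,
    classify_path,
    detect_catch,
    detect_start,
    detect_takeoff,
    horizontal_extremes,
    subject_adherence,
)
from snatchlab.simulate import TrialParams, generate_trial


class TestDetectStart:
    def test_first_sustained_crossing(self):
        # fs=50 Hz, 40 ms sustain window = 2 samples
        vvel = np.array([0.0, 0.005, 0.02, 0.5, 1.0, 1.2, 1.0])
        assert detect_start(vvel, fs=50.0) == 2

    def test_all_zero_velocity_raises(self):
        with pytest.raises(EventDetectionError, match="no movement"):
            detect_start(np.zeros(100), fs=250.0)

    def test_single_sample_spike_rejected(self):
        vvel = np.zeros(60)
        vvel[10] = 0.5                      # isolated noise spike
        vvel[30:] = np.linspace(0.02, 1.0, 30)  # real, sustained onset
        assert detect_start(vvel, fs=50.0) == 30


class TestDetectCatch:
    def test_catch_at_first_nonnegative_after_descent(self):
        vpos = np.array([0.0, 0.5, 1.0, 0.8, 0.6, 0.6, 0.6])
        vvel = np.array([0.5, 0.5, 0.1, -0.3, -0.2, 0.0, 0.0])
        ymax, catch = detect_catch(vpos, vvel, start_idx=0)
        assert ymax == 2
        assert catch == 5

    def test_monotone_rise_has_no_catch(self):
        vpos = np.linspace(0, 1, 50)
        vvel = np.full(50, 0.5)
        with pytest.raises(EventDetectionError, match="no descent"):
            detect_catch(vpos, vvel, start_idx=0)

    def test_generator_catch_time_within_two_samples(self, noiseless_trial):
        _, _, truth, signals, events, _ = noiseless_trial
        assert abs(events.catch_idx - truth.catch_time * signals.f_kin) <= 2


class TestDetectTakeoff:
    def test_sustained_drop_found_at_first_sample(self):
        vgrf = np.ones(300)
        vgrf[120:160] = 0.01   # 40 ms below threshold at 1000 Hz
        assert detect_takeoff(vgrf, fs=1000.0) == 120

    def test_no_flight_returns_none(self):
        assert detect_takeoff(np.full(500, 0.9), fs=1000.0) is None

    def test_generator_flight_onset_within_5_ms(self, noiseless_trial):
        _, _, truth, signals, events, _ = noiseless_trial
        assert events.takeoff_idx is not None
        err = events.takeoff_idx / signals.f_force - truth.takeoff_time
        assert abs(err) < 0.005


class TestHorizontalExtremes:
    def _path(self, x1, x2, x3, n=400):
        """Piecewise-linear AP path 0 -> x1 -> x2 -> x3 (m), landmarks interior."""
        a = np.concatenate([
            np.zeros(40),
            np.linspace(0.0, x1, 80),
            np.linspace(x1, x2, 120)[1:],
            np.linspace(x2, x3, 120)[1:],
            np.full(42, x3),
        ])
        return a

    def test_published_dl_means_recovered_from_constructed_path(self):
        ap = self._path(0.0031, -0.1693, 0.0919)
        start, ymax, catch = 20, 180, 357
        _, _, x1, x2, x3 = horizontal_extremes(ap, start, ymax, catch)
        assert x1 == pytest.approx(0.31, abs=1e-9)
        assert x2 == pytest.approx(-16.93, abs=1e-9)
        assert x3 == pytest.approx(9.19, abs=1e-9)

    def test_flat_path_gives_zeros(self):
        ap = np.zeros(400)
        _, _, x1, x2, x3 = horizontal_extremes(ap, 20, 180, 357)
        assert (x1, x2, x3) == (0.0, 0.0, 0.0)

    def test_mirror_symmetry(self):
        ap = self._path(0.0031, -0.1693, 0.0919)
        r, f, x1, x2, x3 = horizontal_extremes(ap, 20, 180, 357)
        r2, f2, m1, m2, m3 = horizontal_extremes(-ap, 20, 180, 357)
        assert (r2, f2) == (r, f)
        np.testing.assert_allclose([m1, m2, m3], [-x1, -x2, -x3], atol=1e-9)

    def test_mirror_symmetry_on_generated_trial(self, noiseless_trial):
        p, raw, truth, _, _, feats = noiseless_trial
        mirrored_left = raw.marker_left * [-1.0, 1.0, 1.0]
        mirrored_right = raw.marker_right * [-1.0, 1.0, 1.0]
        from snatchlab.io import RawTrial

        raw_m = RawTrial(raw.subject_id, raw.condition, raw.trial_index,
                         mirrored_left, mirrored_right, raw.f_kin,
                         raw.plate1, raw.plate2, raw.f_force)
        _, _, fm = process_trial(raw_m, SubjectInfo("S01", p.body_height,
                                                    p.body_mass))
        assert fm.x1 == pytest.approx(-feats.x1, abs=1e-9)
        assert fm.x2 == pytest.approx(-feats.x2, abs=1e-9)
        assert fm.x3_dxt == pytest.approx(-feats.x3_dxt, abs=1e-9)

    def test_negative_x1_recovered_via_recovery_point(self):
        p = TrialParams(x1=-0.88, noise_sd_pos=0.0, noise_sd_force=0.0, seed=3)
        raw, truth = generate_trial(p)
        _, _, feats = process_trial(raw, SubjectInfo("S01", p.body_height,
                                                     p.body_mass))
        assert feats.x1 == pytest.approx(-0.88, abs=0.5)
        assert feats.x1 < 0


class TestFeatureValues:
    def test_identities_hold_exactly(self, noisy_trial):
        *_, feats = noisy_trial
        assert feats.vtr == pytest.approx(feats.y_max - feats.y_catch, abs=1e-12)
        assert feats.dxv == pytest.approx(feats.x1 - feats.x2, abs=1e-12)
        assert feats.dxl == pytest.approx(feats.x3_dxt - feats.x2, abs=1e-12)
        assert feats.mvt_duration > 0

    def test_event_ordering_invariant(self, noisy_trial):
        _, _, _, _, events, _ = noisy_trial
        assert events.start_idx < events.ymax_idx < events.catch_idx
        assert events.start_idx <= events.rearmost_idx <= events.ymax_idx
        assert events.rearmost_idx <= events.foremost_idx <= events.catch_idx

    def test_event_ordering_holds_over_200_noise_seeds(self):
        """start < ymax < catch (with rearmost/foremost between) on every
        synthetic trial across a 200-seed sensor-noise sweep."""
        p0 = TrialParams()
        sub = SubjectInfo("S01", p0.body_height, p0.body_mass)
        from dataclasses import replace

        for seed in range(200):
            raw, _ = generate_trial(replace(p0, seed=seed))
            _, events, _ = process_trial(raw, sub)
            assert events.start_idx < events.ymax_idx < events.catch_idx
            assert events.start_idx <= events.rearmost_idx <= events.ymax_idx
            assert events.rearmost_idx <= events.foremost_idx <= events.catch_idx

    def test_phase_events_reject_bad_ordering(self):
        with pytest.raises(ValueError, match="order"):
            PhaseEvents(start_idx=10, rearmost_idx=12, ymax_idx=8,
                        foremost_idx=14, catch_idx=20)

    def test_vgrf_max_recovers_programmed_peak(self, noiseless_trial):
        _, _, truth, _, _, feats = noiseless_trial
        assert feats.vgrf_max == pytest.approx(truth.vgrf_max_bw, rel=0.02)

    def test_rfd_definition_on_synthetic_step(self):
        """A 0.01 BW step between consecutive 1000 Hz samples is 10 BW/s."""
        from snatchlab.preprocess import TrialSignals

        vgrf = np.ones(3000)
        vgrf[1500:] = 1.01
        n_kin = 750
        sig = TrialSignals(
            subject_id="S", condition="DL", trial_index=1,
            barbell_pos=np.zeros((n_kin, 2)), barbell_vel=np.zeros((n_kin, 2)),
            barbell_acc=np.zeros((n_kin, 2)), f_kin=250.0,
            vgrf_total=vgrf * 700.0, vgrf_bw=vgrf,
            rfd=np.diff(vgrf) / 0.001, vvel_force=np.zeros(3000),
            power=np.zeros(3000), f_force=1000.0,
            body_weight=700.0, body_height=1.78,
        )
        assert sig.rfd[1499] == pytest.approx(10.0)
        assert sig.rfd[100] == 0.0
        assert np.count_nonzero(sig.rfd) == 1

    def test_no_flight_flags_jump_windows(self):
        p = TrialParams(flight=False, noise_sd_pos=0.0, noise_sd_force=0.0)
        raw, _ = generate_trial(p)
        _, events, feats = process_trial(
            raw, SubjectInfo("S01", p.body_height, p.body_mass))
        assert events.takeoff_idx is None
        assert feats.jump_window_is_whole_movement
        assert feats.vgrf_mean_jump == pytest.approx(feats.vgrf_mean_all)


class TestClassification:
    def test_published_means_classify_as_reported(self):
        dl = classify_path(0.31, -16.93, 9.19)
        rl = classify_path(-0.88, -16.32, 10.5)
        assert dl.is_optimal
        assert not rl.is_optimal
        assert rl.sign_pattern[0] == -1  # X1 is the failing leg

    def test_exactly_one_of_eight_sign_patterns_is_optimal(self):
        patterns = [(sx * 1.0, sy * 1.0, sz * 1.0)
                    for sx in (1, -1) for sy in (1, -1) for sz in (1, -1)]
        optimal = [p for p in patterns if classify_path(*p).is_optimal]
        assert optimal == [(1.0, -1.0, 1.0)]

    def test_zero_displacement_is_not_optimal(self):
        assert not classify_path(0.0, -16.0, 9.0).is_optimal

    def test_subject_adherence_requires_all_three(self):
        opt = classify_path(1.0, -1.0, 1.0)
        non = classify_path(-1.0, -1.0, 1.0)
        assert subject_adherence([opt, opt, opt])
        assert not subject_adherence([opt, non, opt])
        with pytest.raises(ValueError):
            subject_adherence([])
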