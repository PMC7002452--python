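"""Trial segmentation and the response statistic: oracles and identities."""

import numpy as np
import pytest

from phimage import BASELINE_PH, SensorGeometry
from phimage import synth
from phimage.calibration import convert_voltage_to_ph, fit_standard_curves
from phimage.response import (
    ResponseMaps,
    TrialMatrix,
    TruncatedTrialError,
    compute_response_maps,
    compute_trial_responses,
    segment_trials,
)


def _ph_movie(geometry, protocol, truth, condition="hepes", seed=0):
    movie = synth.generate_recording(geometry, protocol, truth, condition, seed=seed)
    calset, _ = synth.generate_calibration_set(geometry=geometry, seed=seed + 1)
    return convert_voltage_to_ph(movie, fit_standard_curves(calset))


@pytest.fixture
def constant_ph_movie(small_geometry, tiny_protocol):
    truth = synth.make_ground_truth(small_geometry, angles_deg=(0.0, 90.0))
    return _ph_movie(small_geometry, tiny_protocol, truth)


class TestSegmentTrials:
    def test_constant_movie_means(self, constant_ph_movie, tiny_protocol):
        tm = segment_trials(constant_ph_movie, tiny_protocol)
        np.testing.assert_allclose(tm.ph_stim, BASELINE_PH, atol=1e-5)
        np.testing.assert_allclose(tm.ph_interval_trial, BASELINE_PH, atol=1e-5)

    def test_frame_counts_per_window(self):
        geom = SensorGeometry(n_rows=4, n_cols=4, frame_rate_hz=50.0)
        protocol = synth.generate_protocol(
            pre_phase_s=2.0, stim_s=2.0, interval_s=8.0, n_trials_per_angle=2, angles_deg=(0.0,), seed=0
        )
        truth = synth.make_ground_truth(geom, angles_deg=(0.0,))
        tm = segment_trials(_ph_movie(geom, protocol, truth), protocol)
        assert np.all(tm.n_frames_used[:, 0] == 100)  # 2 s stim at 50 Hz
        assert np.all(tm.n_frames_used[:, 1] == 400)  # 8 s interval

    def test_stim_mean_matches_analytic_time_average(self, small_geometry):
        # single trial, single responsive pixel, noise-free
        protocol = synth.generate_protocol(
            pre_phase_s=4.0, stim_s=2.0, interval_s=8.0, n_trials_per_angle=1, angles_deg=(0.0,), seed=0
        )
        field = np.zeros(small_geometry.shape + (1,))
        field[5, 5, 0] = 0.02
        truth = synth.make_ground_truth(small_geometry, response_field=field, angles_deg=(0.0,))
        tm = segment_trials(
            _ph_movie(small_geometry, protocol, truth, condition="brain"), protocol
        )
        kin = truth.alkaline_kinetics
        T, f = 2.0, kin.frac_fast
        # (1/T) * integral_0^T k(t) dt, each component integrating to
        # 1 - (tau/T) * (1 - exp(-T/tau))
        mean_k = f * (1 - kin.tau_fast_s / T * (1 - np.exp(-T / kin.tau_fast_s))) + (
            1 - f
        ) * (1 - kin.tau_slow_s / T * (1 - np.exp(-T / kin.tau_slow_s)))
        expected = BASELINE_PH + 0.02 * mean_k
        assert tm.ph_stim[5, 5, 0] == pytest.approx(expected, abs=2e-4)

    def test_truncated_trial_raises_and_can_be_dropped(self, small_geometry, tiny_protocol):
        truth = synth.make_ground_truth(small_geometry, angles_deg=(0.0, 90.0))
        movie = synth.generate_recording(
            small_geometry, tiny_protocol, truth, "hepes", seed=0
        )
        # chop the last interval off
        cut = int(24.0 * small_geometry.frame_rate_hz)
        movie.frames = movie.frames[:cut]
        movie.timestamps = movie.timestamps[:cut]
        calset, _ = synth.generate_calibration_set(geometry=small_geometry, seed=1)
        ph = convert_voltage_to_ph(movie, fit_standard_curves(calset))
        with pytest.raises(TruncatedTrialError) as exc:
            segment_trials(ph, tiny_protocol)
        assert 3 in exc.value.trial_indices
        tm = segment_trials(ph, tiny_protocol, allow_truncated=True)
        assert tm.n_trials == 3


def _hand_matrix():
    """1-pixel, 2-angle (0/90), 2-trial toy with hand-chosen window means."""
    stim = np.array([7.50, 7.46, 7.44, 7.40]).reshape(1, 1, 4)
    interval = np.array([7.40, 7.44, 7.38, 7.42]).reshape(1, 1, 4)
    return TrialMatrix(
        ph_stim=stim,
        ph_interval_trial=interval,
        trial_angles=np.array([0.0, 90.0, 0.0, 90.0]),
        angles_deg=np.array([0.0, 90.0]),
        n_frames_used=np.full((4, 2), 10),
    )


class TestResponseMaps:
    def test_hand_spreadsheet_oracle(self):
        # worked by hand: pH_int_0 = 7.39, pH_int_90 = 7.43, pH_interval = 7.41
        # dpH_trial = [0.09, 0.05, 0.03, -0.01]; dpH_0 = 0.06, dpH_90 = 0.02
        # dpH = 0.04; ddpH = [+0.02, -0.02]; ddpH_trial = [0.05, 0.01, -0.01, -0.05]
        tm = _hand_matrix()
        maps = compute_response_maps(tm)
        assert maps.ph_interval_theta[0, 0].tolist() == pytest.approx([7.39, 7.43])
        assert maps.ph_interval[0, 0] == pytest.approx(7.41)
        assert maps.delta_ph_trial[0, 0].tolist() == pytest.approx([0.09, 0.05, 0.03, -0.01])
        assert maps.delta_ph_theta[0, 0].tolist() == pytest.approx([0.06, 0.02])
        assert maps.delta_ph[0, 0] == pytest.approx(0.04)
        assert maps.delta_delta_ph[0, 0].tolist() == pytest.approx([0.02, -0.02])
        ddt = compute_trial_responses(tm, maps)
        assert ddt[0, 0].tolist() == pytest.approx([0.05, 0.01, -0.01, -0.05])

    def test_constant_movie_maps_are_zero(self, constant_ph_movie, tiny_protocol):
        tm = segment_trials(constant_ph_movie, tiny_protocol)
        maps = compute_response_maps(tm)
        np.testing.assert_allclose(maps.delta_delta_ph, 0.0, atol=1e-9)
        np.testing.assert_allclose(maps.ph_interval, BASELINE_PH, atol=1e-5)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_algebraic_identities_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n_angles, n_per = 8, 5
        trial_angles = np.repeat(np.arange(n_angles) * 45.0, n_per)
        rng.shuffle(trial_angles)
        tm = TrialMatrix(
            ph_stim=7.4 + rng.standard_normal((6, 4, n_angles * n_per)),
            ph_interval_trial=7.4 + rng.standard_normal((6, 4, n_angles * n_per)),
            trial_angles=trial_angles,
            angles_deg=np.arange(n_angles) * 45.0,
            n_frames_used=np.full((n_angles * n_per, 2), 10),
        )
        tm.ph_stim[2, 2, :] = np.nan  # a masked pixel must stay masked
        maps = compute_response_maps(tm)
        ddt = compute_trial_responses(tm, maps)
        finite = np.isfinite(maps.delta_delta_ph).all(axis=2)
        # identity 1: mean over angles of ddpH vanishes
        assert np.abs(maps.delta_delta_ph.mean(axis=2)[finite]).max() < 1e-12
        # identity 2: per-angle trial mean of ddpH_trial equals ddpH
        for k, angle in enumerate(maps.angles_deg):
            idx = trial_angles == angle
            np.testing.assert_allclose(
                ddt[:, :, idx].mean(axis=2)[finite],
                maps.delta_delta_ph[:, :, k][finite],
                atol=1e-12,
            )
        # NaN isolation: only the masked pixel is NaN
        assert np.isnan(maps.delta_delta_ph[2, 2]).all()
        assert finite.sum() == 23

    def test_missing_angle_rejected(self):
        tm = _hand_matrix()
        tm.angles_deg = np.array([0.0, 90.0, 180.0])
        from phimage import InvalidParameterError

        with pytest.raises(InvalidParameterError):
            compute_response_maps(tm)


def _naive_eqs(ph_movie, protocol):
    """Deliberately slow frame-by-frame implementation of the statistic."""
    rate = ph_movie.geometry.frame_rate_hz
    mids = ph_movie.timestamps + 0.5 / rate
    angles = list(protocol.angles_deg)
    n_rows, n_cols = ph_movie.geometry.shape
    stim_means, int_means, trial_angles = [], [], []
    for onset, angle in protocol.events:
        stim_acc, stim_n = np.zeros((n_rows, n_cols)), 0
        int_acc, int_n = np.zeros((n_rows, n_cols)), 0
        for f in range(ph_movie.n_frames):
            if onset <= mids[f] < onset + protocol.stim_s:
                stim_acc += ph_movie.frames[f]
                stim_n += 1
            elif onset + protocol.stim_s <= mids[f] < onset + protocol.stim_s + protocol.interval_s:
                int_acc += ph_movie.frames[f]
                int_n += 1
        stim_means.append(stim_acc / stim_n)
        int_means.append(int_acc / int_n)
        trial_angles.append(angle)
    stim_means, int_means = np.array(stim_means), np.array(int_means)
    ph_int_theta = np.array(
        [
            np.mean([m for m, a in zip(int_means, trial_angles) if a == angle], axis=0)
            for angle in angles
        ]
    )
    ph_interval = ph_int_theta.mean(axis=0)
    dph_trial = stim_means - ph_interval
    dph_theta = np.array(
        [
            np.mean([m for m, a in zip(dph_trial, trial_angles) if a == angle], axis=0)
            for angle in angles
        ]
    )
    dph = dph_theta.mean(axis=0)
    ddph = dph_theta - dph
    ddph_trial = dph_trial - dph
    return ph_int_theta, ph_interval, dph_trial, dph_theta, dph, ddph, ddph_trial


class TestNaiveLoopOracle:
    def test_production_matches_naive_loops(self, small_geometry, tiny_protocol):
        field = synth.generate_response_field(
            small_geometry, angles_deg=(0.0, 90.0), amplitude_ph=0.02,
            angle_means={0.0: 1.0, 90.0: -1.0}, seed=3,
        )
        truth = synth.make_ground_truth(
            small_geometry, response_field=field, angles_deg=(0.0, 90.0), noise_sd_ph=0.01
        )
        ph = _ph_movie(small_geometry, tiny_protocol, truth, condition="brain", seed=5)
        tm = segment_trials(ph, tiny_protocol)
        maps = compute_response_maps(tm)
        ddt = compute_trial_responses(tm, maps)
        (n_it, n_i, n_dt, n_dth, n_d, n_dd, n_ddt) = _naive_eqs(ph, tiny_protocol)
        np.testing.assert_allclose(maps.ph_interval, n_i, atol=1e-12)
        np.testing.assert_allclose(np.moveaxis(maps.ph_interval_theta, 2, 0), n_it, atol=1e-12)
        np.testing.assert_allclose(np.moveaxis(maps.delta_ph_trial, 2, 0), n_dt, atol=1e-12)
        np.testing.assert_allclose(np.moveaxis(maps.delta_delta_ph, 2, 0), n_dd, atol=1e-12)
        np.testing.assert_allclose(np.moveaxis(ddt, 2, 0), n_ddt, atol=1e-12)


class TestNullScaling:
    def test_response_sd_shrinks_with_trials(self):
        """Across-pixel SD of the null statistic ~ 1/sqrt(n_trials)."""
        geom = SensorGeometry(n_rows=16, n_cols=8, frame_rate_hz=25.0)
        sds = {}
        for n_trials in (3, 12):
            protocol = synth.generate_protocol(
                pre_phase_s=2.0, stim_s=1.0, interval_s=1.0,
                n_trials_per_angle=n_trials, angles_deg=tuple(range(0, 360, 45)), seed=0,
            )
            truth = synth.make_ground_truth(geom, noise_sd_ph=0.01)
            ph = _ph_movie(geom, protocol, truth, seed=n_trials)
            maps = compute_response_maps(segment_trials(ph, protocol))
            sds[n_trials] = maps.delta_delta_ph.std()
        ratio = sds[3] / sds[12]
        assert ratio == pytest.approx(2.0, rel=0.2)
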