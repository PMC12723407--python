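"""Matrix-coil calibration: protocol, demodulation, solvers, closed loops."""

import numpy as np
import pytest

import opmcal as oc
from opmcal._utils import rotation_about_axis
from opmcal.calibration import (
    CalibrationDesign,
    component_amplitudes,
    demodulate,
    solve_orientation_gain,
    solve_position,
)
from opmcal.errors import (
    DeadChannelError,
    DegenerateOrientationError,
    InvalidArgumentError,
)
from opmcal.timeseries import TimeSeries


@pytest.fixture(scope="module")
def protocol():
    return oc.default_protocol()


@pytest.fixture(scope="module")
def design(protocol):
    return CalibrationDesign.from_protocol(protocol)


class TestProtocol:
    def test_frequency_comb(self, protocol):
        assert set(protocol.frequencies) == set(range(3, 11))

    def test_uniform_amplitude(self, protocol):
        assert all(c.amplitude == pytest.approx(0.2e-9)
                   for c in protocol.uniform_components)

    def test_gradient_amplitude(self, protocol):
        assert all(c.amplitude == pytest.approx(2e-9)
                   for c in protocol.gradient_components)

    def test_duration_and_rate(self, protocol):
        assert protocol.duration == 4.0
        assert protocol.sample_rate == 375.0


class TestSimulation:
    def test_noiseless_single_channel_pure_sinusoid(self):
        # identity-casing sensor at the origin: only the uniform fields couple
        slot = oc.SensorSlot(0, np.array([0.0, 0.0, 0.0]), np.eye(3))
        channels = [oc.TrueChannel(0, lab, np.eye(3)[i], 1.0, 0.0)
                    for i, lab in enumerate(("X", "Y", "Z"))]
        arr = oc.SensorArray(slots=[slot], channels=channels)
        ts = oc.simulate_calibration_recording(arr, seed=0)
        t = ts.times
        expected = 0.2e-9 * np.sin(2 * np.pi * 3.0 * t)
        assert np.allclose(ts.data[0], expected, atol=1e-24)

    def test_seed_determinism(self, small_array, protocol):
        a = oc.simulate_calibration_recording(small_array, protocol, seed=9)
        b = oc.simulate_calibration_recording(small_array, protocol, seed=9)
        c = oc.simulate_calibration_recording(small_array, protocol, seed=10)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)
        # different seeds differ only in the noise around the same signal
        amps = component_amplitudes(small_array, protocol)
        drives = np.sin(2 * np.pi * protocol.frequencies[:, None] * a.times[None, :])
        signal = amps @ drives
        sigma = 17e-15 * np.sqrt(375.0 / 2.0)
        for rec in (a, c):
            resid = rec.data - signal
            assert np.std(resid) == pytest.approx(sigma, rel=0.05)

    def test_superposed_field_below_linearity_limit(self, helmet_slots):
        assert oc.superposed_field_max(helmet_slots) < 1e-9


class TestDemodulation:
    def test_pure_tone_recovery_and_orthogonality(self, protocol):
        fs, t = 375.0, np.arange(int(4 * 375)) / 375.0
        data = 0.24e-9 * np.sin(2 * np.pi * 3.0 * t)[None, :]
        ts = TimeSeries(data=data, sample_rate=fs)
        resp = demodulate(ts, protocol, window_start=0.5, window_length=1.0)
        assert resp.b[0, 0] == pytest.approx(0.24e-9, rel=1e-12)
        others = np.concatenate([resp.b[0, 1:], resp.bg[0]])
        assert np.all(np.abs(others) < 1e-12 * 1e-9)

    def test_non_integer_cycle_window_rejected(self, protocol):
        ts = TimeSeries(data=np.zeros((1, 1500)), sample_rate=375.0)
        with pytest.raises(InvalidArgumentError):
            demodulate(ts, protocol, window_start=0.0, window_length=0.9)

    def test_window_outside_recording_rejected(self, protocol):
        ts = TimeSeries(data=np.zeros((1, 300)), sample_rate=375.0)
        with pytest.raises(InvalidArgumentError):
            demodulate(ts, protocol, window_start=0.5, window_length=1.0)

    def test_noise_floor_of_amplitude_estimates(self, protocol):
        """White noise at 17 fT/rtHz gives ~17 fT std per component (1-s window)."""
        rng = np.random.default_rng(21)
        nd = 17e-15
        sigma = nd * np.sqrt(375.0 / 2.0)
        data = rng.normal(0.0, sigma, size=(2000, 1500))
        ts = TimeSeries(data=data, sample_rate=375.0)
        resp = demodulate(ts, protocol, 0.5, 1.0)
        est_sd = np.concatenate([resp.b.ravel(), resp.bg.ravel()]).std()
        # oracle: sd = noise_density / sqrt(window_length) = 17 fT
        assert est_sd == pytest.approx(nd, rel=0.05)


class TestSolvers:
    def test_diagonal_solve(self, design):
        u, gain = solve_orientation_gain(np.array([0, 0, 0.24e-9]), design)
        assert np.allclose(u, [0, 0, 1])
        assert gain == pytest.approx(1.2)

    def test_orientation_gain_exact_recovery(self, design):
        rng = np.random.default_rng(5)
        for _ in range(20):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            gain = rng.uniform(0.5, 1.5)
            b = design.uniform_matrix @ (gain * v)
            u, g = solve_orientation_gain(b, design)
            assert np.allclose(u, v, atol=1e-12)
            assert g == pytest.approx(gain, rel=1e-12)

    def test_orientation_gain_matches_brute_force(self, design):
        """pinv solve equals hand-rolled normal-equations least squares."""
        rng = np.random.default_rng(6)
        U = design.uniform_matrix
        for _ in range(10):
            b = rng.normal(size=3) * 1e-10
            g_hand = np.linalg.inv(U.T @ U) @ (U.T @ b)
            u, g = solve_orientation_gain(b, design)
            assert np.allclose(g * u, g_hand, rtol=1e-10)

    def test_dead_channel_detected(self, design):
        with pytest.raises(DeadChannelError):
            solve_orientation_gain(np.zeros(3), design)

    def test_position_hand_example(self, design):
        """Only the dBx/dx basis gives an x-channel signal at an x-offset."""
        bg = np.array([0.1e-9, 0, 0, 0, 0])
        r = solve_position(bg, np.array([1.0, 0, 0]), 1.0, design)
        assert np.allclose(r, [0.05, 0, 0], atol=1e-15)

    def test_position_closed_loop_and_brute_force(self, design):
        rng = np.random.default_rng(7)
        for _ in range(20):
            u = rng.normal(size=3)
            u /= np.linalg.norm(u)
            gain = rng.uniform(0.8, 1.4)
            r_true = rng.uniform(-0.1, 0.1, 3)
            BG = np.array([gain * u @ G for G in design.gradient_tensors])
            bg = BG @ r_true
            r = solve_position(bg, u, gain, design)
            assert np.allclose(r, r_true, atol=1e-12)
            # independent oracle: normal equations
            r_hand = np.linalg.solve(BG.T @ BG, BG.T @ bg)
            assert np.allclose(r, r_hand, atol=1e-10)

    def test_zero_response_gives_origin(self, design):
        r = solve_position(np.zeros(5), np.array([0, 1.0, 0]), 1.0, design)
        assert np.allclose(r, 0.0)

    def test_degenerate_design_detected(self, design):
        # five copies of the same tensor leave rank-1 rows
        bad = CalibrationDesign(design.uniform_matrix,
                                np.repeat(design.gradient_tensors[:1], 5, axis=0))
        with pytest.raises(DegenerateOrientationError):
            solve_position(np.zeros(5), np.array([1.0, 0, 0]), 1.0, bad)


class TestClosedLoopCalibration:
    def test_noiseless_recovery_is_exact(self, quiet_small_array):
        res = oc.ArrayCalibrationModel.from_array(quiet_small_array, seed=3).fit()
        rep = res.compare_to_truth(quiet_small_array)
        assert rep.angle_error_deg.max() < 1e-6
        assert np.abs(rep.gain_ratio - 1).max() < 1e-9
        assert rep.position_error_mm.max() < 1e-6

    def test_noisy_recovery_default_array(self, full_array):
        """Default noise, 1-s window: tight orientation/gain/position errors."""
        res = oc.ArrayCalibrationModel.from_array(full_array, seed=4).fit()
        rep = res.compare_to_truth(full_array)
        assert np.mean(rep.angle_error_deg < 0.5) >= 0.95
        assert np.mean(np.abs(rep.gain_ratio - 1) < 0.01) >= 0.95
        assert np.median(rep.position_error_mm) < 1.0

    def test_error_scales_with_noise(self, helmet_slots):
        medians = []
        for scale in (0.5, 1.0, 2.0):
            arr = oc.make_synthetic_array(helmet_slots, n_sensors=32,
                                          noise_density=17.0 * scale, seed=30)
            res = oc.ArrayCalibrationModel.from_array(arr, seed=31).fit()
            rep = res.compare_to_truth(arr)
            medians.append(np.median(rep.position_error_mm))
        assert medians[0] < medians[1] < medians[2]
        assert medians[2] / medians[0] == pytest.approx(4.0, rel=0.5)

    def test_dead_channel_flagged_others_unaffected(self, quiet_small_array):
        protocol = oc.default_protocol()
        rec = oc.simulate_calibration_recording(quiet_small_array, protocol, seed=5)
        rec.data[7] = 0.0
        res = oc.calibrate_array(rec, protocol, quiet_small_array.sensor_ids)
        assert not res.ok[7]
        assert 7 in res.flagged
        others = np.ones(res.n_channels, dtype=bool)
        others[7] = False
        assert res.ok[others].all()
        rep = res.compare_to_truth(quiet_small_array)
        assert np.nanmax(rep.angle_error_deg[others]) < 1e-6

    def test_rotational_equivariance(self, quiet_small_array):
        """Rotating array and coil patterns together rotates the estimates."""
        protocol = oc.default_protocol()
        base = CalibrationDesign.from_protocol(protocol)
        res = oc.ArrayCalibrationModel.from_array(quiet_small_array, seed=6).fit()

        R = rotation_about_axis([0.3, -1.0, 0.7], 0.8)
        pos, ori, gains = quiet_small_array.channel_matrices()
        rot_design = base.rotated(R)
        amps = component_amplitudes((pos @ R.T, ori @ R.T, gains), protocol, rot_design)
        n_samp = int(4 * 375)
        t = np.arange(n_samp) / 375.0
        drives = np.sin(2 * np.pi * protocol.frequencies[:, None] * t[None, :])
        ts = TimeSeries(data=amps @ drives, sample_rate=375.0)
        res_rot = oc.calibrate_array(ts, protocol, quiet_small_array.sensor_ids,
                                     design=rot_design)
        assert np.allclose(res_rot.orientations, res.orientations @ R.T, atol=1e-9)
        assert np.allclose(res_rot.positions, res.positions @ R.T, atol=1e-9)
        assert np.allclose(res_rot.gains, res.gains, rtol=1e-9)

    def test_sensor_position_is_mean_of_channels(self, quiet_small_array):
        res = oc.ArrayCalibrationModel.from_array(quiet_small_array, seed=7).fit()
        sid = quiet_small_array.sensor_ids[0]
        mask = quiet_small_array.sensor_ids == sid
        assert np.allclose(res.sensor_positions[int(sid)],
                           res.positions[mask].mean(axis=0))

    def test_summary_table(self, quiet_small_array):
        res = oc.ArrayCalibrationModel.from_array(quiet_small_array, seed=8).fit()
        df = res.summary()
        assert len(df) == quiet_small_array.n_channels
        assert {"gain", "x_m", "residual_T", "ok"} <= set(df.columns)


class TestCompareToTruth:
    def test_perfect_match(self, quiet_small_array):
        pos, ori, gains = quiet_small_array.channel_matrices()
        res = oc.ArrayCalibrationModel.from_array(quiet_small_array, seed=9).fit()
        res.orientations, res.positions, res.gains = ori, pos, gains
        rep = res.compare_to_truth(quiet_small_array)
        # arccos amplifies unit rounding near 1, hence the 1e-5 deg floor
        assert np.all(rep.angle_error_deg < 1e-5)
        assert np.allclose(rep.gain_ratio, 1.0)
        assert np.allclose(rep.position_error_mm, 0.0)

    def test_injected_rotation_reported(self, quiet_small_array):
        res = oc.ArrayCalibrationModel.from_array(quiet_small_array, seed=10).fit()
        u = res.orientations[0]
        perp = np.cross(u, [0.0, 0.0, 1.0])
        perp /= np.linalg.norm(perp)
        res.orientations[0] = rotation_about_axis(perp, np.deg2rad(10.0)) @ u
        rep = res.compare_to_truth(quiet_small_array)
        assert rep.angle_error_deg[0] == pytest.approx(10.0, abs=1e-6)

    def test_per_axis_summary_shape(self, small_array):
        res = oc.ArrayCalibrationModel.from_array(small_array, seed=11).fit()
        df = res.compare_to_truth(small_array).summary()
        assert set(df.index) == {"X", "Y", "Z"}

    def test_mismatched_channel_count_rejected(self, small_array, quiet_small_array):
        res = oc.ArrayCalibrationModel.from_array(small_array, seed=12).fit()
        bad = oc.make_synthetic_array(small_array.slots, n_sensors=8, seed=1)
        with pytest.raises(InvalidArgumentError):
            res.compare_to_truth(bad)
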