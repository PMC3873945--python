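"""Generator contracts: shapes, determinism, and planted-coupling soundness."""

import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d
from scipy.signal import periodogram

from ecogdecode import (
    AlignmentError,
    ElectrodeLayout,
    GeneratorConfig,
    GroundTruth,
    InvalidArgumentError,
    PHYSIOLOGICAL_BANDS,
    bandpass,
    common_average_reference,
    envelope,
    generate_ecog,
    generate_trajectory,
    load_dataset,
    make_dataset,
    save_dataset,
)
from ecogdecode.synthetic import _bandlimited_noise, kinematic_drive, _AMPLITUDE


class TestTrajectory:
    def test_shape_and_bounds(self):
        tr = generate_trajectory(20.0, 250.0, cycle_period_s=5.0, jitter_sd=0.1, seed=0)
        assert tr.data.shape == (3, 5000)
        lo = -0.5 * _AMPLITUDE
        hi = 2.0 * _AMPLITUDE
        assert np.all(tr.data >= lo[:, None]) and np.all(tr.data <= hi[:, None])

    def test_zero_jitter_is_exactly_periodic(self):
        tr = generate_trajectory(20.0, 500.0, cycle_period_s=5.0, jitter_sd=0.0, seed=3)
        per = 2500
        assert np.array_equal(tr.data[:, :per], tr.data[:, per : 2 * per])

    def test_deterministic_for_fixed_seed(self):
        a = generate_trajectory(10.0, 200.0, seed=7)
        b = generate_trajectory(10.0, 200.0, seed=7)
        c = generate_trajectory(10.0, 200.0, seed=8)
        assert np.array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    @pytest.mark.parametrize("kwargs", [
        {"duration_s": 0}, {"fs": -1}, {"cycle_period_s": 0},
    ])
    def test_invalid_arguments(self, kwargs):
        args = {"duration_s": 10.0, "fs": 100.0, "cycle_period_s": 5.0} | kwargs
        with pytest.raises(InvalidArgumentError):
            generate_trajectory(**args)


class TestCarriers:
    def test_band_limited_power(self):
        """Each carrier's spectral power outside its band is < 5% of total."""
        rng = np.random.default_rng(0)
        for band in PHYSIOLOGICAL_BANDS:
            x = _bandlimited_noise(rng, 1, 50_000, 500.0, band.low_hz, band.high_hz)[0]
            f, p = periodogram(x, fs=500.0)
            outside = p[(f < band.low_hz) | (f >= band.high_hz)].sum()
            assert outside / p.sum() < 0.05


class TestGenerateEcog:
    def test_null_truth_envelopes_uncorrelated_with_drive(self):
        """With zero coupling weights the band envelopes carry no kinematics."""
        layout = ElectrodeLayout.grid(2, 2)
        traj = generate_trajectory(300.0, 500.0, seed=42)
        rec = generate_ecog(traj, layout, GroundTruth.null(), fs=500.0, seed=43)
        drive = kinematic_drive(traj, np.random.default_rng(43).standard_normal((4, 4)))
        referenced = common_average_reference(rec)
        for band in PHYSIOLOGICAL_BANDS:
            env = envelope(bandpass(referenced, (band.low_hz, band.high_hz)))
            for ch in range(2):
                r = np.corrcoef(env.data[ch, 2000:], drive[ch, 2000:])[0, 1]
                assert abs(r) < 0.1

    def test_car_removes_planted_common_mode_share(self):
        """Variance bookkeeping: CAR strips the common-mode term (plus 1/C of
        the independent per-channel power)."""
        cm = 3.0
        cfg = GeneratorConfig(
            duration_s=60.0, n_rows=2, n_cols=4, seed=7,
            truth=GroundTruth.null(), common_mode_sd=cm,
        )
        ds = make_dataset(cfg)
        n_ch = ds.recording.n_channels
        v_before = ds.recording.data.var(axis=1).mean()
        v_after = common_average_reference(ds.recording).data.var(axis=1).mean()
        v_indep = v_before - cm**2
        expected_drop = cm**2 + v_indep / n_ch
        assert (v_before - v_after) == pytest.approx(expected_drop, rel=0.05)

    def test_planted_gamma3_envelope_tracks_lagged_drive(self):
        """Single informative channel at high SNR: its gamma3 envelope
        correlates strongly (r > 0.8) with the lagged kinematic drive."""
        fs = 500.0
        layout = ElectrodeLayout.grid(2, 2)
        truth = GroundTruth(
            informative_channels=frozenset([2]),
            band_weights={"gamma3": 1.0}, snr=100.0, coupling_lag_s=0.09,
        )
        traj = generate_trajectory(120.0, fs, seed=5)
        rec = generate_ecog(traj, layout, truth, fs=fs, seed=6, modulation_depth=0.8)
        env = envelope(bandpass(common_average_reference(rec), (90.0, 120.0)))
        est = gaussian_filter1d(env.data[1], sigma=0.2 * fs)  # channel id 2 -> row 1
        drive = kinematic_drive(traj, np.random.default_rng(6).standard_normal((4, 4)))[1]
        d = int(0.09 * fs)
        lagged = np.concatenate([np.full(d, drive[0]), drive[:-d]])
        r = np.corrcoef(est[2500:], lagged[2500:])[0, 1]
        assert r > 0.8

    def test_lag_out_of_range_rejected(self):
        layout = ElectrodeLayout.grid(2, 2)
        traj = generate_trajectory(5.0, 100.0, seed=0)
        bad = GroundTruth(frozenset([1]), {"gamma3": 1.0}, coupling_lag_s=0.7)
        with pytest.raises(InvalidArgumentError):
            generate_ecog(traj, layout, bad, fs=100.0, seed=0)

    def test_fs_mismatch_rejected(self):
        layout = ElectrodeLayout.grid(2, 2)
        traj = generate_trajectory(5.0, 100.0, seed=0)
        with pytest.raises(AlignmentError):
            generate_ecog(traj, layout, GroundTruth.null(), fs=200.0, seed=0)


class TestMakeDataset:
    def test_default_config_emulates_32_channel_session(self):
        ds = make_dataset(GeneratorConfig())
        assert ds.recording.data.shape == (32, 350_000)
        assert ds.trajectory.data.shape == (3, 350_000)
        assert ds.recording.fs == 500.0
        assert (ds.recording.layout.n_rows, ds.recording.layout.n_cols) == (4, 8)

    def test_15_channel_variant(self):
        cfg = GeneratorConfig(duration_s=10.0, n_rows=5, n_cols=3)
        ds = make_dataset(cfg)
        assert ds.recording.n_channels == 15
        assert ds.trajectory.duration_s == ds.recording.duration_s

    def test_determinism(self):
        cfg = GeneratorConfig(duration_s=10.0, n_rows=2, n_cols=2, seed=5)
        a, b = make_dataset(cfg), make_dataset(cfg)
        assert np.array_equal(a.recording.data, b.recording.data)
        assert np.array_equal(a.trajectory.data, b.trajectory.data)
        assert a.truth == b.truth


class TestRoundTrip:
    def test_save_load_lossless(self, tmp_path):
        cfg = GeneratorConfig(duration_s=8.0, n_rows=2, n_cols=3, seed=9)
        ds = make_dataset(cfg)
        path = save_dataset(ds, tmp_path / "session.h5")
        back = load_dataset(path)
        assert np.array_equal(back.recording.data, ds.recording.data)
        assert np.array_equal(back.trajectory.data, ds.trajectory.data)
        assert back.recording.fs == ds.recording.fs
        assert back.recording.layout == ds.recording.layout
        assert back.truth == ds.truth
        assert back.seed == ds.seed


class TestLayout:
    def test_positions_unique_and_in_range(self):
        layout = ElectrodeLayout.grid(4, 8)
        assert layout.n_channels == 32
        assert len({layout.position_of(c) for c in layout.channel_ids}) == 32

    def test_unknown_channel(self):
        with pytest.raises(InvalidArgumentError):
            ElectrodeLayout.grid(2, 2).position_of(99)

    def test_duplicate_position_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ElectrodeLayout(
                n_rows=2, n_cols=2, channel_ids=(1, 2, 3, 4),
                positions={1: (1, 1), 2: (1, 1), 3: (2, 1), 4: (2, 2)},
            )
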