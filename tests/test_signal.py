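"""Preprocessing and technical quality checks."""

import numpy as np
import pytest

from sdmkit.errors import InsufficientDataError
from sdmkit.signal import (
    bandpass_zero_phase,
    flag_orientation,
    flag_sampling,
    gravity_and_norm,
    resample_uniform,
    sampling_stats,
)


class TestSamplingStats:
    def test_uniform_grid(self):
        ts = np.arange(1000) / 100.0
        s = sampling_stats(ts)
        assert s.median_freq == pytest.approx(100.0)
        assert s.irregularity == pytest.approx(0.0)
        assert s.max_gap == pytest.approx(0.01)

    def test_single_gap(self):
        ts = np.concatenate([np.arange(500) / 100.0,
                             5.0 + 0.5 + np.arange(500) / 100.0])
        assert sampling_stats(ts).max_gap == pytest.approx(0.51, abs=1e-9)

    def test_jittered_irregularity(self, rng):
        dt = 0.01 + rng.normal(0.0, 0.002, 5000)
        dt = np.clip(dt, 1e-4, None)
        ts = np.concatenate([[0.0], np.cumsum(dt)])
        s = sampling_stats(ts)
        assert s.irregularity == pytest.approx(0.2, rel=0.1)

    def test_too_few_samples(self):
        with pytest.raises(InsufficientDataError):
            sampling_stats([0.0, 0.1])

    def test_invariant_under_time_offset(self, rng):
        ts = np.sort(rng.uniform(0, 10, 200))
        a, b = sampling_stats(ts), sampling_stats(ts + 1234.5)
        assert a.irregularity == pytest.approx(b.irregularity, abs=1e-9)
        assert a.max_gap == pytest.approx(b.max_gap, abs=1e-9)


class TestFlagSampling:
    def test_uniform_not_flagged(self):
        s = sampling_stats(np.arange(1000) / 100.0, 100.0)
        assert flag_sampling(s, 100.0) is None

    def test_gap_flagged(self):
        ts = np.concatenate([np.arange(100) / 100.0,
                             1.5 + np.arange(100) / 100.0])
        flag = flag_sampling(sampling_stats(ts), 100.0, task="sixmwt")
        assert flag is not None
        assert flag.id == "sixmwt-technical-deviation-unstable_sampling"

    def test_jitter_flagged(self, rng):
        dt = np.clip(0.01 + rng.normal(0.0, 0.002, 2000), 1e-4, None)
        ts = np.concatenate([[0.0], np.cumsum(dt)])
        assert flag_sampling(sampling_stats(ts), 100.0) is not None


class TestResampleUniform:
    def test_uniform_input_unchanged(self):
        ts = np.arange(100) / 50.0
        vals = np.sin(ts)
        grid, out = resample_uniform(ts, vals, 50.0)
        assert np.allclose(grid, ts, atol=1e-12)
        assert np.allclose(out, vals, atol=1e-12)

    def test_linear_ramp_exact_midpoints(self):
        ts = np.array([0.0, 1.0, 2.0])
        vals = np.array([0.0, 10.0, 20.0])
        grid, out = resample_uniform(ts, vals, 2.0)
        assert np.allclose(out, 10.0 * grid, atol=1e-12)

    def test_sine_downsample_error_small(self):
        ts = np.arange(200) / 100.0
        vals = np.sin(2 * np.pi * 2.0 * ts)
        grid, out = resample_uniform(ts, vals, 50.0)
        assert np.max(np.abs(out - np.sin(2 * np.pi * 2.0 * grid))) < 0.01

    def test_idempotent_on_uniform(self):
        ts = np.arange(64) / 32.0
        vals = np.cos(ts)
        g1, v1 = resample_uniform(ts, vals, 32.0)
        g2, v2 = resample_uniform(g1, v1, 32.0)
        assert np.allclose(v1, v2, atol=1e-12)


class TestBandpass:
    def test_dc_rejected(self):
        x = np.full(2000, 3.0)
        y = bandpass_zero_phase(x, 100.0, 2, 0.5, 5.0)
        assert np.max(np.abs(y[200:-200])) < 1e-6 * 3.0

    def test_in_band_sine_zero_lag(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 2.0 * t)
        y = bandpass_zero_phase(x, 100.0, 2, 0.5, 5.0)
        xc = np.correlate(y[300:-300], x[300:-300], "full")
        lag = int(np.argmax(xc)) - (len(x) - 601)
        assert lag == 0

    def test_out_of_band_attenuated(self):
        t = np.arange(2000) / 100.0
        x = np.sin(2 * np.pi * 20.0 * t)
        y = bandpass_zero_phase(x, 100.0, 2, 0.5, 5.0)
        assert np.max(np.abs(y[300:-300])) < 0.1

    def test_time_reversal_symmetry(self, rng):
        x = rng.normal(0, 1, 1024)
        fwd = bandpass_zero_phase(x, 100.0, 2, 0.5, 5.0)
        rev = bandpass_zero_phase(x[::-1], 100.0, 2, 0.5, 5.0)
        assert np.allclose(fwd, rev[::-1], atol=1e-9)

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            bandpass_zero_phase(np.zeros(100), 100.0, 2, 5.0, 0.5)


class TestGravityAndNorm:
    def test_constant_gravity(self):
        acc = np.tile([0.0, 0.0, 9.81], (100, 1))
        norm, g = gravity_and_norm(acc)
        assert np.allclose(g, [0, 0, 9.81])
        assert np.allclose(norm, 0.0)

    def test_x_sine_amplitude_recovered(self):
        t = np.arange(1000) / 100.0
        acc = np.column_stack(
            [2.0 * np.sin(2 * np.pi * t), np.zeros_like(t),
             np.full_like(t, 9.81)]
        )
        norm, g = gravity_and_norm(acc)
        assert np.max(norm) == pytest.approx(2.0, rel=0.01)

    def test_zeros(self):
        norm, g = gravity_and_norm(np.zeros((10, 3)))
        assert np.allclose(norm, 0.0) and np.allclose(g, 0.0)


class TestFlagOrientation:
    def make_acc(self, z):
        return np.column_stack(
            [np.zeros(100), np.zeros(100), np.full(100, z)]
        )

    def test_correct_orientation_unflagged(self):
        assert flag_orientation(self.make_acc(9.81), "z", 1) is None

    def test_flipped_device_flagged(self):
        flag = flag_orientation(self.make_acc(-9.81), "z", 1, task="sixmwt")
        assert flag is not None
        assert flag.id == "sixmwt-behavioral-deviation-wrong_orientation"

    def test_weak_gravity_component_flagged(self):
        # 0.3 g on the expected axis: device tilted away
        assert flag_orientation(self.make_acc(0.3 * 9.81), "z", 1) is not None
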