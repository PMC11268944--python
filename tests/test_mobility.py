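"""Gait, turn and sway extraction."""

import math

import numpy as np
import pytest

from sdmkit.errors import InsufficientDataError
from sdmkit.mobility import (
    CHI2_95_2DF,
    detect_steps,
    detect_turns,
    sway_metrics,
)
from sdmkit.processing import process
from sdmkit.synthetic import corrupt, gen_walk


class TestDetectSteps:
    def test_pure_sine_exact_count(self):
        fs, dur, f = 100.0, 60.0, 2.0
        t = np.arange(int(dur * fs)) / fs
        x = 1.0 * np.sin(2 * np.pi * f * t)
        res = detect_steps(x, fs)
        assert res.count == 120
        assert res.cadence == pytest.approx(120.0, abs=1e-9)
        # filter edge transients shift the first/last peak slightly
        assert res.step_time_cv < 0.02

    def test_zero_signal(self):
        res = detect_steps(np.zeros(1000), 100.0)
        assert res.count == 0 and res.cadence == 0.0
        assert res.step_time_cv is None

    def test_noisy_sine_count_close(self):
        rng = np.random.default_rng(7)
        fs = 100.0
        t = np.arange(6000) / fs
        x = np.sin(2 * np.pi * 2.0 * t) + rng.normal(0, 0.05, t.size)
        res = detect_steps(x, fs)
        assert abs(res.count - 120) <= 2

    def test_short_signal_raises(self):
        with pytest.raises(InsufficientDataError):
            detect_steps(np.zeros(300), 100.0)

    @pytest.mark.parametrize("cadence", [80.0, 100.0, 120.0])
    def test_cadence_recovery_through_pipeline(self, cadence, registry):
        r, truth = gen_walk(cadence=cadence, duration=60.0, fs=100.0,
                            noise_sd=0.05, seed=11)
        r, _ = process(r, registry.steps_for("sixmwt"))
        est = r.levels[0].measures["sixmwt-cadence"].value
        assert abs(est - cadence) <= 2.0


class TestDetectTurns:
    def test_constant_rate_half_turn(self):
        fs = 100.0
        w = np.concatenate(
            [np.zeros(100), np.full(200, math.radians(90.0)), np.zeros(100)]
        )
        turns = detect_turns(w, fs)
        assert len(turns) == 1
        assert turns[0].angle == pytest.approx(math.pi, abs=0.01)
        assert turns[0].duration == pytest.approx(2.0, abs=0.1)
        assert turns[0].peak_rate == pytest.approx(math.radians(90.0))

    def test_zero_rate_no_turns(self):
        assert detect_turns(np.zeros(1000), 100.0) == []

    def test_opposite_turns_signed(self):
        fs = 100.0
        w = np.concatenate(
            [np.zeros(100), np.full(200, math.radians(90.0)),
             np.zeros(300), np.full(200, -math.radians(90.0)), np.zeros(100)]
        )
        turns = detect_turns(w, fs)
        assert [round(t.angle, 3) for t in turns] == [
            round(math.pi, 3), round(-math.pi, 3)
        ]
        assert turns[0].end <= turns[1].start  # non-overlapping, ordered

    def test_small_angle_discarded(self):
        fs = 100.0
        w = np.concatenate([np.zeros(50), np.full(100, math.radians(90.0)),
                            np.zeros(50)])  # 90 deg < 160 deg minimum
        assert detect_turns(w, fs) == []

    def test_physical_time_reversal_negates_angles(self):
        rng = np.random.default_rng(3)
        fs = 100.0
        w = np.concatenate(
            [np.zeros(150), np.full(250, math.radians(80.0)), np.zeros(150)]
        ) + rng.normal(0, 0.01, 550)
        fwd = detect_turns(w, fs)
        rev = detect_turns(-w[::-1], fs)
        assert len(fwd) == len(rev)
        for a, b in zip(fwd, reversed(rev)):
            assert a.angle == pytest.approx(-b.angle, abs=1e-6)


class TestSwayMetrics:
    def test_isotropic_gaussian_matches_closed_form(self):
        rng = np.random.default_rng(42)
        sigma = 0.05
        ap = rng.normal(0, sigma, 6000)
        ml = rng.normal(0, sigma, 6000)
        m = sway_metrics(ap, ml, 100.0)
        expected = math.pi * CHI2_95_2DF * sigma**2
        assert m.ellipse_area == pytest.approx(expected, rel=0.10)

    def test_constant_signals_zero(self):
        m = sway_metrics(np.full(2000, 1.5), np.full(2000, -0.7), 100.0)
        assert m.rms_ap == pytest.approx(0.0, abs=1e-12)
        assert m.rms_ml == pytest.approx(0.0, abs=1e-12)
        assert m.ellipse_area == pytest.approx(0.0, abs=1e-12)
        assert m.jerk_rms == pytest.approx(0.0, abs=1e-9)

    def test_scaling_law(self, rng):
        ap, ml = rng.normal(0, 1, 2000), rng.normal(0, 1, 2000)
        m1 = sway_metrics(ap, ml, 100.0)
        m2 = sway_metrics(2 * ap, 2 * ml, 100.0)
        assert m2.rms_ap == pytest.approx(2 * m1.rms_ap)
        assert m2.ellipse_area == pytest.approx(4 * m1.ellipse_area)

    def test_rotation_invariance_of_ellipse_area(self, rng):
        ap = rng.normal(0, 0.08, 3000)
        ml = rng.normal(0, 0.03, 3000)
        theta = 0.7
        ap2 = math.cos(theta) * ap - math.sin(theta) * ml
        ml2 = math.sin(theta) * ap + math.cos(theta) * ml
        a1 = sway_metrics(ap, ml, 100.0).ellipse_area
        a2 = sway_metrics(ap2, ml2, 100.0).ellipse_area
        assert a2 == pytest.approx(a1, rel=1e-9)

    def test_too_short_raises(self):
        with pytest.raises(InsufficientDataError):
            sway_metrics(np.zeros(500), np.zeros(500), 100.0)


class TestSixmwtPipeline:
    def test_fixture_cadence_recovered(self, registry):
        r, truth = gen_walk(cadence=108.0, duration=360.0, seed=5)
        r, _ = process(r, registry.steps_for("sixmwt"))
        ms = r.levels[0].measures
        assert ms["sixmwt-cadence"].value == pytest.approx(108.0, abs=2.0)
        assert ms["sixmwt-cadence-mean"].value == pytest.approx(108.0, abs=2.0)
        assert not r.flags

    def test_truncated_recording_invalidated_but_measured(self, registry):
        r, _ = gen_walk(cadence=108.0, duration=360.0, seed=5)
        r = corrupt(r, "truncate", frac=0.1)
        r, _ = process(r, registry.steps_for("sixmwt"))
        assert "sixmwt-behavioral-invalidation-too_short" in r.flag_ids()
        ms = r.levels[0].measures
        assert "sixmwt-cadence" in ms
        # invalidation annotates the extracted measures
        assert "sixmwt-behavioral-invalidation-too_short" in (
            ms["sixmwt-cadence"].flag_ids
        )

    def test_flipped_device_flagged_measures_present(self, registry):
        r, _ = gen_walk(cadence=108.0, duration=360.0, seed=5)
        r = corrupt(r, "flip_orientation")
        r, _ = process(r, registry.steps_for("sixmwt"))
        assert "sixmwt-behavioral-deviation-wrong_orientation" in r.flag_ids()
        assert "sixmwt-cadence" in r.levels[0].measures
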