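"""Drawing similarity, pinch, processing speed, event statistics."""

import math

import numpy as np
import pytest

from sdmkit.errors import InsufficientDataError
from sdmkit.synthetic import reference_shape
from sdmkit.upperlimb import (
    ResponseLog,
    arc_length_resample,
    cps_stats,
    drawing_similarity,
    dtw_distance,
    event_stats,
    pinch_stats,
)


def brute_force_dtw(a, b):
    """Independent DTW oracle: exhaustively enumerate every monotone
    alignment path and return the minimum-total-cost path average."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    n, m = len(a), len(b)
    best = (np.inf, 1)

    def walk(i, j, total, length):
        nonlocal best
        total += np.linalg.norm(a[i] - b[j])
        length += 1
        if total >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best = (total, length)
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, total, length)
        if i + 1 < n:
            walk(i + 1, j, total, length)
        if j + 1 < m:
            walk(i, j + 1, total, length)

    walk(0, 0, 0.0, 0)
    return best[0] / best[1]


class TestDrawingSimilarity:
    def test_identity_zero(self):
        ref = reference_shape("circle")
        t = np.linspace(0, 5, len(ref))
        res = drawing_similarity(t, ref, ref)
        assert res.sim == 0.0 and res.dtw_sim == 0.0
        assert res.duration == pytest.approx(5.0)

    def test_rigid_translation_exact_offset(self):
        ref = reference_shape("square")
        t = np.linspace(0, 5, len(ref))
        res = drawing_similarity(t, ref + np.array([3.0, 4.0]), ref)
        assert res.sim == pytest.approx(5.0, abs=1e-9)

    def test_dtw_relaxation_property(self, rng):
        """DTW may only reduce the mean distance relative to index
        pairing, for arbitrary perturbed traces."""
        ref = reference_shape("infinity")
        t = np.linspace(0, 5, len(ref))
        for _ in range(20):
            perturbed = ref + rng.normal(0, 5.0, ref.shape)
            res = drawing_similarity(t, perturbed, ref, n_points=60)
            assert res.dtw_sim <= res.sim + 1e-12

    def test_dtw_matches_exhaustive_oracle(self, rng):
        a = rng.normal(0, 1, (7, 2))
        b = rng.normal(0, 1, (6, 2))
        assert dtw_distance(a, b) == pytest.approx(
            brute_force_dtw(a, b), abs=1e-9
        )

    def test_invariant_under_common_rigid_transform(self, rng):
        ref = reference_shape("spiral")
        t = np.linspace(0, 5, len(ref))
        trace = ref + rng.normal(0, 3.0, ref.shape)
        theta, shift = 1.1, np.array([40.0, -25.0])
        rot = np.array([[math.cos(theta), -math.sin(theta)],
                        [math.sin(theta), math.cos(theta)]])
        res0 = drawing_similarity(t, trace, ref, n_points=80)
        res1 = drawing_similarity(
            t, trace @ rot.T + shift, ref @ rot.T + shift, n_points=80
        )
        assert res1.sim == pytest.approx(res0.sim, rel=1e-9)
        assert res1.dtw_sim == pytest.approx(res0.dtw_sim, rel=1e-9)

    def test_single_point_trace_rejected(self):
        with pytest.raises(InsufficientDataError):
            drawing_similarity([0.0], [[0.0, 0.0]], reference_shape("circle"))

    def test_arc_length_resample_uniform_spacing(self):
        # irregularly spaced vertices on a straight line: resampled
        # points must come out equally spaced along the arc
        line = np.array([[0.0, 0.0], [0.3, 0.3], [4.0, 4.0], [10.0, 10.0]])
        out = arc_length_resample(line, 50)
        seg = np.linalg.norm(np.diff(out, axis=0), axis=1)
        assert np.allclose(seg, seg[0], rtol=1e-9)


class TestPinch:
    def _streams(self, specs, fs=50.0):
        """specs: list of final distances (success < 50)."""
        t, cid, x, y = [], [], [], []
        t0 = 0.0
        for final in specs:
            n = int(0.5 * fs)
            for i in range(n):
                d = 200.0 + (final - 200.0) * i / (n - 1)
                for c, s in ((0, -0.5), (1, 0.5)):
                    t.append(t0 + i / fs)
                    cid.append(c)
                    x.append(s * d)
                    y.append(0.0)
            t0 += 1.5
        return t, cid, x, y

    def test_three_successes(self):
        res = pinch_stats(*self._streams([10, 10, 10]), target_distance=50.0)
        assert (res.attempts, res.successes) == (3, 3)
        assert res.success_rate == 1.0

    def test_alternating_success_failure(self):
        res = pinch_stats(
            *self._streams([10, 120, 10, 120, 10, 120, 10, 120]),
            target_distance=50.0,
        )
        assert res.attempts == 8 and res.success_rate == 0.5

    def test_single_finger_flagged_no_attempts(self):
        t = np.arange(100) / 50.0
        res = pinch_stats(t, np.zeros(100), np.zeros(100), np.zeros(100),
                          target_distance=50.0)
        assert res.attempts == 0 and res.single_finger


class TestCps:
    def make_log(self, n, n_correct, rts):
        key_map = {"a": "1", "b": "2"}
        trials = []
        t = 0.0
        for i in range(n):
            resp = "1" if i < n_correct else "9"
            trials.append(("a", resp, t, t + rts[i]))
            t += rts[i] + 0.2
        return ResponseLog(trials, key_map)

    def test_constructed_log_scores(self):
        log = self.make_log(20, 18, [0.5] * 20)
        s = cps_stats(log)
        assert s["n_correct"] == 18 and s["n_total"] == 20
        assert s["accuracy"] == pytest.approx(0.9)
        assert s["rt_mean"] == pytest.approx(0.5)
        assert s["rt_drift"] == pytest.approx(0.0, abs=1e-12)

    def test_empty_log_raises(self):
        with pytest.raises(InsufficientDataError):
            cps_stats(ResponseLog([], {}))

    def test_increasing_rts_positive_drift(self):
        rts = np.linspace(0.4, 0.8, 30).tolist()
        s = cps_stats(self.make_log(30, 30, rts))
        assert s["rt_drift"] > 0

    def test_accuracy_bounds_property(self, rng):
        for _ in range(20):
            n = int(rng.integers(1, 40))
            k = int(rng.integers(0, n + 1))
            s = cps_stats(self.make_log(n, k, [0.5] * n))
            assert 0.0 <= s["accuracy"] <= 1.0
            assert s["n_correct"] <= s["n_total"]


class TestEventStats:
    def test_unit_rate(self):
        s = event_stats(np.arange(10.0))
        assert s["count"] == 10
        assert s["rate"] == pytest.approx(10 / 9)
        assert s["iei_mean"] == pytest.approx(1.0)
        assert s["iei_cv"] == pytest.approx(0.0)

    def test_single_event_no_intervals(self):
        s = event_stats([4.2])
        assert s == {"count": 1}

    def test_empty(self):
        assert event_stats([]) == {"count": 0}
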