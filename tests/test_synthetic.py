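"""Generators: schema validity, determinism, parameter recovery,
corruption operators."""

import json

import numpy as np
import pytest

from sdmkit.io import write_reading
from sdmkit.processing import process
from sdmkit.schema import validate_document
from sdmkit.synthetic import (
    corrupt,
    gen_cps,
    gen_drawing,
    gen_sway,
    gen_turns,
    gen_walk,
    generate,
)


class TestGenerators:
    def test_all_fixtures_schema_valid(self, registry):
        for code in registry.codes():
            reading, truth = generate(code, seed=0)
            validate_document(json.loads(write_reading(reading)))
            assert truth.seed == 0

    def test_same_seed_identical_bytes(self):
        a = write_reading(gen_walk(duration=30.0, seed=9)[0])
        b = write_reading(gen_walk(duration=30.0, seed=9)[0])
        assert a == b
        assert a != write_reading(gen_walk(duration=30.0, seed=10)[0])

    def test_noise_free_walk_peaks_at_analytic_times(self):
        r, _ = gen_walk(cadence=120.0, duration=20.0, fs=100.0,
                        noise_sd=0.0, seed=0)
        from scipy.signal import find_peaks

        z = r.levels[0].datasets["acc"]["z"]
        t = r.levels[0].datasets["acc"]["ts"]
        # vertical maxima of sin(2*pi*2t) at t = 0.125 + k/2; the true
        # maximum falls between two equal samples, so allow half a sample
        peaks, _ = find_peaks(z, prominence=0.5)
        times = t[peaks]
        expected = 0.125 + 0.5 * np.arange(len(times))
        assert len(times) == 40  # one maximum per cycle over 20 s
        assert np.allclose(times, expected[: len(times)], atol=0.006)

    def test_full_drawing_session_16_levels(self):
        r, _ = gen_drawing(shape=None, seed=1)
        assert len(r.levels) == 16
        combos = {(lv.modality_value("shape"), lv.modality_value("hand"),
                   lv.modality_value("attempt")) for lv in r.levels}
        assert len(combos) == 16

    def test_cps_exact_correct_count(self, registry):
        r, truth = gen_cps(n_trials=20, p_correct=0.9, seed=3)
        r, _ = process(r, registry.steps_for("cps"))
        assert r.levels[0].measures["cps-correct"].value == 18
        assert truth.measures["cps-correct"] == 18

    def test_turn_fixture_recovered(self, registry):
        r, _ = gen_turns([180.0], [90.0], seed=0)
        r, _ = process(r, registry.steps_for("utt"))
        ms = r.levels[0].measures
        assert ms["utt-turns"].value == 1
        assert ms["utt-turn_angle-mean"].value == pytest.approx(
            np.pi, abs=0.01
        )


class TestParameterRecovery:
    """Ground-truth parameters are recovered across a seed sweep."""

    def test_cadence_sweep(self, registry):
        steps = registry.steps_for("sixmwt")
        for seed in range(10):
            r, truth = gen_walk(cadence=100.0, duration=60.0, noise_sd=0.05,
                                seed=seed)
            r, _ = process(r, registry.steps_for("sixmwt"))
            est = r.levels[0].measures["sixmwt-cadence"].value
            assert abs(est - 100.0) <= 2.0

    def test_sway_sigma_sweep(self, registry):
        for seed in range(10):
            r, truth = gen_sway(sigma_ap=0.05, sigma_ml=0.05, seed=seed)
            r, _ = process(r, registry.steps_for("sbt"))
            est = r.levels[0].measures["sbt-rms_ap"].value
            assert est == pytest.approx(0.05, rel=0.1)

    def test_cps_accuracy_sweep(self, registry):
        for seed in range(10):
            r, truth = gen_cps(n_trials=30, p_correct=0.8, seed=seed)
            r, _ = process(r, registry.steps_for("cps"))
            est = r.levels[0].measures["cps-accuracy"].value
            assert est == pytest.approx(truth.measures["cps-accuracy"])


class TestCorrupt:
    def test_drop_samples_triggers_sampling_flag(self, registry):
        r, _ = gen_walk(duration=60.0, seed=1)
        rc = corrupt(r, "drop_samples", frac=0.2, seed=1)
        rc, _ = process(rc, registry.steps_for("sixmwt"))
        assert "sixmwt-technical-deviation-unstable_sampling" in rc.flag_ids()

    def test_original_untouched_by_corrupt(self):
        r, _ = gen_walk(duration=30.0, seed=1)
        before = r.content_hash()
        corrupt(r, "flip_orientation")
        assert r.content_hash() == before

    def test_shuffle_timestamps_flagged_on_reload(self):
        from sdmkit.io import read_reading

        r, _ = gen_walk(duration=30.0, seed=1)
        rc = corrupt(r, "shuffle_timestamps", seed=2)
        r2 = read_reading(write_reading(rc))
        assert "sixmwt-technical-deviation-ts_nonmonotone" in r2.flag_ids()

    def test_unknown_mode_rejected(self):
        r, _ = gen_walk(duration=30.0, seed=1)
        with pytest.raises(ValueError):
            corrupt(r, "melt")
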