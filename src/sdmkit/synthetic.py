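"""Synthetic structured-test recordings with known ground truth.

Every generator returns a schema-valid :class:`~sdmkit.model.Reading`
plus a :class:`GroundTruth` recording the true parameter values, the
seed, and the generator settings — so every pipeline can be tested end
to end without any device data.  All randomness flows through one
explicitly seeded ``numpy`` generator; the same seed reproduces the
reading bit for bit.

The walking model is a single vertical harmonic at the step frequency
(amplitude 1 m/s^2) on top of gravity plus white noise — enough to
exercise band-pass step detection and cadence logic, not a biomechanical
gait model.  Corruption operators (sample dropping, orientation flip,
truncation, timestamp shuffling) emulate the technical and behavioral
problems the quality flags are designed to catch.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .model import (
    DeviceSource,
    Level,
    Modality,
    RawDataSet,
    Reading,
    ValueDefinition,
)
from .questionnaires import load_instrument, score_questionnaire

GRAVITY = 9.81

_TS = ValueDefinition("ts", "timestamp", "s", "timestamp")


@dataclass
class GroundTruth:
    """True values behind a synthetic reading."""

    measures: dict[str, float]
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(
            {"measures": self.measures, "seed": self.seed, "params": self.params},
            indent=1,
        )


def _device(sensor: str, fs: Optional[float], placement: str) -> DeviceSource:
    return DeviceSource("synthetic", sensor, fs, placement)


def _acc_dataset(t, x, y, z, fs: float, placement: str = "belt") -> RawDataSet:
    cols = [
        _TS,
        ValueDefinition("x", "acceleration x", "m/s^2"),
        ValueDefinition("y", "acceleration y", "m/s^2"),
        ValueDefinition("z", "acceleration z", "m/s^2"),
    ]
    return RawDataSet(
        "acc", _device("accelerometer", fs, placement), cols, [t, x, y, z]
    )


def _reading(code: str, seed: int, levels: list[Level],
             device_sensor: str = "imu", fs: Optional[float] = None,
             placement: str = "belt") -> Reading:
    return Reading(
        evaluation_code=code,
        subject_id=f"subj{seed:03d}",
        session_id=f"{code}_{seed:03d}",
        device=_device(device_sensor, fs, placement),
        levels=levels,
    )


def gen_walk(
    cadence: float = 108.0,
    duration: float = 360.0,
    fs: float = 100.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    amplitude: float = 1.0,
) -> tuple[Reading, GroundTruth]:
    """Six-minute-walk recording: vertical harmonic at the step frequency.

    The vertical (z) axis carries gravity plus
    ``amplitude * sin(2*pi*(cadence/60)*t)`` and white noise; x and y are
    noise only.  Defaults follow the test protocol: 360 s at 100 Hz with
    the device on a belt.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    step_freq = cadence / 60.0
    z = GRAVITY + amplitude * np.sin(2 * math.pi * step_freq * t)
    if noise_sd > 0:
        z = z + rng.normal(0.0, noise_sd, n)
        x = rng.normal(0.0, noise_sd, n)
        y = rng.normal(0.0, noise_sd, n)
    else:
        x = np.zeros(n)
        y = np.zeros(n)
    level = Level(
        id="main", start=0.0, end=duration,
        context={"protocol_duration": 360.0},
    )
    level.add_dataset(_acc_dataset(t, x, y, z, fs))
    reading = _reading("sixmwt", seed, [level], "accelerometer", fs, "belt")
    truth = GroundTruth(
        measures={
            "sixmwt-cadence": cadence,
            "sixmwt-steps": round(step_freq * duration),
        },
        seed=seed,
        params={"cadence": cadence, "duration": duration, "fs": fs,
                "noise_sd": noise_sd, "amplitude": amplitude},
    )
    return reading, truth


def gen_sway(
    sigma_ap: float = 0.05,
    sigma_ml: float = 0.05,
    duration: float = 60.0,
    fs: float = 100.0,
    seed: int = 0,
) -> tuple[Reading, GroundTruth]:
    """Static-balance recording: iid Gaussian AP (x) / ML (y) acceleration
    around gravity on +z."""
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    t = np.arange(n) / fs
    x = rng.normal(0.0, sigma_ap, n)
    y = rng.normal(0.0, sigma_ml, n)
    z = GRAVITY + rng.normal(0.0, 0.01, n)
    level = Level(id="main", start=0.0, end=duration)
    level.add_dataset(_acc_dataset(t, x, y, z, fs))
    reading = _reading("sbt", seed, [level], "accelerometer", fs, "belt")
    from .mobility import CHI2_95_2DF

    truth = GroundTruth(
        measures={
            "sbt-rms_ap": sigma_ap,
            "sbt-rms_ml": sigma_ml,
            "sbt-ellipse_area": math.pi * CHI2_95_2DF * sigma_ap * sigma_ml,
        },
        seed=seed,
        params={"sigma_ap": sigma_ap, "sigma_ml": sigma_ml,
                "duration": duration, "fs": fs},
    )
    return reading, truth


def gen_turns(
    angles_deg: Sequence[float] = (180.0, -180.0),
    rates_deg: Sequence[float] = (90.0, 90.0),
    fs: float = 100.0,
    gap: float = 3.0,
    seed: int = 0,
    noise_sd: float = 0.0,
) -> tuple[Reading, GroundTruth]:
    """U-turn recording: piecewise-constant yaw rate.

    Each turn k rotates through ``angles_deg[k]`` at a constant
    ``rates_deg[k]`` (sign taken from the angle), separated by ``gap``
    seconds of zero rate.
    """
    if len(angles_deg) != len(rates_deg):
        raise ValueError("need one rate per angle")
    rng = np.random.default_rng(seed)
    pieces = [np.zeros(int(round(gap * fs)))]
    for angle, rate in zip(angles_deg, rates_deg):
        dur = abs(angle) / abs(rate)
        w = math.copysign(math.radians(abs(rate)), angle)
        pieces.append(np.full(int(round(dur * fs)), w))
        pieces.append(np.zeros(int(round(gap * fs))))
    yaw = np.concatenate(pieces)
    if noise_sd > 0:
        yaw = yaw + rng.normal(0.0, noise_sd, yaw.size)
    n = yaw.size
    t = np.arange(n) / fs
    cols = [_TS, ValueDefinition("yaw", "yaw rate", "rad/s")]
    ds = RawDataSet("gyro", _device("gyroscope", fs, "belt"), cols, [t, yaw])
    level = Level(id="main", start=0.0, end=n / fs)
    level.add_dataset(ds)
    reading = _reading("utt", seed, [level], "gyroscope", fs, "belt")
    truth = GroundTruth(
        measures={"utt-turns": len(angles_deg)},
        seed=seed,
        params={"angles_deg": list(angles_deg), "rates_deg": list(rates_deg),
                "fs": fs, "gap": gap},
    )
    return reading, truth


# -- drawing ---------------------------------------------------------------

SHAPES = ("square", "circle", "spiral", "infinity")


def reference_shape(shape: str, size: float = 200.0, n: int = 100) -> np.ndarray:
    """Reference polyline of a drawing shape, centred at the origin,
    in screen units (px)."""
    if shape == "square":
        h = size / 2
        corners = np.array(
            [[-h, -h], [h, -h], [h, h], [-h, h], [-h, -h]], dtype=float
        )
        per_side = max(2, n // 4)
        pts = [
            np.linspace(corners[i], corners[i + 1], per_side, endpoint=False)
            for i in range(4)
        ]
        return np.vstack(pts + [corners[-1:]])
    theta = np.linspace(0.0, 2 * math.pi, n)
    if shape == "circle":
        r = size / 2
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    if shape == "spiral":
        r = np.linspace(0.1 * size, 0.5 * size, n)
        theta = np.linspace(0.0, 4 * math.pi, n)
        return np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    if shape == "infinity":
        # lemniscate of Gerono
        a = size / 2
        return np.column_stack(
            [a * np.cos(theta), a * np.sin(theta) * np.cos(theta)]
        )
    raise ValueError(f"unknown shape {shape!r}; choose from {SHAPES}")


def _drawing_level(shape: str, hand: str, attempt: str, jitter_sd: float,
                   rng: np.random.Generator, t0: float,
                   duration: float = 5.0, fs: float = 60.0) -> Level:
    ref = reference_shape(shape)
    n = int(round(duration * fs))
    from .upperlimb import arc_length_resample

    path = arc_length_resample(ref, n)
    if jitter_sd > 0:
        path = path + rng.normal(0.0, jitter_sd, path.shape)
    t = t0 + np.arange(n) / fs
    cols = [
        _TS,
        ValueDefinition("x", "touch x", "px"),
        ValueDefinition("y", "touch y", "px"),
    ]
    ds = RawDataSet(
        "touch", _device("touchscreen", fs, "handheld"), cols,
        [t, path[:, 0], path[:, 1]],
    )
    level = Level(
        id=f"{shape}_{hand}_{attempt}",
        modalities=[
            Modality("shape", shape),
            Modality("hand", hand),
            Modality("attempt", attempt),
        ],
        start=t0,
        end=t0 + duration,
        context={"reference": ref.tolist()},
    )
    level.add_dataset(ds)
    return level


def gen_drawing(
    shape: Optional[str] = None,
    jitter_sd: float = 2.0,
    hand: str = "right",
    attempt: str = "first",
    seed: int = 0,
) -> tuple[Reading, GroundTruth]:
    """Drawing recording.

    With ``shape`` given, a single level; with ``shape=None``, the full
    evaluation of 16 levels (4 shapes x 2 hands x 2 attempts).  The
    drawn trace is the reference arc-length path plus Gaussian jitter.
    """
    rng = np.random.default_rng(seed)
    levels = []
    t0 = 0.0
    if shape is None:
        for sh in SHAPES:
            for hd in ("right", "left"):
                for at in ("first", "second"):
                    levels.append(
                        _drawing_level(sh, hd, at, jitter_sd, rng, t0)
                    )
                    t0 += 6.0
    else:
        levels.append(_drawing_level(shape, hand, attempt, jitter_sd, rng, 0.0))
    reading = _reading("draw", seed, levels, "touchscreen", 60.0, "handheld")
    truth = GroundTruth(
        measures={},
        seed=seed,
        params={"shape": shape, "jitter_sd": jitter_sd, "n_levels": len(levels)},
    )
    return reading, truth


def gen_cps(
    n_trials: int = 30,
    p_correct: float = 0.9,
    rt_mean: float = 0.6,
    rt_sd: float = 0.1,
    seed: int = 0,
) -> tuple[Reading, GroundTruth]:
    """Symbol-digit substitution log with an exact number of correct
    trials: round(p_correct * n_trials)."""
    rng = np.random.default_rng(seed)
    symbols = [f"sym{k}" for k in range(1, 10)]
    key_map = {s: str(k + 1) for k, s in enumerate(symbols)}
    n_correct = int(round(p_correct * n_trials))
    wrong = set(rng.choice(n_trials, size=n_trials - n_correct, replace=False))
    t_shown, stimulus, response, t_answered = [], [], [], []
    t = 0.0
    for i in range(n_trials):
        stim = symbols[int(rng.integers(len(symbols)))]
        rt = max(0.1, float(rng.normal(rt_mean, rt_sd)))
        resp = key_map[stim]
        if i in wrong:
            resp = str((int(resp) % 9) + 1)  # guaranteed incorrect digit
        t_shown.append(t)
        stimulus.append(stim)
        response.append(resp)
        t_answered.append(t + rt)
        t += rt + 0.2
    cols = [
        _TS,
        ValueDefinition("stimulus", "shown symbol", "", "string"),
        ValueDefinition("response", "entered digit", "", "string"),
        ValueDefinition("t_answered", "response time", "s"),
    ]
    ds = RawDataSet(
        "responses", _device("touchscreen", None, "handheld"), cols,
        [t_shown, stimulus, response, t_answered],
    )
    level = Level(id="main", start=0.0, end=t, context={"key_map": key_map})
    level.add_dataset(ds)
    reading = _reading("cps", seed, [level], "touchscreen", None, "handheld")
    truth = GroundTruth(
        measures={
            "cps-correct": n_correct,
            "cps-total": n_trials,
            "cps-accuracy": n_correct / n_trials,
        },
        seed=seed,
        params={"n_trials": n_trials, "p_correct": p_correct,
                "rt_mean": rt_mean, "rt_sd": rt_sd},
    )
    return reading, truth


def gen_pinch(
    n_pinches: int = 3,
    n_failures: int = 0,
    fs: float = 50.0,
    seed: int = 0,
) -> tuple[Reading, GroundTruth]:
    """Pinch recording: two contacts converging (success) or staying
    apart (failure); one-second pauses between attempts."""
    target = 50.0
    t_rows, cid_rows, x_rows, y_rows = [], [], [], []
    t0 = 0.5
    total = n_pinches + n_failures
    for k in range(total):
        success = k < n_pinches
        n = int(round(0.5 * fs))
        for i in range(n):
            frac = i / max(n - 1, 1)
            d0 = 200.0
            d1 = 10.0 if success else 120.0
            d = d0 + (d1 - d0) * frac
            tt = t0 + i / fs
            for cid, sign in ((0, -0.5), (1, 0.5)):
                t_rows.append(tt)
                cid_rows.append(cid)
                x_rows.append(sign * d)
                y_rows.append(0.0)
        t0 += 0.5 + 1.0
    cols = [
        _TS,
        ValueDefinition("contact", "contact id", "", "int"),
        ValueDefinition("x", "touch x", "px"),
        ValueDefinition("y", "touch y", "px"),
    ]
    ds = RawDataSet(
        "touch", _device("touchscreen", fs, "handheld"), cols,
        [t_rows, cid_rows, x_rows, y_rows],
    )
    level = Level(
        id="main", start=0.0, end=t0, context={"target_distance": target}
    )
    level.add_dataset(ds)
    reading = _reading("pinch", seed, [level], "touchscreen", fs, "handheld")
    truth = GroundTruth(
        measures={
            "pinch-attempts": total,
            "pinch-successes": n_pinches,
            "pinch-success_rate": n_pinches / total if total else 0.0,
        },
        seed=seed,
        params={"n_pinches": n_pinches, "n_failures": n_failures},
    )
    return reading, truth


def gen_events(
    task: str = "tap",
    n_events: int = 20,
    interval: float = 0.5,
    jitter_sd: float = 0.02,
    seed: int = 0,
) -> tuple[Reading, GroundTruth]:
    """Event-based recording (tapping, typing, grip, sit-to-stand):
    one timestamp per repetition, roughly ``interval`` s apart."""
    rng = np.random.default_rng(seed)
    t = np.arange(n_events) * interval
    if jitter_sd > 0:
        t = np.sort(t + rng.normal(0.0, jitter_sd, n_events))
        t = t - t[0]
    ds = RawDataSet(
        "events", _device("touchscreen", None, "handheld"), [_TS], [t]
    )
    level = Level(id="main", start=0.0, end=float(t[-1]) if n_events else 0.0)
    level.add_dataset(ds)
    reading = _reading(task, seed, [level], "touchscreen", None, "handheld")
    truth = GroundTruth(
        measures={f"{task}-events": n_events},
        seed=seed,
        params={"interval": interval, "jitter_sd": jitter_sd},
    )
    return reading, truth


def gen_questionnaire(
    instrument: str = "msis29",
    answers: Optional[Sequence[float]] = None,
    seed: int = 0,
) -> tuple[Reading, GroundTruth]:
    """Questionnaire recording; random in-range answers when none given."""
    config = load_instrument(instrument)
    rng = np.random.default_rng(seed)
    if answers is None:
        answers = rng.integers(
            int(config.item_min), int(config.item_max) + 1, config.n_items
        ).tolist()
    answers = [float(a) for a in answers]
    t = np.arange(config.n_items) * 2.0
    cols = [
        _TS,
        ValueDefinition("item", "item number", "", "int"),
        ValueDefinition("answer", "answer value", ""),
    ]
    ds = RawDataSet(
        "answers", _device("touchscreen", None, "handheld"), cols,
        [t, list(range(1, config.n_items + 1)), answers],
    )
    level = Level(id="main", start=0.0, end=float(t[-1]))
    level.add_dataset(ds)
    reading = _reading(instrument, seed, [level], "touchscreen", None, "handheld")
    scores = score_questionnaire(config, answers)
    truth = GroundTruth(
        measures={f"{instrument}-{k}": v for k, v in scores.items()},
        seed=seed,
        params={"answers": answers},
    )
    return reading, truth


# -- dispatcher ------------------------------------------------------------

_QUESTIONNAIRES = ("msis29", "alsfrs_r", "pdq39", "mood", "fatigue", "qol")


def generate(code: str, seed: int = 0, **kwargs) -> tuple[Reading, GroundTruth]:
    """Generate a default fixture for any registered evaluation code."""
    if code == "sixmwt":
        return gen_walk(seed=seed, **kwargs)
    if code == "sbt":
        return gen_sway(seed=seed, **kwargs)
    if code == "utt":
        return gen_turns(seed=seed, **kwargs)
    if code == "draw":
        return gen_drawing(seed=seed, **kwargs)
    if code == "cps":
        return gen_cps(seed=seed, **kwargs)
    if code == "pinch":
        return gen_pinch(seed=seed, **kwargs)
    if code in ("tap", "typing", "grip", "sts"):
        defaults = {"tap": 0.3, "typing": 0.4, "grip": 1.5, "sts": 2.0}
        kwargs.setdefault("interval", defaults[code])
        return gen_events(task=code, seed=seed, **kwargs)
    if code in _QUESTIONNAIRES:
        return gen_questionnaire(instrument=code, seed=seed, **kwargs)
    raise KeyError(f"no generator for evaluation code {code!r}")


# -- corruption operators --------------------------------------------------

def _rebuild_dataset(ds: RawDataSet, new_data: dict) -> RawDataSet:
    return RawDataSet(
        ds.id, ds.source, ds.columns, [new_data[c.id] for c in ds.columns]
    )


def corrupt(reading: Reading, mode: str, frac: float = 0.2,
            seed: int = 0) -> Reading:
    """Return a corrupted deep copy of a reading.

    Modes: ``drop_samples`` removes a random fraction of rows from every
    dataset (unstable sampling); ``flip_orientation`` negates the z
    acceleration (device worn upside down); ``truncate`` keeps only the
    first ``frac`` of every dataset (abandoned test); and
    ``shuffle_timestamps`` permutes the timestamp column (broken clock).
    """
    rng = np.random.default_rng(seed)
    out = reading.copy()
    for level in out.levels:
        for ds_id in list(level.datasets):
            ds = level.datasets[ds_id]
            n = len(ds)
            if mode == "drop_samples":
                keep = np.sort(
                    rng.choice(n, size=max(2, int(round(n * (1 - frac)))),
                               replace=False)
                )
                new = {c.id: ds[c.id][keep] for c in ds.columns}
            elif mode == "flip_orientation":
                if "z" not in {c.id for c in ds.columns}:
                    continue
                new = {c.id: ds[c.id].copy() for c in ds.columns}
                new["z"] = -new["z"]
            elif mode == "truncate":
                keep_n = max(2, int(round(n * frac)))
                new = {c.id: ds[c.id][:keep_n] for c in ds.columns}
            elif mode == "shuffle_timestamps":
                new = {c.id: ds[c.id].copy() for c in ds.columns}
                ts_col = ds.columns[0].id
                new[ts_col] = rng.permutation(new[ts_col])
            else:
                raise ValueError(f"unknown corruption mode {mode!r}")
            level.datasets[ds_id] = _rebuild_dataset(ds, new)
    return out
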