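"""Sensor-derived measures for mobility tests with a belt-worn device.

Three structured tests are covered:

* six-minute walk ("sixmwt") — step detection on the signed vertical
  (gravity-axis) acceleration: zero-phase band-pass 0.5–5 Hz, then local
  maxima with prominence and separation constraints; cadence in
  steps/min.
* U-turn test ("utt") — turns found by integrating the yaw rate over
  intervals where it stays above a rate threshold (trapezoidal rule,
  extended one sample into the entry/exit ramps) and keeping intervals
  whose absolute angle reaches the minimum turn angle.
* static balance test ("sbt") — postural sway summarized by RMS
  anterior-posterior (AP) and medio-lateral (ML) acceleration, the 95%
  confidence ellipse area pi * 5.991 * sqrt(lambda1 * lambda2) of the
  (AP, ML) covariance eigenvalues, and resultant jerk RMS.

The device sits on the lower back in a running belt: gravity on +z, AP
on x, ML on y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.signal import find_peaks

from .config import DEFAULT_THRESHOLDS, Thresholds
from .errors import InsufficientDataError
from .model import (
    Flag,
    FlagTarget,
    Level,
    LevelEpoch,
    MeasureValue,
    RawDataSet,
    Reading,
    ValueDefinition,
    generate_measure_id,
)
from .processing import ProcessingStep
from .signal import (
    bandpass_zero_phase,
    flag_orientation,
    flag_sampling,
    sampling_stats,
)

#: 95% quantile of the chi-square distribution with 2 degrees of freedom
CHI2_95_2DF = 5.991


@dataclass(frozen=True)
class StepEvents:
    """Detected heel-strike surrogates on a gait acceleration series."""

    times: tuple[float, ...]
    count: int
    cadence: float  # steps/min
    step_time_cv: Optional[float]  # std/mean of successive step times


@dataclass(frozen=True)
class TurnEpoch:
    """One detected turn: signed angle (rad), duration (s), peak rate."""

    start: float
    end: float
    angle: float
    duration: float
    peak_rate: float


@dataclass(frozen=True)
class SwayMetrics:
    rms_ap: float  # m/s^2
    rms_ml: float  # m/s^2
    ellipse_area: float  # (m/s^2)^2
    jerk_rms: float  # m/s^3


def detect_steps(
    acc_norm,
    fs: float,
    min_prominence: float = 0.3,
    min_separation: float = 0.25,
    band: tuple[float, float] = (0.5, 5.0),
) -> StepEvents:
    """Detect steps on a gravity-removed gait acceleration series.

    The signal is band-passed (zero phase) to the locomotor band, then
    local maxima with at least ``min_prominence`` m/s^2 prominence and
    ``min_separation`` s separation are counted as steps.  Cadence is
    60 * count / signal duration; the step-time coefficient of variation
    needs at least 3 steps and is None otherwise.
    """
    x = np.asarray(acc_norm, dtype=float)
    duration = x.size / fs
    if duration < 5.0:
        raise InsufficientDataError(
            f"step detection needs >= 5 s of signal, got {duration:.2f} s"
        )
    filtered = bandpass_zero_phase(x, fs, order=2, low_hz=band[0], high_hz=band[1])
    peaks, _ = find_peaks(
        filtered,
        prominence=min_prominence,
        distance=max(1, int(round(min_separation * fs))),
    )
    times = peaks / fs
    count = int(peaks.size)
    cadence = 60.0 * count / duration
    cv = None
    if count >= 3:
        dt = np.diff(times)
        cv = float(np.std(dt) / np.mean(dt)) if np.mean(dt) > 0 else None
    return StepEvents(tuple(float(t) for t in times), count, cadence, cv)


def detect_turns(
    gyro_yaw,
    fs: float,
    min_angle: float = math.radians(160.0),
    rate_threshold: float = math.radians(15.0),
) -> list[TurnEpoch]:
    """Detect turns by integrating yaw rate over high-rate intervals.

    Contiguous runs where |rate| >= ``rate_threshold`` are extended one
    sample into the surrounding low-rate signal (capturing the entry and
    exit ramps) and integrated with the trapezoidal rule; intervals with
    |angle| >= ``min_angle`` become epochs.  Epochs are non-overlapping
    and time-ordered; the angle keeps the sign of the rate.
    """
    w = np.asarray(gyro_yaw, dtype=float)
    above = np.abs(w) >= rate_threshold
    if not np.any(above):
        return []
    # run boundaries of the boolean mask
    padded = np.diff(above.astype(int), prepend=0, append=0)
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1  # inclusive
    epochs: list[TurnEpoch] = []
    prev_end = -1
    for s, e in zip(starts, ends):
        s_ext = max(s - 1, prev_end + 1, 0)
        e_ext = min(e + 1, w.size - 1)
        angle = float(np.trapezoid(w[s_ext : e_ext + 1], dx=1.0 / fs))
        if abs(angle) < min_angle:
            prev_end = e
            continue
        seg = w[s : e + 1]
        peak = float(seg[np.argmax(np.abs(seg))])
        epochs.append(
            TurnEpoch(
                start=s_ext / fs,
                end=e_ext / fs,
                angle=angle,
                duration=(e_ext - s_ext) / fs,
                peak_rate=peak,
            )
        )
        prev_end = e_ext
    return epochs


def sway_metrics(acc_ap, acc_ml, fs: float) -> SwayMetrics:
    """Postural sway metrics from AP and ML acceleration during quiet
    standing.

    Means are removed before computing the RMS values and the 2x2
    covariance; the 95% confidence ellipse area is
    pi * chi2(0.95, 2) * sqrt(lambda1 * lambda2) with lambda_i the
    covariance eigenvalues.  Jerk is the first difference divided by the
    sample interval; its RMS is taken on the AP/ML resultant.
    """
    ap = np.asarray(acc_ap, dtype=float)
    ml = np.asarray(acc_ml, dtype=float)
    if ap.size != ml.size:
        raise ValueError("AP and ML series must have equal length")
    if ap.size / fs < 10.0:
        raise InsufficientDataError(
            f"sway metrics need >= 10 s of signal, got {ap.size / fs:.2f} s"
        )
    ap = ap - ap.mean()
    ml = ml - ml.mean()
    rms_ap = float(np.sqrt(np.mean(ap**2)))
    rms_ml = float(np.sqrt(np.mean(ml**2)))
    cov = np.cov(np.vstack([ap, ml]))
    eigvals = np.linalg.eigvalsh(cov)
    eigvals = np.clip(eigvals, 0.0, None)
    area = float(math.pi * CHI2_95_2DF * math.sqrt(eigvals[0] * eigvals[1]))
    dt = 1.0 / fs
    jerk = np.sqrt(np.diff(ap) ** 2 + np.diff(ml) ** 2) / dt
    jerk_rms = float(np.sqrt(np.mean(jerk**2))) if jerk.size else 0.0
    return SwayMetrics(rms_ap, rms_ml, area, jerk_rms)


# ---------------------------------------------------------------------------
# measure helpers and pipeline step factories
# ---------------------------------------------------------------------------

def _measure(task, level, abbr, name, value, unit="", agg=None) -> MeasureValue:
    mid = generate_measure_id(task, level.modalities, abbr, agg)
    return MeasureValue(ValueDefinition(mid, name, unit), value)


def _fs_of(ds: RawDataSet, default: float = 100.0) -> float:
    ts = ds.timestamps
    if ts.size >= 3:
        med = float(np.median(np.diff(ts)))
        if med > 0:
            return 1.0 / med
    return ds.source.sampling_freq or default


def _sampling_flag_func(task: str, dataset_id: str, thresholds: Thresholds):
    def func(level: Level, reading: Reading, params: dict):
        ds = level.datasets[dataset_id]
        try:
            stats = sampling_stats(ds.timestamps, ds.source.sampling_freq or 0.0)
        except InsufficientDataError:
            return []
        nominal = ds.source.sampling_freq or stats.median_freq
        flag = flag_sampling(
            stats,
            nominal,
            task=task,
            target=FlagTarget("dataset", level.id, dataset_id),
            thresholds=thresholds,
        )
        return [flag] if flag else []

    return func


def _orientation_flag_func(task: str, dataset_id: str, thresholds: Thresholds):
    def func(level: Level, reading: Reading, params: dict):
        ds = level.datasets[dataset_id]
        acc = np.column_stack([ds["x"], ds["y"], ds["z"]])
        flag = flag_orientation(
            acc,
            "z",
            +1,
            task=task,
            target=FlagTarget("dataset", level.id, dataset_id),
            thresholds=thresholds,
        )
        return [flag] if flag else []

    return func


def _duration_flag_func(task: str, dataset_id: str, thresholds: Thresholds,
                        default_protocol: float):
    def func(level: Level, reading: Reading, params: dict):
        ds = level.datasets[dataset_id]
        ts = ds.timestamps
        if ts.size < 2:
            return []
        span = float(ts[-1] - ts[0])
        protocol = float(level.context.get("protocol_duration", default_protocol))
        if span < thresholds.too_short_fraction * protocol:
            return [
                Flag(
                    id=f"{task}-behavioral-invalidation-too_short",
                    reason=(
                        f"recording spans {span:.1f} s, below "
                        f"{thresholds.too_short_fraction:.0%} of the "
                        f"{protocol:.0f} s protocol"
                    ),
                    targets=[FlagTarget("dataset", level.id, dataset_id)],
                )
            ]
        return []

    return func


def _acc_vertical_transform(level: Level, reading: Reading, params: dict):
    """Signed projection of gravity-removed acceleration onto the gravity
    axis.  Step detection uses this rather than the Euclidean norm: the
    norm rectifies the vertical oscillation (two maxima per step cycle),
    while the signed vertical component keeps one impact peak per step.
    """
    ds = level.datasets["acc"]
    acc = np.column_stack([ds["x"], ds["y"], ds["z"]])
    gravity = np.median(acc, axis=0)
    g_norm = np.linalg.norm(gravity)
    if g_norm == 0:
        vertical = np.zeros(len(ds))
    else:
        vertical = (acc - gravity) @ (gravity / g_norm)
    out = RawDataSet(
        "acc_vertical",
        ds.source,
        [
            ValueDefinition("ts", "timestamp", "s", "timestamp"),
            ValueDefinition("vertical", "vertical acceleration", "m/s^2"),
        ],
        [ds.timestamps.copy(), vertical],
    )
    return [out]


def _gait_extract_func(thresholds: Thresholds):
    def func(level: Level, reading: Reading, params: dict):
        ds = level.datasets["acc_vertical"]
        fs = _fs_of(ds)
        try:
            steps = detect_steps(
                ds["vertical"],
                fs,
                min_prominence=thresholds.step_min_prominence,
                min_separation=thresholds.step_min_separation,
                band=(thresholds.step_band_low_hz, thresholds.step_band_high_hz),
            )
        except InsufficientDataError as exc:
            return [
                Flag(
                    id="sixmwt-technical-invalidation-insufficient_data",
                    reason=str(exc),
                    targets=[FlagTarget("dataset", level.id, "acc_vertical")],
                )
            ]
        out = [
            _measure("sixmwt", level, "steps", "step count", steps.count),
            _measure(
                "sixmwt", level, "cadence", "cadence", steps.cadence, "steps/min"
            ),
        ]
        if steps.step_time_cv is not None:
            out.append(
                _measure(
                    "sixmwt", level, "step_time_cv",
                    "step time coefficient of variation", steps.step_time_cv,
                )
            )
        # minute-wise cadence, half-open windows [k*60, (k+1)*60)
        duration = len(ds) / fs
        times = np.asarray(steps.times)
        per_minute = []
        k = 0
        while k * 60.0 < duration:
            lo, hi = k * 60.0, min((k + 1) * 60.0, duration)
            n = int(np.sum((times >= lo) & (times < hi)))
            per_minute.append(60.0 * n / (hi - lo))
            k += 1
        if per_minute:
            for agg, fn in (("min", min), ("max", max), ("mean", np.mean)):
                out.append(
                    _measure(
                        "sixmwt", level, "cadence",
                        f"per-minute cadence {agg}", float(fn(per_minute)),
                        "steps/min", agg=agg,
                    )
                )
        return out

    return func


def _turn_extract_func(thresholds: Thresholds):
    def func(level: Level, reading: Reading, params: dict):
        ds = level.datasets["gyro"]
        fs = _fs_of(ds)
        turns = detect_turns(
            ds["yaw"],
            fs,
            min_angle=math.radians(thresholds.turn_min_angle_deg),
            rate_threshold=math.radians(thresholds.turn_rate_threshold_deg),
        )
        out: list = [
            LevelEpoch(
                ValueDefinition("turn", "detected turn", ""),
                t.start,
                t.end,
                payload={
                    "angle": t.angle,
                    "duration": t.duration,
                    "peak_rate": t.peak_rate,
                },
            )
            for t in turns
        ]
        out.append(_measure("utt", level, "turns", "turn count", len(turns)))
        if turns:
            angles = [abs(t.angle) for t in turns]
            durations = [t.duration for t in turns]
            rates = [abs(t.peak_rate) for t in turns]
            out += [
                _measure("utt", level, "turn_angle", "mean absolute turn angle",
                         float(np.mean(angles)), "rad", agg="mean"),
                _measure("utt", level, "turn_duration", "mean turn duration",
                         float(np.mean(durations)), "s", agg="mean"),
                _measure("utt", level, "turn_peak_rate", "mean peak turn rate",
                         float(np.mean(rates)), "rad/s", agg="mean"),
            ]
        return out

    return func


def _sway_extract_func(thresholds: Thresholds):
    def func(level: Level, reading: Reading, params: dict):
        ds = level.datasets["acc"]
        fs = _fs_of(ds)
        try:
            m = sway_metrics(ds["x"], ds["y"], fs)
        except InsufficientDataError as exc:
            return [
                Flag(
                    id="sbt-technical-invalidation-insufficient_data",
                    reason=str(exc),
                    targets=[FlagTarget("dataset", level.id, "acc")],
                )
            ]
        return [
            _measure("sbt", level, "rms_ap", "RMS AP acceleration",
                     m.rms_ap, "m/s^2"),
            _measure("sbt", level, "rms_ml", "RMS ML acceleration",
                     m.rms_ml, "m/s^2"),
            _measure("sbt", level, "ellipse_area",
                     "95% confidence sway ellipse area",
                     m.ellipse_area, "(m/s^2)^2"),
            _measure("sbt", level, "jerk_rms", "resultant jerk RMS",
                     m.jerk_rms, "m/s^3"),
        ]

    return func


def sixmwt_steps(thresholds: Thresholds = DEFAULT_THRESHOLDS) -> list[ProcessingStep]:
    """Pipeline for the six-minute walk test (accelerometer dataset 'acc')."""
    return [
        ProcessingStep(
            "check_sampling", "flag",
            _sampling_flag_func("sixmwt", "acc", thresholds),
            input_ids=["acc"],
        ),
        ProcessingStep(
            "check_orientation", "flag",
            _orientation_flag_func("sixmwt", "acc", thresholds),
            input_ids=["acc"],
        ),
        ProcessingStep(
            "check_duration", "flag",
            _duration_flag_func("sixmwt", "acc", thresholds, 360.0),
            input_ids=["acc"],
            params={"protocol_duration": 360.0,
                    "min_fraction": thresholds.too_short_fraction},
        ),
        ProcessingStep(
            "acc_vertical", "transform", _acc_vertical_transform,
            input_ids=["acc"], output_ids=["acc_vertical"],
        ),
        ProcessingStep(
            "gait", "extract", _gait_extract_func(thresholds),
            input_ids=["acc_vertical"],
            output_ids=["sixmwt-steps", "sixmwt-cadence", "sixmwt-step_time_cv"],
            params={"band_hz": [thresholds.step_band_low_hz,
                                thresholds.step_band_high_hz],
                    "min_prominence": thresholds.step_min_prominence,
                    "min_separation": thresholds.step_min_separation},
        ),
    ]


def utt_steps(thresholds: Thresholds = DEFAULT_THRESHOLDS) -> list[ProcessingStep]:
    """Pipeline for the U-turn test (gyroscope dataset 'gyro')."""
    return [
        ProcessingStep(
            "check_sampling", "flag",
            _sampling_flag_func("utt", "gyro", thresholds),
            input_ids=["gyro"],
        ),
        ProcessingStep(
            "turns", "extract", _turn_extract_func(thresholds),
            input_ids=["gyro"],
            output_ids=["utt-turns"],
            params={"min_angle_deg": thresholds.turn_min_angle_deg,
                    "rate_threshold_deg": thresholds.turn_rate_threshold_deg},
        ),
    ]


def sbt_steps(thresholds: Thresholds = DEFAULT_THRESHOLDS) -> list[ProcessingStep]:
    """Pipeline for the static balance test (accelerometer dataset 'acc')."""
    return [
        ProcessingStep(
            "check_sampling", "flag",
            _sampling_flag_func("sbt", "acc", thresholds),
            input_ids=["acc"],
        ),
        ProcessingStep(
            "check_orientation", "flag",
            _orientation_flag_func("sbt", "acc", thresholds),
            input_ids=["acc"],
        ),
        ProcessingStep(
            "sway", "extract", _sway_extract_func(thresholds),
            input_ids=["acc"],
            output_ids=["sbt-rms_ap", "sbt-rms_ml", "sbt-ellipse_area",
                        "sbt-jerk_rms"],
        ),
    ]
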