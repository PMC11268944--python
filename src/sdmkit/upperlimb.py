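"""Upper-limb and cognition measures: drawing, pinching, symbol-digit
substitution, and generic event-based tests (tapping, typing, grip,
sit-to-stand).

Drawing similarity compares the drawn trajectory with the reference shape
after arc-length resampling both to a common number of points: ``sim`` is
the mean Euclidean distance between index-paired points, ``dtw_sim`` the
dynamic-time-warping path-averaged distance (full unconstrained DP with
Euclidean local cost).  DTW relaxes the index coupling, so
``dtw_sim <= sim`` always.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import numpy as np

from .errors import InsufficientDataError
from .model import (
    Flag,
    FlagTarget,
    Level,
    MeasureValue,
    Reading,
    ValueDefinition,
    generate_measure_id,
)
from .processing import ProcessingStep

#: traces longer than this are arc-length-downsampled before DTW
DTW_MAX_POINTS = 2000


def arc_length_resample(points, n_points: int) -> np.ndarray:
    """Resample a polyline to ``n_points`` equally spaced along its arc.

    Degenerate polylines (zero total length) are resampled to repeats of
    the first point.  Input (n, 2); output (n_points, 2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
        raise ValueError("need an (n >= 2, 2) polyline")
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0.0:
        return np.repeat(pts[:1], n_points, axis=0)
    grid = np.linspace(0.0, total, n_points)
    return np.column_stack(
        [np.interp(grid, s, pts[:, 0]), np.interp(grid, s, pts[:, 1])]
    )


def dtw_distance(a, b) -> float:
    """Path-averaged DTW distance between two 2-D trajectories.

    Full (unconstrained) dynamic-programming alignment with Euclidean
    local cost; the accumulated cost of the optimal path is divided by
    the path length.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n, m = len(a), len(b)
    cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = cost[i, j] + best
    # backtrack for path length
    i, j = n - 1, m - 1
    length = 1
    while i > 0 or j > 0:
        candidates = []
        if i > 0 and j > 0:
            candidates.append((acc[i - 1, j - 1], i - 1, j - 1))
        if i > 0:
            candidates.append((acc[i - 1, j], i - 1, j))
        if j > 0:
            candidates.append((acc[i, j - 1], i, j - 1))
        _, i, j = min(candidates, key=lambda c: c[0])
        length += 1
    return float(acc[n - 1, m - 1] / length)


@dataclass(frozen=True)
class DrawingSimilarity:
    sim: float  # mean paired point distance, screen units
    dtw_sim: float  # DTW path-averaged distance, screen units
    duration: float  # s


def drawing_similarity(
    trace_t, trace_xy, reference_xy, n_points: int = 100
) -> DrawingSimilarity:
    """Similarity of a drawn trace to its reference shape.

    Both polylines are arc-length-resampled to ``n_points``; ``sim``
    pairs points by index, ``dtw_sim`` aligns them by DTW.  ``duration``
    is the drawing time t_last - t_first.
    """
    t = np.asarray(trace_t, dtype=float)
    xy = np.asarray(trace_xy, dtype=float)
    if len(xy) < 2:
        raise InsufficientDataError("drawing trace needs >= 2 points")
    n_points = min(n_points, DTW_MAX_POINTS)
    a = arc_length_resample(xy, n_points)
    b = arc_length_resample(np.asarray(reference_xy, float), n_points)
    sim = float(np.mean(np.linalg.norm(a - b, axis=1)))
    dtw = dtw_distance(a, b)
    return DrawingSimilarity(sim, dtw, float(t[-1] - t[0]))


@dataclass(frozen=True)
class PinchStats:
    attempts: int
    successes: int
    success_rate: Optional[float]
    mean_interval: Optional[float]  # s between successive attempt starts
    single_finger: bool


def pinch_stats(
    times, contact_ids, xs, ys, target_distance: float,
    gap_threshold: float = 0.5,
) -> PinchStats:
    """Pinch attempts and successes from a two-finger touch stream.

    An attempt is a maximal interval with two simultaneous contacts; a
    pause longer than ``gap_threshold`` s (fingers lifted) ends the
    attempt.  An attempt succeeds when the inter-contact distance
    shrinks below ``target_distance``.  ``single_finger`` is set when no
    two contacts are ever simultaneous (behavioral deviation: the test
    requires two fingers).
    """
    t = np.asarray(times, dtype=float)
    cid = np.asarray(contact_ids)
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    uniq = np.unique(t)
    two = np.zeros(uniq.size, dtype=bool)
    min_dist = np.full(uniq.size, np.inf)
    for k, tu in enumerate(uniq):
        rows = np.flatnonzero(t == tu)
        if len(set(cid[rows].tolist())) >= 2:
            two[k] = True
            pts = np.column_stack([x[rows], y[rows]])
            d = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            min_dist[k] = d[np.triu_indices(len(rows), 1)].min()
    if not np.any(two):
        return PinchStats(0, 0, None, None, single_finger=t.size > 0)
    # a lifted pause (long gap between samples) also ends an attempt
    gap_break = np.zeros(uniq.size, dtype=bool)
    gap_break[1:] = np.diff(uniq) > gap_threshold
    padded = np.diff(two.astype(int), prepend=0, append=0)
    starts = list(np.flatnonzero(padded == 1))
    ends = list(np.flatnonzero(padded == -1) - 1)
    k = 0
    while k < len(starts):
        s, e = starts[k], ends[k]
        breaks = np.flatnonzero(gap_break[s + 1 : e + 1])
        if breaks.size:
            cut = s + 1 + breaks[0]
            starts.insert(k + 1, cut)
            ends.insert(k, cut - 1)
        k += 1
    successes = sum(
        1 for s, e in zip(starts, ends) if min_dist[s : e + 1].min() < target_distance
    )
    attempts = len(starts)
    start_times = uniq[starts]
    mean_interval = (
        float(np.mean(np.diff(start_times))) if attempts >= 2 else None
    )
    return PinchStats(
        attempts, successes, successes / attempts, mean_interval, False
    )


@dataclass
class ResponseLog:
    """Stimulus-response trials of a symbol-digit substitution test."""

    trials: list[tuple[str, str, float, float]]  # stimulus, response, shown, answered
    key_map: Mapping[str, str]

    def __post_init__(self):
        for stim, resp, shown, answered in self.trials:
            if answered < shown:
                raise ValueError("t_answered precedes t_shown")


def cps_stats(log: ResponseLog) -> dict[str, float]:
    """Scores of a processing-speed (symbol-digit substitution) log.

    ``accuracy`` = correct / total; reaction-time summaries are over
    correct trials only; ``rt_drift`` is the mean RT of the last third of
    correct trials minus the first third (fatigue indicator), present
    when there are at least 3 correct trials.
    """
    if not log.trials:
        raise InsufficientDataError("empty response log")
    n_total = len(log.trials)
    correct_rts = [
        answered - shown
        for stim, resp, shown, answered in log.trials
        if log.key_map.get(stim) == resp
    ]
    n_correct = len(correct_rts)
    out: dict[str, float] = {
        "n_correct": n_correct,
        "n_total": n_total,
        "accuracy": n_correct / n_total,
    }
    if n_correct:
        out["rt_mean"] = float(np.mean(correct_rts))
        out["rt_median"] = float(np.median(correct_rts))
    third = n_correct // 3
    if third >= 1:
        out["rt_drift"] = float(
            np.mean(correct_rts[n_correct - third :]) - np.mean(correct_rts[:third])
        )
    return out


def event_stats(events) -> dict[str, float]:
    """Count/rate/interval statistics of a timestamp list.

    ``rate`` = count / span with span = last - first (needs >= 2 events
    and positive span); interval mean needs >= 2 events, interval CV
    >= 3 events.
    """
    t = np.sort(np.asarray(events, dtype=float))
    out: dict[str, float] = {"count": int(t.size)}
    if t.size >= 2:
        span = float(t[-1] - t[0])
        if span > 0:
            out["rate"] = t.size / span
        iei = np.diff(t)
        out["iei_mean"] = float(np.mean(iei))
        if t.size >= 3 and np.mean(iei) > 0:
            out["iei_cv"] = float(np.std(iei) / np.mean(iei))
    return out


# ---------------------------------------------------------------------------
# pipeline step factories
# ---------------------------------------------------------------------------

def _measure(task, level, abbr, name, value, unit="", agg=None) -> MeasureValue:
    mid = generate_measure_id(task, level.modalities, abbr, agg)
    return MeasureValue(ValueDefinition(mid, name, unit), value)


def _draw_extract(level: Level, reading: Reading, params: dict):
    ds = level.datasets["touch"]
    reference = np.asarray(level.context["reference"], dtype=float)
    try:
        res = drawing_similarity(
            ds["ts"], np.column_stack([ds["x"], ds["y"]]),
            reference, n_points=params.get("n_points", 100),
        )
    except InsufficientDataError as exc:
        return [
            Flag(
                id="draw-technical-invalidation-insufficient_data",
                reason=str(exc),
                targets=[FlagTarget("dataset", level.id, "touch")],
            )
        ]
    return [
        _measure("draw", level, "sim", "mean distance to reference",
                 res.sim, "px"),
        _measure("draw", level, "dtw_sim", "DTW distance to reference",
                 res.dtw_sim, "px"),
        _measure("draw", level, "duration", "drawing duration",
                 res.duration, "s"),
    ]


def draw_steps(thresholds=None) -> list[ProcessingStep]:
    """Pipeline for the shape-drawing test (touch dataset + reference
    polyline in the level context); runs on every shape/hand/attempt
    level."""
    return [
        ProcessingStep(
            "similarity", "extract", _draw_extract,
            input_ids=["touch", "context:reference"],
            output_ids=["draw-sim"],
            params={"n_points": 100},
        ),
    ]


def _pinch_extract(level: Level, reading: Reading, params: dict):
    ds = level.datasets["touch"]
    target = float(level.context.get("target_distance", params["target_distance"]))
    stats = pinch_stats(ds["ts"], ds["contact"], ds["x"], ds["y"], target)
    out: list = []
    if stats.single_finger:
        out.append(
            Flag(
                id="pinch-behavioral-deviation-single_finger",
                reason="no two simultaneous contacts detected",
                targets=[FlagTarget("dataset", level.id, "touch")],
            )
        )
    out.append(_measure("pinch", level, "attempts", "pinch attempts",
                        stats.attempts))
    out.append(_measure("pinch", level, "successes", "successful pinches",
                        stats.successes))
    if stats.success_rate is not None:
        out.append(_measure("pinch", level, "success_rate",
                            "pinch success rate", stats.success_rate))
    if stats.mean_interval is not None:
        out.append(_measure("pinch", level, "inter_pinch_interval",
                            "mean inter-pinch interval",
                            stats.mean_interval, "s", agg="mean"))
    return out


def pinch_steps(thresholds=None) -> list[ProcessingStep]:
    """Pipeline for the pinch test (two-finger touch dataset 'touch')."""
    return [
        ProcessingStep(
            "pinch", "extract", _pinch_extract,
            input_ids=["touch"],
            output_ids=["pinch-attempts"],
            params={"target_distance": 50.0},
        ),
    ]


def _cps_extract(level: Level, reading: Reading, params: dict):
    ds = level.datasets["responses"]
    key_map = level.context["key_map"]
    log = ResponseLog(
        trials=[
            (str(s), str(r), float(ts), float(ta))
            for s, r, ts, ta in zip(
                ds["stimulus"], ds["response"], ds["ts"], ds["t_answered"]
            )
        ],
        key_map=key_map,
    )
    try:
        stats = cps_stats(log)
    except InsufficientDataError as exc:
        return [
            Flag(
                id="cps-technical-invalidation-insufficient_data",
                reason=str(exc),
                targets=[FlagTarget("dataset", level.id, "responses")],
            )
        ]
    out = [
        _measure("cps", level, "correct", "correct responses",
                 stats["n_correct"]),
        _measure("cps", level, "total", "total responses", stats["n_total"]),
        _measure("cps", level, "accuracy", "response accuracy",
                 stats["accuracy"]),
    ]
    if "rt_mean" in stats:
        out.append(_measure("cps", level, "rt", "mean reaction time",
                            stats["rt_mean"], "s", agg="mean"))
        out.append(_measure("cps", level, "rt", "median reaction time",
                            stats["rt_median"], "s", agg="median"))
    if "rt_drift" in stats:
        out.append(_measure("cps", level, "rt_drift",
                            "reaction-time drift (last minus first third)",
                            stats["rt_drift"], "s"))
    return out


def cps_steps(thresholds=None) -> list[ProcessingStep]:
    """Pipeline for the symbol-digit processing-speed test."""
    return [
        ProcessingStep(
            "score", "extract", _cps_extract,
            input_ids=["responses", "context:key_map"],
            output_ids=["cps-accuracy"],
        ),
    ]


def _event_extract_factory(task: str):
    def func(level: Level, reading: Reading, params: dict):
        ds = level.datasets["events"]
        stats = event_stats(ds["ts"])
        out = [_measure(task, level, "events", "event count", stats["count"])]
        if "rate" in stats:
            out.append(_measure(task, level, "rate", "event rate",
                                stats["rate"], "1/s"))
        if "iei_mean" in stats:
            out.append(_measure(task, level, "iei", "mean inter-event interval",
                                stats["iei_mean"], "s", agg="mean"))
        if "iei_cv" in stats:
            out.append(_measure(task, level, "iei_cv",
                                "inter-event interval CV", stats["iei_cv"]))
        return out

    return func


def event_test_steps(task: str):
    """Generic pipeline for event-based tests (tapping, typing, grip
    squeezes, sit-to-stand repetitions): an 'events' dataset whose
    timestamps mark one repetition each."""

    def factory(thresholds=None) -> list[ProcessingStep]:
        return [
            ProcessingStep(
                "events", "extract", _event_extract_factory(task),
                input_ids=["events"],
                output_ids=[f"{task}-events"],
            ),
        ]

    return factory
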