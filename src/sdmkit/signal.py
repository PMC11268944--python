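"""Shared preprocessing and technical quality checks for time series.

Covers sampling-regularity statistics and flags, uniform resampling,
zero-phase band-pass filtering, gravity removal for 3-axis accelerometry,
and device-orientation checks.  All functions operate on plain numpy
arrays; timestamps are seconds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal as sp_signal

from .config import DEFAULT_THRESHOLDS, Thresholds
from .errors import InsufficientDataError
from .model import Flag, FlagTarget


@dataclass(frozen=True)
class SamplingStats:
    """Sampling regularity summary of a timestamp vector.

    ``irregularity`` is the coefficient of variation of the successive
    time differences, std(dt)/mean(dt); 0 for a perfectly uniform grid.
    """

    median_freq: float
    nominal_freq: float
    max_gap: float
    irregularity: float


def sampling_stats(timestamps, nominal_freq: float = 0.0) -> SamplingStats:
    """Compute sampling statistics from a non-decreasing timestamp vector."""
    ts = np.asarray(timestamps, dtype=float)
    if ts.size < 3:
        raise InsufficientDataError(
            f"sampling_stats needs >= 3 samples, got {ts.size}"
        )
    dt = np.diff(ts)
    if np.any(dt < 0):
        raise ValueError("timestamps must be non-decreasing")
    mean_dt = float(np.mean(dt))
    median_dt = float(np.median(dt))
    return SamplingStats(
        median_freq=1.0 / median_dt if median_dt > 0 else np.inf,
        nominal_freq=float(nominal_freq),
        max_gap=float(np.max(dt)),
        irregularity=float(np.std(dt) / mean_dt) if mean_dt > 0 else 0.0,
    )


def flag_sampling(
    stats: SamplingStats,
    nominal: float,
    task: str = "generic",
    target: Optional[FlagTarget] = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> Optional[Flag]:
    """Technical-deviation flag for unstable sampling frequency.

    Raised when the relative jitter exceeds ``sampling_irregularity`` or
    the largest gap exceeds ``sampling_gap_factor`` nominal periods.
    """
    if nominal <= 0:
        raise ValueError("nominal frequency must be positive")
    gap_limit = thresholds.sampling_gap_factor / nominal
    reasons = []
    if stats.irregularity > thresholds.sampling_irregularity:
        reasons.append(
            f"irregularity {stats.irregularity:.3f} > "
            f"{thresholds.sampling_irregularity}"
        )
    if stats.max_gap > gap_limit:
        reasons.append(f"max gap {stats.max_gap:.3f} s > {gap_limit:.3f} s")
    if not reasons:
        return None
    return Flag(
        id=f"{task}-technical-deviation-unstable_sampling",
        reason="; ".join(reasons),
        targets=[target] if target else [],
    )


def resample_uniform(timestamps, values, target_freq: float):
    """Linear interpolation onto a uniform grid spanning [t0, tN].

    No extrapolation: the grid starts at the first and never passes the
    last input timestamp.  Idempotent on already-uniform input at the
    same rate.  Returns ``(new_timestamps, new_values)``; ``values`` may
    be 1-D or (n, k) 2-D.
    """
    ts = np.asarray(timestamps, dtype=float)
    vals = np.asarray(values, dtype=float)
    if ts.size < 2:
        raise InsufficientDataError("resample_uniform needs >= 2 samples")
    span = ts[-1] - ts[0]
    n_out = int(np.floor(span * target_freq + 1e-9)) + 1
    grid = ts[0] + np.arange(n_out) / target_freq
    if vals.ndim == 1:
        out = np.interp(grid, ts, vals)
    else:
        out = np.column_stack(
            [np.interp(grid, ts, vals[:, j]) for j in range(vals.shape[1])]
        )
    return grid, out


def bandpass_zero_phase(
    series, fs: float, order: int = 2, low_hz: float = 0.5, high_hz: float = 5.0
):
    """Forward-backward Butterworth band-pass (zero net phase).

    ``order`` is the order of the underlying one-pass filter; the
    forward-backward application doubles the effective order and cancels
    the phase, so in-band components keep their timing.  The result is
    symmetrized (averaged with the filter of the time-reversed signal),
    making it exactly invariant under time reversal, including the edge
    transients.
    """
    if not 0 < low_hz < high_hz < fs / 2:
        raise ValueError(
            f"band ({low_hz}, {high_hz}) Hz invalid for fs={fs} Hz"
        )
    x = np.asarray(series, dtype=float)
    sos = sp_signal.butter(
        order, [low_hz, high_hz], btype="bandpass", fs=fs, output="sos"
    )
    fwd = sp_signal.sosfiltfilt(sos, x)
    rev = sp_signal.sosfiltfilt(sos, x[::-1])[::-1]
    return 0.5 * (fwd + rev)


def gravity_and_norm(acc3d):
    """Split 3-axis accelerometry into a gravity estimate and a norm series.

    Gravity is the per-axis median — robust to activity bursts.  The norm
    is the Euclidean norm of the gravity-subtracted signal.  Input shape
    (n, 3); returns ``(norm, gravity)``.
    """
    a = np.asarray(acc3d, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected (n, 3) acceleration, got {a.shape}")
    gravity = np.median(a, axis=0)
    norm = np.linalg.norm(a - gravity, axis=1)
    return norm, gravity


_AXES = {"x": 0, "y": 1, "z": 2}


def flag_orientation(
    acc3d,
    expected_axis: str = "z",
    expected_sign: int = 1,
    task: str = "generic",
    target: Optional[FlagTarget] = None,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> Optional[Flag]:
    """Behavioral-deviation flag for wrong device orientation.

    The gravity vector should sit on ``expected_axis`` with
    ``expected_sign``; the flag is raised when the median component has
    the wrong sign or its magnitude falls below
    ``orientation_min_g_fraction`` of g — the device was likely held or
    worn incorrectly.
    """
    a = np.asarray(acc3d, dtype=float)
    if a.ndim != 2 or a.shape[1] != 3:
        raise ValueError(f"expected (n, 3) acceleration, got {a.shape}")
    med = float(np.median(a[:, _AXES[expected_axis]]))
    min_mag = thresholds.orientation_min_g_fraction * thresholds.gravity
    ok = np.sign(med) == np.sign(expected_sign) and abs(med) >= min_mag
    if ok:
        return None
    return Flag(
        id=f"{task}-behavioral-deviation-wrong_orientation",
        reason=(
            f"median {expected_axis}-acceleration {med:.2f} m/s^2; expected "
            f"sign {expected_sign:+d} with magnitude >= {min_mag:.2f} m/s^2"
        ),
        targets=[target] if target else [],
    )
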