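"""Tunable thresholds for quality flags and extraction algorithms.

Every threshold named here can be overridden from a YAML config file; CLI
flags override the file.  Defaults are package choices documented in
docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml


@dataclass(frozen=True)
class Thresholds:
    #: sampling is flagged when std(dt)/mean(dt) exceeds this
    sampling_irregularity: float = 0.10
    #: ... or when the largest gap exceeds this multiple of the nominal period
    sampling_gap_factor: float = 1.5
    #: orientation flagged when |median gravity component| < this fraction of g
    orientation_min_g_fraction: float = 0.5
    #: step detection: band-pass edges (Hz), peak prominence (m/s^2),
    #: minimum peak separation (s)
    step_band_low_hz: float = 0.5
    step_band_high_hz: float = 5.0
    step_min_prominence: float = 0.3
    step_min_separation: float = 0.25
    #: turn detection: yaw-rate threshold (deg/s) and minimum angle (deg)
    turn_rate_threshold_deg: float = 15.0
    turn_min_angle_deg: float = 160.0
    #: recordings shorter than this fraction of the protocol duration are
    #: invalidated as too short
    too_short_fraction: float = 0.8
    #: gravitational acceleration (m/s^2)
    gravity: float = 9.81


DEFAULT_THRESHOLDS = Thresholds()


def load_thresholds(path: Optional[str | Path] = None, **overrides) -> Thresholds:
    """Thresholds from an optional YAML file, then keyword overrides."""
    values: dict = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(Thresholds)}
        unknown = set(doc) - known
        if unknown:
            raise KeyError(f"unknown threshold keys in {path}: {sorted(unknown)}")
        values.update(doc)
    values.update({k: v for k, v in overrides.items() if v is not None})
    return replace(DEFAULT_THRESHOLDS, **values)
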