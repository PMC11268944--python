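"""Hierarchical data model for structured-test recordings.

A *reading* is one subject's one session of one structured test.  Its
sub-task attempts are *levels*, distinguished by *modalities* (e.g. the
shape drawn and the hand used).  Levels hold columnar, timestamped raw
datasets, analysis windows (*epochs*), extracted scalar measures, and
quality *flags*.  All timestamps are seconds (float64) relative to the
start of the reading.

Measures are sensor-derived measures (SDMs): named, unit-carrying scalars
whose identifiers are generated from the task, the level modalities, a
measure abbreviation and an optional aggregation, so that every measure
name links back to what produced it.  Flags annotate quality issues
(technical or behavioral) without ever deleting data.
"""

from __future__ import annotations

import copy
import hashlib
import re
from dataclasses import dataclass, field
from typing import Any, Iterator, Optional, Sequence

import numpy as np

from .errors import (
    FlagReferenceError,
    MeasureCollisionError,
    SlugError,
)

SLUG_RE = re.compile(r"^[a-z0-9_]+(-[a-z0-9_]+)*$")
#: Parts fed to :func:`generate_measure_id` must not contain the "-" field
#: separator; "_" is permitted (it joins modality values).
PART_RE = re.compile(r"^[a-z0-9_]+$")

DATA_TYPES = {"float", "int", "bool", "string", "timestamp"}
FLAG_DOMAINS = {"technical", "behavioral"}
FLAG_SEVERITIES = {"deviation", "invalidation"}
PLACEMENTS = {"handheld", "belt", "none"}


def check_slug(value: str, what: str = "id") -> str:
    if not isinstance(value, str) or not SLUG_RE.match(value):
        raise SlugError(f"{what} {value!r} is not a valid slug")
    return value


@dataclass(frozen=True)
class ValueDefinition:
    """Definition of one value: its id, display name, unit and type.

    ``unit`` uses SI abbreviations; the empty string marks dimensionless
    quantities and counts.  ``valid_range`` is a closed interval; values
    outside it are flagged, never dropped.
    """

    id: str
    name: str
    unit: str = ""
    data_type: str = "float"
    valid_range: Optional[tuple[float, float]] = None

    def __post_init__(self):
        check_slug(self.id, "definition id")
        if self.data_type not in DATA_TYPES:
            raise ValueError(
                f"data_type {self.data_type!r} not in {sorted(DATA_TYPES)}"
            )
        if self.valid_range is not None:
            lo, hi = self.valid_range
            if lo > hi:
                raise ValueError("valid_range lower bound exceeds upper bound")


@dataclass(frozen=True)
class DeviceSource:
    """Descriptor of the device/sensor a dataset came from."""

    device_model: str = "unknown"
    sensor: str = "unknown"
    sampling_freq: Optional[float] = None
    placement: str = "none"

    def __post_init__(self):
        if self.placement not in PLACEMENTS:
            raise ValueError(
                f"placement {self.placement!r} not in {sorted(PLACEMENTS)}"
            )


class RawDataSet:
    """Columnar timestamped sensor/event data.

    The first column is the timestamp column (seconds, expected
    non-decreasing — violations are tolerated at construction and flagged
    by the io layer).  Columns are stored column-major as numpy arrays
    (``object`` dtype for string columns).
    """

    def __init__(
        self,
        id: str,
        source: DeviceSource,
        columns: Sequence[ValueDefinition],
        data: Sequence[Sequence[Any]],
    ):
        check_slug(id, "dataset id")
        if len(columns) != len(data):
            raise ValueError("one data column required per column definition")
        if not columns:
            raise ValueError("dataset needs at least one column")
        if columns[0].data_type != "timestamp":
            raise ValueError("first column must have data_type 'timestamp'")
        ids = [c.id for c in columns]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate column ids in dataset {id!r}")
        lengths = {len(col) for col in data}
        if len(lengths) > 1:
            raise ValueError(f"ragged columns in dataset {id!r}: {lengths}")
        self.id = id
        self.source = source
        self.columns = list(columns)
        self._data: dict[str, np.ndarray] = {}
        for cdef, col in zip(columns, data):
            if cdef.data_type == "string":
                arr = np.asarray(col, dtype=object)
            elif cdef.data_type == "bool":
                arr = np.asarray(col, dtype=bool)
            elif cdef.data_type == "int":
                arr = np.asarray(col, dtype=np.int64)
            else:
                arr = np.asarray(col, dtype=np.float64)
            self._data[cdef.id] = arr

    def __len__(self) -> int:
        return len(self._data[self.columns[0].id])

    def __getitem__(self, column_id: str) -> np.ndarray:
        return self._data[column_id]

    @property
    def timestamps(self) -> np.ndarray:
        return self._data[self.columns[0].id]

    def timestamps_monotone(self) -> bool:
        ts = self.timestamps
        return len(ts) < 2 or bool(np.all(np.diff(ts) >= 0))

    def content_hash(self) -> str:
        """SHA-256 over column ids and values; used to prove raw data
        is never mutated by a processing run."""
        h = hashlib.sha256()
        for cdef in self.columns:
            h.update(cdef.id.encode())
            arr = self._data[cdef.id]
            if arr.dtype == object:
                h.update("\x00".join(str(v) for v in arr).encode())
            else:
                h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame({c.id: self._data[c.id] for c in self.columns})


@dataclass(frozen=True)
class Modality:
    """One labelled dimension distinguishing levels (e.g. hand=right)."""

    dimension: str
    value: str

    def __post_init__(self):
        check_slug(self.dimension, "modality dimension")
        check_slug(self.value, "modality value")


def level_id_from_modalities(modalities: Sequence[Modality]) -> str:
    """Render an ordered modality list as a level id slug.

    Values are joined with "_", matching the modality segment of measure
    ids.  A level with no modalities gets the id "main".
    """
    if not modalities:
        return "main"
    return "_".join(m.value for m in modalities)


@dataclass
class LevelEpoch:
    """A custom window of analysis within a level (e.g. one detected turn)."""

    definition: ValueDefinition
    start: float
    end: float
    payload: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError("epoch start exceeds end")


@dataclass
class MeasureValue:
    """A single named measure with its definition and flag references."""

    definition: ValueDefinition
    value: Any
    flag_ids: list[str] = field(default_factory=list)

    @property
    def id(self) -> str:
        return self.definition.id


class MeasureSet:
    """Collection of measures keyed by definition id.

    Iteration is deterministic: measures come out sorted by id.  Adding a
    measure whose id already exists is a collision error — a measure is
    computed once and annotated, never overwritten.
    """

    def __init__(self, measures: Sequence[MeasureValue] = ()):
        self._measures: dict[str, MeasureValue] = {}
        for m in measures:
            self.add(m)

    def add(self, m: MeasureValue) -> "MeasureSet":
        check_slug(m.definition.id, "measure id")
        if m.definition.id in self._measures:
            raise MeasureCollisionError(
                f"measure id {m.definition.id!r} already present "
                f"(existing name {self._measures[m.definition.id].definition.name!r}, "
                f"new name {m.definition.name!r})"
            )
        self._measures[m.definition.id] = m
        return self

    def merge(self, other: "MeasureSet") -> "MeasureSet":
        for m in other:
            self.add(m)
        return self

    def __contains__(self, measure_id: str) -> bool:
        return measure_id in self._measures

    def __getitem__(self, measure_id: str) -> MeasureValue:
        return self._measures[measure_id]

    def get(self, measure_id: str, default=None):
        return self._measures.get(measure_id, default)

    def __len__(self) -> int:
        return len(self._measures)

    def __iter__(self) -> Iterator[MeasureValue]:
        return iter(sorted(self._measures.values(), key=lambda m: m.id))

    def ids(self) -> list[str]:
        return sorted(self._measures)


def add_measure(measure_set: MeasureSet, m: MeasureValue) -> MeasureSet:
    """Add ``m`` to ``measure_set`` in place; duplicate ids are an error."""
    return measure_set.add(m)


def generate_measure_id(
    task: str,
    modalities: Sequence[Modality] = (),
    abbr: str = "",
    agg: Optional[str] = None,
) -> str:
    """Build a standardized measure id linking task, level and modality.

    The canonical syntax is ``{task}-{modality values joined by "_"}-{abbr}
    [-{agg}]``; an empty modality list omits its segment.  "-" is the
    reserved field separator and may not appear inside any part.
    """
    parts = [task] + [m.value for m in modalities] + [abbr]
    if agg is not None:
        parts.append(agg)
    for part in parts:
        if not isinstance(part, str) or not PART_RE.match(part):
            raise SlugError(
                f"measure-id part {part!r} must match [a-z0-9_]+ "
                "(no '-' separator allowed inside parts)"
            )
    segments = [task]
    if modalities:
        segments.append("_".join(m.value for m in modalities))
    segments.append(abbr)
    if agg is not None:
        segments.append(agg)
    return "-".join(segments)


FLAG_ID_RE = re.compile(
    r"^(?P<task>[a-z0-9_]+)-(?P<domain>technical|behavioral)"
    r"-(?P<severity>deviation|invalidation)-(?P<name>[a-z0-9_]+)$"
)


@dataclass(frozen=True)
class FlagTarget:
    """Reference to the entity a flag annotates.

    ``kind`` is one of reading/level/dataset/epoch/measure.  ``level_id``
    scopes dataset, epoch and level targets; ``item_id`` names the dataset
    or measure (or the epoch index, as a string).  Session-level measures
    use kind="measure" with level_id=None.
    """

    kind: str
    level_id: Optional[str] = None
    item_id: Optional[str] = None

    def __post_init__(self):
        if self.kind not in {"reading", "level", "dataset", "epoch", "measure"}:
            raise ValueError(f"unknown flag target kind {self.kind!r}")


@dataclass
class Flag:
    """Typed quality annotation.

    Flag ids follow ``{task}-{domain}-{severity}-{name}`` with domain in
    {technical, behavioral} and severity in {deviation, invalidation}.
    A *deviation* annotates; an *invalidation* marks the measure(s) as not
    trustworthy — downstream measures extracted from invalidated inputs
    inherit the flag reference.  ``stopped_processing`` aborts later
    pipeline steps on the flagged level only.
    """

    id: str
    reason: str
    targets: list[FlagTarget] = field(default_factory=list)
    stopped_processing: bool = False

    def __post_init__(self):
        m = FLAG_ID_RE.match(self.id)
        if not m:
            raise SlugError(
                f"flag id {self.id!r} does not match "
                "'{task}-{domain}-{severity}-{name}'"
            )
        self.task = m.group("task")
        self.domain = m.group("domain")
        self.severity = m.group("severity")
        self.name = m.group("name")


@dataclass
class Level:
    """One sub-task attempt: datasets, epochs, measures and flags.

    ``context`` carries protocol parameters (e.g. the reference shape for
    a drawing level, or the protocol duration of a walk).
    """

    id: str
    modalities: list[Modality] = field(default_factory=list)
    start: float = 0.0
    end: float = 0.0
    context: dict[str, Any] = field(default_factory=dict)
    datasets: dict[str, RawDataSet] = field(default_factory=dict)
    epochs: list[LevelEpoch] = field(default_factory=list)
    measures: MeasureSet = field(default_factory=MeasureSet)
    flags: list[Flag] = field(default_factory=list)

    def __post_init__(self):
        check_slug(self.id, "level id")
        if self.start > self.end:
            raise ValueError(f"level {self.id!r}: start exceeds end")
        pairs = [(m.dimension, m.value) for m in self.modalities]
        if len(set(pairs)) != len(pairs):
            raise ValueError(f"level {self.id!r}: duplicate modality pairs")

    def add_dataset(self, ds: RawDataSet) -> None:
        if ds.id in self.datasets:
            raise ValueError(f"duplicate dataset id {ds.id!r} in level {self.id!r}")
        self.datasets[ds.id] = ds

    def modality_value(self, dimension: str) -> Optional[str]:
        for m in self.modalities:
            if m.dimension == dimension:
                return m.value
        return None


@dataclass
class Reading:
    """One subject's one session of one structured test."""

    evaluation_code: str
    subject_id: str
    session_id: str
    device: DeviceSource = field(default_factory=DeviceSource)
    schema_version: str = "1.0"
    levels: list[Level] = field(default_factory=list)
    measures: MeasureSet = field(default_factory=MeasureSet)
    flags: list[Flag] = field(default_factory=list)
    extra: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self):
        check_slug(self.evaluation_code, "evaluation code")
        ids = [lv.id for lv in self.levels]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate level ids in reading")

    def get_level(self, level_id: str) -> Level:
        for lv in self.levels:
            if lv.id == level_id:
                return lv
        raise KeyError(f"no level {level_id!r} in reading")

    def add_level(self, level: Level) -> None:
        if any(lv.id == level.id for lv in self.levels):
            raise ValueError(f"duplicate level id {level.id!r}")
        self.levels.append(level)

    # -- flag queries -------------------------------------------------
    def flags_for(self, target: FlagTarget) -> list[Flag]:
        return [f for f in self.flags if target in f.targets]

    def flag_ids(self) -> list[str]:
        return [f.id for f in self.flags]

    def content_hash(self) -> str:
        """Hash over all raw dataset contents (mutation sentinel)."""
        h = hashlib.sha256()
        for lv in self.levels:
            for ds_id in sorted(lv.datasets):
                h.update(f"{lv.id}/{ds_id}".encode())
                h.update(lv.datasets[ds_id].content_hash().encode())
        return h.hexdigest()

    def copy(self) -> "Reading":
        return copy.deepcopy(self)


def _resolve_target(reading: Reading, target: FlagTarget):
    """Return the referenced entity or raise FlagReferenceError."""
    if target.kind == "reading":
        return reading
    if target.kind == "measure" and target.level_id is None:
        m = reading.measures.get(target.item_id)
        if m is None:
            raise FlagReferenceError(
                f"no session-level measure {target.item_id!r}"
            )
        return m
    try:
        level = reading.get_level(target.level_id)
    except KeyError as exc:
        raise FlagReferenceError(str(exc)) from exc
    if target.kind == "level":
        return level
    if target.kind == "dataset":
        if target.item_id not in level.datasets:
            raise FlagReferenceError(
                f"no dataset {target.item_id!r} in level {target.level_id!r}"
            )
        return level.datasets[target.item_id]
    if target.kind == "epoch":
        idx = int(target.item_id)
        if not 0 <= idx < len(level.epochs):
            raise FlagReferenceError(
                f"epoch index {idx} out of range in level {target.level_id!r}"
            )
        return level.epochs[idx]
    if target.kind == "measure":
        m = level.measures.get(target.item_id)
        if m is None:
            raise FlagReferenceError(
                f"no measure {target.item_id!r} in level {target.level_id!r}"
            )
        return m
    raise FlagReferenceError(f"unresolvable target {target!r}")


def attach_flag(reading: Reading, flag: Flag) -> Reading:
    """Attach ``flag`` to the reading and make it visible from each target.

    Measures are annotated with the flag id; data are never removed.  A
    dangling target raises :class:`FlagReferenceError` before anything is
    attached.
    """
    resolved = [(t, _resolve_target(reading, t)) for t in flag.targets]
    if flag not in reading.flags:
        reading.flags.append(flag)
    for target, entity in resolved:
        if target.kind == "level" and flag not in entity.flags:
            entity.flags.append(flag)
        elif target.kind == "measure" and flag.id not in entity.flag_ids:
            entity.flag_ids.append(flag.id)
        elif target.kind == "dataset":
            # datasets carry no flag list; the owning level mirrors it
            level = reading.get_level(target.level_id)
            if flag not in level.flags:
                level.flags.append(flag)
    return reading
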