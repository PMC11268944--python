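"""Read/write the canonical reading format; export measure collections.

The canonical dialect is this package's native JSON format (see
``schema.json``): top-level ``metadata`` and ``levels``; each level holds
its modalities, context, column-major ``datasets``, epochs, measures and
the reading-level ``flags`` block records every flag once with its target
references.  Unknown metadata keys are preserved in ``Reading.extra``.

Loading is lossless and tolerant: a dataset with non-monotone timestamps
loads fine but receives an automatic technical flag
``{task}-technical-deviation-ts_nonmonotone``.
"""

from __future__ import annotations

import csv as csv_module
import io as io_module
import json
import os
from pathlib import Path
from typing import Any, Iterable, Mapping, Union

import pandas as pd

from .errors import ValidationError
from .model import (
    DeviceSource,
    Flag,
    FlagTarget,
    Level,
    LevelEpoch,
    MeasureValue,
    Modality,
    RawDataSet,
    Reading,
    ValueDefinition,
    attach_flag,
)
from .schema import validate_document

_META_KEYS = {
    "evaluation_code", "subject_id", "session_id", "schema_version", "device",
}


# ---------------------------------------------------------------------------
# serialization helpers
# ---------------------------------------------------------------------------

def _source_to_dict(src: DeviceSource) -> dict:
    return {
        "device_model": src.device_model,
        "sensor": src.sensor,
        "sampling_freq": src.sampling_freq,
        "placement": src.placement,
    }


def _source_from_dict(d: Mapping) -> DeviceSource:
    return DeviceSource(
        device_model=d.get("device_model", "unknown"),
        sensor=d.get("sensor", "unknown"),
        sampling_freq=d.get("sampling_freq"),
        placement=d.get("placement", "none"),
    )


def _definition_to_dict(d: ValueDefinition) -> dict:
    out = {"id": d.id, "name": d.name, "unit": d.unit, "data_type": d.data_type}
    if d.valid_range is not None:
        out["valid_range"] = list(d.valid_range)
    return out


def _definition_from_dict(d: Mapping) -> ValueDefinition:
    vr = d.get("valid_range")
    return ValueDefinition(
        id=d["id"],
        name=d["name"],
        unit=d.get("unit", ""),
        data_type=d.get("data_type", "float"),
        valid_range=tuple(vr) if vr else None,
    )


def _measure_to_dict(m: MeasureValue) -> dict:
    return {"definition": _definition_to_dict(m.definition), "value": m.value}


def _dataset_to_dict(ds: RawDataSet) -> dict:
    return {
        "id": ds.id,
        "source": _source_to_dict(ds.source),
        "columns": [_definition_to_dict(c) for c in ds.columns],
        "values": [ds[c.id].tolist() for c in ds.columns],
    }


def reading_to_dict(reading: Reading) -> dict:
    """Plain-dict form of a reading (the canonical document)."""
    doc: dict[str, Any] = {
        "metadata": {
            "evaluation_code": reading.evaluation_code,
            "subject_id": reading.subject_id,
            "session_id": reading.session_id,
            "schema_version": reading.schema_version,
            "device": _source_to_dict(reading.device),
            **reading.extra,
        },
        "levels": [],
    }
    for lv in reading.levels:
        doc["levels"].append(
            {
                "id": lv.id,
                "modalities": [
                    {"dimension": m.dimension, "value": m.value}
                    for m in lv.modalities
                ],
                "start": lv.start,
                "end": lv.end,
                "context": lv.context,
                "datasets": [
                    _dataset_to_dict(lv.datasets[k]) for k in sorted(lv.datasets)
                ],
                "epochs": [
                    {
                        "definition": _definition_to_dict(ep.definition),
                        "start": ep.start,
                        "end": ep.end,
                        "payload": ep.payload,
                    }
                    for ep in lv.epochs
                ],
                "measures": [_measure_to_dict(m) for m in lv.measures],
            }
        )
    doc["measures"] = [_measure_to_dict(m) for m in reading.measures]
    doc["flags"] = [
        {
            "id": f.id,
            "reason": f.reason,
            "stopped_processing": f.stopped_processing,
            "targets": [
                {"kind": t.kind, "level_id": t.level_id, "item_id": t.item_id}
                for t in f.targets
            ],
        }
        for f in reading.flags
    ]
    return doc


def dict_to_reading(doc: Mapping) -> Reading:
    """Build a Reading from a validated canonical document."""
    meta = doc["metadata"]
    reading = Reading(
        evaluation_code=meta["evaluation_code"],
        subject_id=meta["subject_id"],
        session_id=meta["session_id"],
        device=_source_from_dict(meta.get("device", {})),
        schema_version=meta.get("schema_version", "1.0"),
        extra={k: v for k, v in meta.items() if k not in _META_KEYS},
    )
    for lv_doc in doc["levels"]:
        level = Level(
            id=lv_doc["id"],
            modalities=[
                Modality(m["dimension"], m["value"])
                for m in lv_doc.get("modalities", [])
            ],
            start=float(lv_doc.get("start", 0.0)),
            end=float(lv_doc.get("end", 0.0)),
            context=dict(lv_doc.get("context", {})),
        )
        for ds_doc in lv_doc["datasets"]:
            level.add_dataset(
                RawDataSet(
                    id=ds_doc["id"],
                    source=_source_from_dict(ds_doc.get("source", {})),
                    columns=[
                        _definition_from_dict(c) for c in ds_doc["columns"]
                    ],
                    data=ds_doc["values"],
                )
            )
        for ep_doc in lv_doc.get("epochs", []):
            level.epochs.append(
                LevelEpoch(
                    definition=_definition_from_dict(ep_doc["definition"]),
                    start=float(ep_doc["start"]),
                    end=float(ep_doc["end"]),
                    payload=dict(ep_doc.get("payload", {})),
                )
            )
        for m_doc in lv_doc.get("measures", []):
            level.measures.add(
                MeasureValue(
                    _definition_from_dict(m_doc["definition"]), m_doc["value"]
                )
            )
        reading.add_level(level)
    for m_doc in doc.get("measures", []):
        reading.measures.add(
            MeasureValue(_definition_from_dict(m_doc["definition"]), m_doc["value"])
        )
    for f_doc in doc.get("flags", []):
        flag = Flag(
            id=f_doc["id"],
            reason=f_doc["reason"],
            targets=[
                FlagTarget(t["kind"], t.get("level_id"), t.get("item_id"))
                for t in f_doc.get("targets", [])
            ],
            stopped_processing=f_doc.get("stopped_processing", False),
        )
        attach_flag(reading, flag)
    return reading


# ---------------------------------------------------------------------------
# public io
# ---------------------------------------------------------------------------

def read_reading(source: Union[str, Path, Mapping]) -> Reading:
    """Load a canonical reading from a file path, JSON text, or dict.

    The document is schema-validated first (violations raise
    :class:`ValidationError` naming the JSON-pointer path).  Datasets
    with non-monotone timestamps load successfully and receive an
    automatic ``{task}-technical-deviation-ts_nonmonotone`` flag.
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        text = str(source)
        if text.lstrip().startswith("{"):
            pass
        elif os.path.exists(text):
            with open(text, "r", encoding="utf-8") as fh:
                text = fh.read()
        else:
            raise FileNotFoundError(f"no such file: {text}")
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as exc:
            raise ValidationError(f"not valid JSON: {exc}", "") from exc
    validate_document(doc)
    reading = dict_to_reading(doc)
    for lv in reading.levels:
        for ds_id in sorted(lv.datasets):
            if not lv.datasets[ds_id].timestamps_monotone():
                attach_flag(
                    reading,
                    Flag(
                        id=(
                            f"{reading.evaluation_code}"
                            "-technical-deviation-ts_nonmonotone"
                        ),
                        reason=(
                            f"dataset {ds_id!r} in level {lv.id!r} has "
                            "non-monotone timestamps"
                        ),
                        targets=[FlagTarget("dataset", lv.id, ds_id)],
                    ),
                )
    return reading


def write_reading(reading: Reading, path: Union[str, Path, None] = None) -> str:
    """Serialize a reading to canonical JSON; optionally write to disk.

    Inverse of :func:`read_reading` up to key ordering; floats are
    emitted via Python's shortest-round-trip repr, which preserves all
    17 significant digits of the binary value.
    """
    text = json.dumps(reading_to_dict(reading), indent=1)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# measure collection
# ---------------------------------------------------------------------------

#: exact CSV header of a measure collection export
COLLECTION_FIELDS = [
    "subject_id", "session_id", "evaluation_code", "level_id",
    "measure_id", "measure_name", "value", "unit", "flag_count", "flag_ids",
]


class MeasureCollection:
    """Tabular wrapper over measures from one or many readings.

    One row per (session, measure id); ``flag_count`` always equals the
    number of ids in ``flag_ids``.  Exportable to a Python mapping, JSON
    records, or CSV.
    """

    def __init__(self, rows: Iterable[Mapping] = ()):
        self.rows = [dict(r) for r in rows]
        for r in self.rows:
            r["flag_count"] = len(
                [f for f in str(r.get("flag_ids", "")).split(";") if f]
            )

    @classmethod
    def from_readings(cls, readings: Iterable[Reading]) -> "MeasureCollection":
        rows = []
        for reading in readings:
            base = {
                "subject_id": reading.subject_id,
                "session_id": reading.session_id,
                "evaluation_code": reading.evaluation_code,
            }
            for m in reading.measures:
                rows.append(
                    {**base, "level_id": "", "measure_id": m.id,
                     "measure_name": m.definition.name, "value": m.value,
                     "unit": m.definition.unit,
                     "flag_ids": ";".join(m.flag_ids)}
                )
            for lv in reading.levels:
                for m in lv.measures:
                    rows.append(
                        {**base, "level_id": lv.id, "measure_id": m.id,
                         "measure_name": m.definition.name, "value": m.value,
                         "unit": m.definition.unit,
                         "flag_ids": ";".join(m.flag_ids)}
                    )
        return cls(rows)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=COLLECTION_FIELDS)
        return df

    def __len__(self) -> int:
        return len(self.rows)

    @classmethod
    def from_csv(cls, text: str) -> "MeasureCollection":
        reader = csv_module.DictReader(io_module.StringIO(text))
        rows = []
        for r in reader:
            r = dict(r)
            try:
                r["value"] = float(r["value"])
            except (TypeError, ValueError):
                pass
            rows.append(r)
        return cls(rows)


def export_measures(
    collection: MeasureCollection, format: str = "csv"
) -> Union[dict, str]:
    """Export a measure collection.

    ``mapping`` returns a dict keyed (session_id, measure_id); ``json``
    a record-list JSON string; ``csv`` UTF-8 text with exactly the
    :data:`COLLECTION_FIELDS` header and "." as decimal separator.
    """
    if format == "mapping":
        return {
            (r["session_id"], r["measure_id"]): r["value"]
            for r in collection.rows
        }
    if format == "json":
        records = [
            {k: r.get(k, "") for k in COLLECTION_FIELDS} for r in collection.rows
        ]
        return json.dumps(records, indent=1)
    if format == "csv":
        buf = io_module.StringIO()
        writer = csv_module.DictWriter(
            buf, fieldnames=COLLECTION_FIELDS, extrasaction="ignore",
            lineterminator="\n",
        )
        writer.writeheader()
        for r in collection.rows:
            writer.writerow({k: r.get(k, "") for k in COLLECTION_FIELDS})
        return buf.getvalue()
    raise ValueError(f"unknown export format {format!r}")
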