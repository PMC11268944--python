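"""Validation of canonical reading documents.

The schema is published as ``schema.json`` (JSON-Schema 2020-12); this
module implements the same rules directly so that every violation is
reported with the JSON-pointer path of the offending element.
"""

from __future__ import annotations

import re
from typing import Any

from .errors import ValidationError
from .model import DATA_TYPES, PLACEMENTS, SLUG_RE
from .model import FLAG_ID_RE

_TARGET_KINDS = {"reading", "level", "dataset", "epoch", "measure"}


def _require(doc: dict, key: str, pointer: str) -> Any:
    if key not in doc:
        raise ValidationError(f"missing required key {key!r}", pointer)
    return doc[key]


def _check_slug(value, pointer: str):
    if not isinstance(value, str) or not SLUG_RE.match(value):
        raise ValidationError(f"{value!r} is not a valid slug", pointer)


def _check_number(value, pointer: str):
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ValidationError(f"{value!r} is not a number", pointer)


def _validate_source(src, pointer: str):
    if not isinstance(src, dict):
        raise ValidationError("source must be an object", pointer)
    placement = src.get("placement", "none")
    if placement not in PLACEMENTS:
        raise ValidationError(
            f"placement {placement!r} not one of {sorted(PLACEMENTS)}",
            f"{pointer}/placement",
        )
    freq = src.get("sampling_freq")
    if freq is not None:
        _check_number(freq, f"{pointer}/sampling_freq")


def _validate_definition(d, pointer: str):
    if not isinstance(d, dict):
        raise ValidationError("definition must be an object", pointer)
    _check_slug(_require(d, "id", pointer), f"{pointer}/id")
    if not isinstance(_require(d, "name", pointer), str):
        raise ValidationError("name must be a string", f"{pointer}/name")
    dtype = d.get("data_type", "float")
    if dtype not in DATA_TYPES:
        raise ValidationError(
            f"data_type {dtype!r} not one of {sorted(DATA_TYPES)}",
            f"{pointer}/data_type",
        )
    vr = d.get("valid_range")
    if vr is not None:
        if not (isinstance(vr, list) and len(vr) == 2):
            raise ValidationError(
                "valid_range must be [low, high]", f"{pointer}/valid_range"
            )
        for k, bound in enumerate(vr):
            _check_number(bound, f"{pointer}/valid_range/{k}")


def _validate_measure(m, pointer: str):
    if not isinstance(m, dict):
        raise ValidationError("measure must be an object", pointer)
    _validate_definition(_require(m, "definition", pointer), f"{pointer}/definition")
    _require(m, "value", pointer)


def _validate_dataset(ds, pointer: str):
    if not isinstance(ds, dict):
        raise ValidationError("dataset must be an object", pointer)
    _check_slug(_require(ds, "id", pointer), f"{pointer}/id")
    columns = _require(ds, "columns", pointer)
    if not isinstance(columns, list) or not columns:
        raise ValidationError(
            "columns must be a non-empty array", f"{pointer}/columns"
        )
    seen = set()
    for k, col in enumerate(columns):
        _validate_definition(col, f"{pointer}/columns/{k}")
        if col["id"] in seen:
            raise ValidationError(
                f"duplicate column id {col['id']!r}", f"{pointer}/columns/{k}/id"
            )
        seen.add(col["id"])
    if columns[0].get("data_type") != "timestamp":
        raise ValidationError(
            "first column must have data_type 'timestamp'",
            f"{pointer}/columns/0/data_type",
        )
    values = _require(ds, "values", pointer)
    if not isinstance(values, list):
        raise ValidationError("values must be an array", f"{pointer}/values")
    if len(values) != len(columns):
        raise ValidationError(
            f"{len(values)} value columns for {len(columns)} definitions",
            f"{pointer}/values",
        )
    lengths = set()
    for k, col in enumerate(values):
        if not isinstance(col, list):
            raise ValidationError(
                "value column must be an array", f"{pointer}/values/{k}"
            )
        lengths.add(len(col))
    if len(lengths) > 1:
        raise ValidationError(
            f"ragged value columns (lengths {sorted(lengths)})",
            f"{pointer}/values",
        )
    for k, ts in enumerate(values[0]):
        _check_number(ts, f"{pointer}/values/0/{k}")
    if "source" in ds:
        _validate_source(ds["source"], f"{pointer}/source")


def _validate_flag(f, pointer: str):
    if not isinstance(f, dict):
        raise ValidationError("flag must be an object", pointer)
    fid = _require(f, "id", pointer)
    if not isinstance(fid, str) or not FLAG_ID_RE.match(fid):
        raise ValidationError(
            f"flag id {fid!r} does not match "
            "'{task}-{domain}-{severity}-{name}'",
            f"{pointer}/id",
        )
    if not isinstance(_require(f, "reason", pointer), str):
        raise ValidationError("reason must be a string", f"{pointer}/reason")
    for k, t in enumerate(f.get("targets", [])):
        tp = f"{pointer}/targets/{k}"
        if not isinstance(t, dict):
            raise ValidationError("target must be an object", tp)
        if _require(t, "kind", tp) not in _TARGET_KINDS:
            raise ValidationError(
                f"kind {t['kind']!r} not one of {sorted(_TARGET_KINDS)}",
                f"{tp}/kind",
            )


def validate_document(doc: Any) -> None:
    """Validate a canonical reading document; raise
    :class:`ValidationError` (with a JSON-pointer path) on the first
    violation."""
    if not isinstance(doc, dict):
        raise ValidationError("document root must be an object", "")
    meta = _require(doc, "metadata", "")
    if not isinstance(meta, dict):
        raise ValidationError("metadata must be an object", "/metadata")
    _check_slug(
        _require(meta, "evaluation_code", "/metadata"),
        "/metadata/evaluation_code",
    )
    for key in ("subject_id", "session_id"):
        if not isinstance(_require(meta, key, "/metadata"), str):
            raise ValidationError(f"{key} must be a string", f"/metadata/{key}")
    if "device" in meta:
        _validate_source(meta["device"], "/metadata/device")
    levels = _require(doc, "levels", "")
    if not isinstance(levels, list):
        raise ValidationError("levels must be an array", "/levels")
    seen_levels = set()
    for i, level in enumerate(levels):
        lp = f"/levels/{i}"
        if not isinstance(level, dict):
            raise ValidationError("level must be an object", lp)
        _check_slug(_require(level, "id", lp), f"{lp}/id")
        if level["id"] in seen_levels:
            raise ValidationError(
                f"duplicate level id {level['id']!r}", f"{lp}/id"
            )
        seen_levels.add(level["id"])
        for key in ("start", "end"):
            if key in level:
                _check_number(level[key], f"{lp}/{key}")
        for j, mod in enumerate(level.get("modalities", [])):
            mp = f"{lp}/modalities/{j}"
            if not isinstance(mod, dict):
                raise ValidationError("modality must be an object", mp)
            _check_slug(_require(mod, "dimension", mp), f"{mp}/dimension")
            _check_slug(_require(mod, "value", mp), f"{mp}/value")
        datasets = _require(level, "datasets", lp)
        if not isinstance(datasets, list):
            raise ValidationError("datasets must be an array", f"{lp}/datasets")
        seen_ds = set()
        for j, ds in enumerate(datasets):
            _validate_dataset(ds, f"{lp}/datasets/{j}")
            if ds["id"] in seen_ds:
                raise ValidationError(
                    f"duplicate dataset id {ds['id']!r}",
                    f"{lp}/datasets/{j}/id",
                )
            seen_ds.add(ds["id"])
        for j, ep in enumerate(level.get("epochs", [])):
            ep_p = f"{lp}/epochs/{j}"
            if not isinstance(ep, dict):
                raise ValidationError("epoch must be an object", ep_p)
            _validate_definition(
                _require(ep, "definition", ep_p), f"{ep_p}/definition"
            )
            _check_number(_require(ep, "start", ep_p), f"{ep_p}/start")
            _check_number(_require(ep, "end", ep_p), f"{ep_p}/end")
        for j, m in enumerate(level.get("measures", [])):
            _validate_measure(m, f"{lp}/measures/{j}")
    for j, m in enumerate(doc.get("measures", [])):
        _validate_measure(m, f"/measures/{j}")
    for j, f in enumerate(doc.get("flags", [])):
        _validate_flag(f, f"/flags/{j}")
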