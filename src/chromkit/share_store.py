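"""Experiment serialization and the shareable URL-state codec.

An :class:`~chromkit.transform.Experiment` round-trips through a versioned,
column-oriented JSON document; a filesystem store keeps one canonical JSON
file per document under ``<doc_id>.json`` with the same put/get/list
contract a remote document database would satisfy.

The URL codec encodes a view — which experiments are shown, the zoomed x
interval, and the normalization interval — as ``<id>+<id>?view-range=
<start>-<end>&norm-range=<start>-<end>``, so a link reproduces not just
the experiment list but the exact region under inspection.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional
from urllib.parse import parse_qsl

import numpy as np
import pandas as pd

from .core_model import TIDY_COLUMNS, TidyTable, empty_records
from .errors import SchemaVersionError, StoreNotFoundError, ValidationError
from .transform import Experiment, FractionRecord, validate_experiment_id

SCHEMA_VERSION = 1


@dataclass
class ViewState:
    """Shareable view: ordered experiment ids plus optional x intervals."""

    experiment_ids: list[str]
    view_range: Optional[tuple[float, float]] = None
    norm_range: Optional[tuple[float, float]] = None

    def __post_init__(self) -> None:
        if not self.experiment_ids:
            raise ValidationError("view state needs at least one experiment id")
        for experiment_id in self.experiment_ids:
            validate_experiment_id(experiment_id)
        for name, rng in (("view_range", self.view_range), ("norm_range", self.norm_range)):
            if rng is None:
                continue
            lo, hi = float(rng[0]), float(rng[1])
            if not (math.isfinite(lo) and math.isfinite(hi)):
                raise ValidationError(f"{name} must be finite, got {rng}")
            if lo < 0 or hi < 0:
                raise ValidationError(f"{name} must be non-negative, got {rng}")
            if not lo < hi:
                raise ValidationError(f"{name} start must be < end, got {rng}")


def _fmt_num(v: float) -> str:
    """Positional decimal with minimal digits (no exponent, no trailing
    zeros) so ranges stay human-readable in URLs."""
    text = np.format_float_positional(float(v), trim="-")
    return text if text else "0"


def encode_state(state: ViewState) -> str:
    """Encode a view as ``ids?query``; ranges appear only when set."""
    path = "+".join(state.experiment_ids)
    query = []
    for key, rng in (("view-range", state.view_range), ("norm-range", state.norm_range)):
        if rng is not None:
            query.append(f"{key}={_fmt_num(rng[0])}-{_fmt_num(rng[1])}")
    return path + ("?" + "&".join(query) if query else "")


def _parse_range(key: str, text: str) -> tuple[float, float]:
    parts = text.split("-")
    if len(parts) != 2:
        raise ValidationError(f"{key} {text!r} is not '<start>-<end>'")
    try:
        lo, hi = float(parts[0]), float(parts[1])
    except ValueError:
        raise ValidationError(f"{key} {text!r} has non-numeric bounds")
    if not lo < hi:
        raise ValidationError(f"{key} {text!r}: start must be < end")
    return (lo, hi)


def decode_state(url_fragment: str) -> ViewState:
    """Inverse of :func:`encode_state`.

    Accepts a bare fragment or a full URL (anything up to the last '/' of
    a ``scheme://host/`` prefix is stripped).  Unknown query keys are
    ignored so newer links stay readable.
    """
    fragment = url_fragment
    if "://" in fragment:
        rest = fragment.split("://", 1)[1]
        fragment = rest.split("/", 1)[1] if "/" in rest else ""
    fragment = fragment.lstrip("/")
    path, _, query = fragment.partition("?")
    ids = [p for p in path.split("+") if p]
    if not ids:
        raise ValidationError(f"no experiment ids in {url_fragment!r}")
    view_range = norm_range = None
    for key, value in parse_qsl(query, keep_blank_values=True):
        if key == "view-range":
            view_range = _parse_range(key, value)
        elif key == "norm-range":
            norm_range = _parse_range(key, value)
        # unknown keys ignored
    return ViewState(experiment_ids=ids, view_range=view_range, norm_range=norm_range)


# -- document codec --------------------------------------------------------

def _table_payload(table: TidyTable) -> dict:
    df = table.records
    payload: dict = {"x_unit": table.x_unit}
    for col in TIDY_COLUMNS:
        values = df[col]
        if col in ("experiment", "sample", "channel"):
            payload[col] = [str(v) for v in values]
        else:
            payload[col] = [None if pd.isna(v) else float(v) for v in values]
    return payload


def _payload_table(payload: dict) -> TidyTable:
    data = {}
    for col in TIDY_COLUMNS:
        values = payload.get(col, [])
        if col in ("experiment", "sample", "channel"):
            data[col] = list(values)
        else:
            data[col] = [np.nan if v is None else float(v) for v in values]
    df = pd.DataFrame(data) if data["sample"] else empty_records()
    return TidyTable(df, payload.get("x_unit", "time"))


def experiment_to_document(experiment: Experiment, provenance: dict | None = None) -> dict:
    """Serialize an Experiment to a plain-JSON document (column-oriented
    arrays; NaN becomes null)."""
    return {
        "doc_id": experiment.id,
        "schema_version": SCHEMA_VERSION,
        "version": experiment.version,
        "analytic": _table_payload(experiment.analytic),
        "preparative": _table_payload(experiment.preparative),
        "fractions": [
            {"label": f.label, "start": f.start, "end": f.end}
            for f in experiment.fractions
        ],
        "provenance": provenance or {},
    }


def document_to_experiment(document: dict) -> Experiment:
    """Inverse of :func:`experiment_to_document`."""
    version = document.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaVersionError(
            f"document {document.get('doc_id')!r} has schema_version {version!r}; "
            f"this reader supports {SCHEMA_VERSION}"
        )
    return Experiment(
        id=document["doc_id"],
        analytic=_payload_table(document.get("analytic", {"sample": []})),
        preparative=_payload_table(document.get("preparative", {"sample": []})),
        fractions=[
            FractionRecord(f["label"], f["start"], f["end"])
            for f in document.get("fractions", [])
        ],
        version=document.get("version", 1),
    )


def canonical_json(document: dict) -> str:
    """The byte layout stored on disk: sorted keys, 2-space indent, no NaN."""
    return json.dumps(document, sort_keys=True, indent=2, allow_nan=False) + "\n"


@dataclass
class FileStore:
    """Directory-backed document store keyed by doc_id.

    ``put`` is an upsert; ``get`` of an absent id raises
    :class:`StoreNotFoundError`; ``list`` returns sorted ids matching a
    prefix.  A CouchDB-style remote backend could implement the same
    three-method contract.
    """

    root: Path

    def __post_init__(self) -> None:
        self.root = Path(self.root)
        self.root.mkdir(parents=True, exist_ok=True)

    def _path(self, doc_id: str) -> Path:
        validate_experiment_id(doc_id)
        return self.root / f"{doc_id}.json"

    def put(self, document: dict) -> Path:
        doc_id = document.get("doc_id")
        if not doc_id:
            raise ValidationError("document has no doc_id")
        path = self._path(doc_id)
        path.write_text(canonical_json(document))
        return path

    def get(self, doc_id: str) -> dict:
        path = self._path(doc_id)
        if not path.exists():
            raise StoreNotFoundError(f"no document with id {doc_id!r}")
        return json.loads(path.read_text())

    def list(self, prefix: str = "") -> list[str]:
        ids = [p.stem for p in self.root.glob("*.json")]
        return sorted(i for i in ids if i.startswith(prefix))
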