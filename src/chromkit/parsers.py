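"""Vendor export dialect detection, parsing, and metadata resolution.

Four text dialects are supported, one per major instrument family:

* ``waters-arw`` — Empower-style tab-delimited ASCII: two header rows
  (field names, then values, including SampleName and Channel) followed by
  two-column time/signal data.  Extension ``.arw``.
* ``shimadzu-ascii`` — sectioned ASCII: a ``[Header]`` block with the
  sample name, then one ``[LC Chromatogram(<channel>)]`` block per channel
  carrying ``Interval(msec)`` and ``# of Points`` followed by one intensity
  value per line; times are reconstructed as index × interval.
* ``agilent-csv`` — bare two-column (time, signal) CSV with no metadata
  block; sample/channel must be supplied via :func:`resolve_metadata`.
* ``akta-csv`` — UNICORN-style paired-column CSV: a two-row header (curve
  names over units), one (volume mL, signal) column pair per channel, and
  optionally a trailing (volume, fraction label) pair marking fraction
  starts.

Detection is by extension for ``.arw`` and by first-line sentinel for the
CSV/TXT dialects; sentinels win over extension.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd
import yaml

from .core_model import TidyTable
from .errors import (
    MetadataError,
    ParseError,
    UnsupportedFormatError,
    ValidationError,
)
from .transform import FractionRecord

DIALECTS = ("waters-arw", "shimadzu-ascii", "agilent-csv", "akta-csv")

#: Reserved curve name marking the fraction-collector pair in akta-csv.
AKTA_FRACTION_NAME = "Fraction"


@dataclass
class RunMeta:
    """Metadata of one parsed run (or one channel of one run)."""

    sample: Optional[str] = None
    channel: Optional[str] = None
    flow_rate: Optional[float] = None  # mL/min
    instrument_kind: str = "hplc"  # "hplc" (analytic) or "fplc" (preparative)
    source_path: str = ""
    dialect: Optional[str] = None

    def __post_init__(self) -> None:
        if self.flow_rate is not None and self.flow_rate <= 0:
            raise ValidationError(f"flow_rate must be > 0, got {self.flow_rate}")
        if self.instrument_kind not in ("hplc", "fplc"):
            raise ValidationError(
                f"instrument_kind must be 'hplc' or 'fplc', got {self.instrument_kind!r}"
            )


@dataclass
class ParsedRun:
    """One trace plus its metadata; AKTA runs also carry fractions."""

    table: TidyTable
    meta: RunMeta
    fractions: list[FractionRecord] = field(default_factory=list)


@dataclass
class MetaSources:
    """Metadata override sources, lowest file-level precedence first.

    Precedence when filling an absent field: values parsed from the file
    itself, then ``per_file`` (keyed by file path or basename), then
    ``batch`` (applies to every file of a processing batch), then
    ``defaults_db`` (persisted per-user mapping keyed by dialect or method
    name).
    """

    per_file: dict[str, dict] = field(default_factory=dict)
    batch: dict = field(default_factory=dict)
    defaults_db: dict[str, dict] = field(default_factory=dict)


def _read_text(path) -> str:
    raw = Path(path).read_bytes()
    try:
        return raw.decode("utf-8")
    except UnicodeDecodeError:
        return raw.decode("latin-1")


def _is_number(token: str) -> bool:
    try:
        float(token)
    except (TypeError, ValueError):
        return False
    return True


def _looks_like_akta_header(line: str) -> bool:
    """First akta-csv line: curve names at even positions, odd cells empty."""
    cells = line.rstrip("\r\n").split(",")
    if len(cells) < 2 or len(cells) % 2 != 0:
        return False
    names = cells[0::2]
    blanks = cells[1::2]
    if any(b.strip() for b in blanks):
        return False
    return all(n.strip() and not _is_number(n) for n in names)


def _looks_like_agilent(lines: list[str]) -> bool:
    rows = [ln for ln in lines if ln.strip()]
    if not rows:
        return False
    first = rows[0].split(",")
    if len(first) > 2:
        return False
    start = 0
    if not all(_is_number(c) for c in first):
        # allow a single header line such as "Time,Signal"
        start = 1
    data = rows[start : start + 5]
    if not data:
        return False
    for ln in data:
        cells = ln.split(",")
        if len(cells) != 2 or not all(_is_number(c) for c in cells):
            return False
    return True


def detect_dialect(path, head_text: str | None = None) -> str:
    """Identify the dialect of an export file.

    Extension decides ``.arw``; for other text files the first-line
    sentinel decides (``[Header]`` → shimadzu, paired-column header →
    akta, two numeric columns → agilent).  Raises
    :class:`UnsupportedFormatError` when nothing matches.
    """
    path = str(path)
    if head_text is None:
        head_text = _read_text(path)[:4096]
    lines = head_text.splitlines()
    stripped = [ln for ln in lines if ln.strip()]
    ext = os.path.splitext(path)[1].lower()
    if ext == ".arw":
        return "waters-arw"
    if not stripped:
        raise UnsupportedFormatError(f"{path}: empty file, no dialect matches")
    first = stripped[0].strip()
    if first == "[Header]":
        return "shimadzu-ascii"
    if _looks_like_akta_header(stripped[0]):
        return "akta-csv"
    if _looks_like_agilent(lines):
        return "agilent-csv"
    raise UnsupportedFormatError(f"{path}: no supported dialect matches")


def _records_frame(sample, channel, x, signal, x_unit) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "experiment": "",
            "sample": sample,
            "channel": channel,
            "time_min": np.nan,
            "volume_mL": np.nan,
            "signal": np.asarray(signal, dtype=float),
            "signal_norm": np.nan,
        }
    )
    df["time_min" if x_unit == "time" else "volume_mL"] = np.asarray(x, dtype=float)
    return df


# -- waters-arw ------------------------------------------------------------

def parse_waters_arw(path) -> ParsedRun:
    """Parse an Empower-style .arw export: 2 header rows then time/signal."""
    text = _read_text(path)
    lines = text.splitlines()
    if len(lines) < 2:
        raise ParseError(f"{path}: expected two tab-delimited header rows")
    fields = lines[0].rstrip("\r\n").split("\t")
    values = lines[1].rstrip("\r\n").split("\t")
    header = dict(zip(fields, values))
    missing = [f for f in ("SampleName", "Channel") if f not in header]
    if missing:
        raise ParseError(f"{path}: header missing fields {missing}")
    flow = None
    if header.get("FlowRate", "").strip():
        try:
            flow = float(header["FlowRate"])
        except ValueError:
            raise ParseError(f"{path}: non-numeric FlowRate {header['FlowRate']!r}")
    times, signals = [], []
    for lineno, line in enumerate(lines[2:], start=3):
        if not line.strip():
            continue
        cells = line.split("\t")
        if len(cells) != 2 or not all(_is_number(c) for c in cells):
            raise ParseError(f"{path}: line {lineno}: expected two numeric columns")
        times.append(float(cells[0]))
        signals.append(float(cells[1]))
    meta = RunMeta(
        sample=header["SampleName"],
        channel=header["Channel"],
        flow_rate=flow,
        instrument_kind="hplc",
        source_path=str(path),
        dialect="waters-arw",
    )
    table = TidyTable(_records_frame(meta.sample, meta.channel, times, signals, "time"))
    return ParsedRun(table, meta)


# -- shimadzu-ascii --------------------------------------------------------

_SHIMADZU_BLOCK = re.compile(r"^\[LC Chromatogram\((?P<channel>.+)\)\]\s*$")


def parse_shimadzu_ascii(path) -> list[ParsedRun]:
    """Parse a sectioned Shimadzu ASCII export into one run per channel.

    Times are reconstructed from each block's ``Interval(msec)`` as
    index × interval, converted to minutes; the number of intensity values
    must equal the declared ``# of Points``.
    """
    text = _read_text(path)
    lines = text.splitlines()
    sample = None
    runs: list[ParsedRun] = []
    i = 0
    n = len(lines)
    while i < n:
        line = lines[i].strip()
        if line == "[Header]":
            i += 1
            while i < n and not lines[i].lstrip().startswith("["):
                if "\t" in lines[i]:
                    key, _, value = lines[i].partition("\t")
                    if key.strip() == "Sample Name":
                        sample = value.strip()
                i += 1
            continue
        m = _SHIMADZU_BLOCK.match(line)
        if m:
            channel = m.group("channel")
            interval_msec = None
            declared = None
            values: list[float] = []
            i += 1
            while i < n and not lines[i].lstrip().startswith("["):
                row = lines[i].rstrip("\r\n")
                if "\t" in row:
                    key, _, value = row.partition("\t")
                    key = key.strip()
                    if key == "Interval(msec)":
                        interval_msec = float(value)
                    elif key == "# of Points":
                        declared = int(value)
                elif row.strip():
                    if not _is_number(row.strip()):
                        raise ParseError(
                            f"{path}: line {i + 1}: non-numeric intensity {row.strip()!r}"
                        )
                    values.append(float(row))
                i += 1
            if declared is None:
                raise ParseError(f"{path}: chromatogram block {channel!r} missing '# of Points'")
            if declared != len(values):
                raise ParseError(
                    f"{path}: block {channel!r} declares {declared} points but has {len(values)}"
                )
            if declared > 0 and interval_msec is None:
                raise ParseError(
                    f"{path}: chromatogram block {channel!r} missing 'Interval(msec)'"
                )
            interval_min = (interval_msec or 0.0) / 60000.0
            times = np.arange(len(values)) * interval_min
            meta = RunMeta(
                sample=sample,
                channel=channel,
                instrument_kind="hplc",
                source_path=str(path),
                dialect="shimadzu-ascii",
            )
            table = TidyTable(_records_frame(sample, channel, times, values, "time"))
            runs.append(ParsedRun(table, meta))
            continue
        i += 1
    if sample is None:
        raise ParseError(f"{path}: missing [Header] block with 'Sample Name'")
    return runs


# -- agilent-csv -----------------------------------------------------------

def parse_agilent_csv(path) -> ParsedRun:
    """Parse a bare two-column (time, signal) CSV.

    The dialect carries no metadata: sample defaults to the file stem and
    channel/flow rate are absent — callers must complete the metadata via
    :func:`resolve_metadata`.
    """
    text = _read_text(path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    start = 0
    if lines and not all(_is_number(c) for c in lines[0].split(",")):
        start = 1  # header line such as "Time,Signal"
    times, signals = [], []
    for lineno, line in enumerate(lines[start:], start=start + 1):
        cells = line.split(",")
        if len(cells) > 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns, got {len(cells)}")
        if len(cells) != 2:
            raise ParseError(f"{path}: line {lineno}: expected 2 columns")
        for col, cell in enumerate(cells, start=1):
            if not _is_number(cell):
                raise ParseError(
                    f"{path}: line {lineno}, column {col}: non-numeric cell {cell!r}"
                )
        times.append(float(cells[0]))
        signals.append(float(cells[1]))
    stem = Path(path).stem
    meta = RunMeta(
        sample=None,  # the table keeps the file stem as a placeholder
        channel=None,
        instrument_kind="hplc",
        source_path=str(path),
        dialect="agilent-csv",
    )
    table = TidyTable(_records_frame(stem, "", times, signals, "time"))
    return ParsedRun(table, meta)


# -- akta-csv --------------------------------------------------------------

def parse_akta_csv(path) -> list[ParsedRun]:
    """Parse a UNICORN-style paired-column CSV into one preparative run.

    Each (volume, signal) pair becomes a channel group of a single sample
    (named after the file stem).  A trailing pair whose curve name is
    ``Fraction`` carries fraction start marks; each fraction ends where the
    next begins and the last one ends at the end of the trace.

    Returns a single-element list for interface symmetry with the other
    multi-group parser.
    """
    text = _read_text(path)
    lines = [ln for ln in text.splitlines() if ln.strip()]
    if len(lines) < 2:
        raise ParseError(f"{path}: expected two header rows")
    names_row = lines[0].split(",")
    if len(names_row) % 2 != 0:
        raise ParseError(f"{path}: odd column count {len(names_row)}; expected pairs")
    names = [c.strip() for c in names_row[0::2]]
    n_pairs = len(names)
    data_rows = [ln.split(",") for ln in lines[2:]]
    sample = Path(path).stem
    frames = []
    fractions: list[FractionRecord] = []
    fraction_marks: list[tuple[float, str]] = []
    trace_end = None
    for p, name in enumerate(names):
        xs: list[float] = []
        ys: list[str] = []
        for lineno, row in enumerate(data_rows, start=3):
            if len(row) % 2 != 0:
                raise ParseError(f"{path}: line {lineno}: odd cell count {len(row)}")
            if 2 * p >= len(row):
                continue
            xcell, ycell = row[2 * p].strip(), row[2 * p + 1].strip()
            if not xcell and not ycell:
                continue
            if not _is_number(xcell):
                raise ParseError(f"{path}: line {lineno}: non-numeric volume {xcell!r}")
            xs.append(float(xcell))
            ys.append(ycell)
        if xs and not (np.diff(xs) > 0).all():
            raise ValidationError(
                f"{path}: volumes of curve {name!r} are not strictly increasing"
            )
        if name == AKTA_FRACTION_NAME:
            fraction_marks = list(zip(xs, ys))
        else:
            sig = []
            for v in ys:
                if not _is_number(v):
                    raise ParseError(f"{path}: non-numeric signal {v!r} in curve {name!r}")
                sig.append(float(v))
            frames.append(_records_frame(sample, name, xs, sig, "volume"))
            if xs:
                trace_end = max(trace_end, xs[-1]) if trace_end is not None else xs[-1]
    if fraction_marks:
        if trace_end is None:
            raise ParseError(f"{path}: fraction marks present but no signal curves")
        for k, (start, label) in enumerate(fraction_marks):
            end = fraction_marks[k + 1][0] if k + 1 < len(fraction_marks) else trace_end
            if end > start:
                fractions.append(FractionRecord(label=label, start=start, end=end))
    if not frames:
        raise ParseError(f"{path}: no signal curves found")
    table = TidyTable(pd.concat(frames, ignore_index=True), x_unit="volume")
    meta = RunMeta(
        sample=sample,
        channel=None,
        instrument_kind="fplc",
        source_path=str(path),
        dialect="akta-csv",
    )
    return [ParsedRun(table, meta, fractions)]


_PARSERS = {
    "waters-arw": lambda p: [parse_waters_arw(p)],
    "shimadzu-ascii": parse_shimadzu_ascii,
    "agilent-csv": lambda p: [parse_agilent_csv(p)],
    "akta-csv": parse_akta_csv,
}


def parse_file(path, dialect: str | None = None) -> list[ParsedRun]:
    """Detect (unless given) and parse; always returns a list of runs."""
    if dialect is None:
        dialect = detect_dialect(path)
    if dialect not in _PARSERS:
        raise UnsupportedFormatError(f"unknown dialect {dialect!r}")
    return list(_PARSERS[dialect](path))


# -- metadata resolution ---------------------------------------------------

def default_config_path() -> Path:
    base = os.environ.get("XDG_CONFIG_HOME", os.path.expanduser("~/.config"))
    return Path(base) / "chromkit" / "defaults.yaml"


def load_defaults_db(path=None) -> dict:
    """Load the persisted defaults mapping ``{key: {flow_rate, channel}}``."""
    path = Path(path) if path is not None else default_config_path()
    if not path.exists():
        return {}
    data = yaml.safe_load(path.read_text()) or {}
    if not isinstance(data, dict):
        raise ValidationError(f"{path}: defaults db must be a mapping")
    return data


def save_defaults_db(db: dict, path=None) -> Path:
    path = Path(path) if path is not None else default_config_path()
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(db, sort_keys=True))
    return path


_RESOLVABLE = ("sample", "channel", "flow_rate")


def apply_run_metadata(run: ParsedRun) -> ParsedRun:
    """Write resolved sample/channel names into a single-group table.

    Multi-group tables (Shimadzu multi-channel, AKTA) already carry their
    names and are left alone.
    """
    df = run.table.records
    if run.meta.sample and df["sample"].nunique() <= 1:
        df["sample"] = run.meta.sample
    if run.meta.channel and df["channel"].nunique() <= 1:
        df["channel"] = run.meta.channel
    return run


def resolve_metadata(
    parsed: RunMeta,
    sources: MetaSources | None = None,
    interactive: bool = False,
    prompt: Callable[[str], object] | None = None,
) -> RunMeta:
    """Fill absent RunMeta fields from the highest-precedence source.

    Precedence: file content (already in ``parsed``) > per-file overrides >
    batch overrides > persisted defaults.  When a field is still absent and
    ``interactive`` is set, the injected ``prompt`` callback is asked for
    it.  Analytic (HPLC) runs must end with both a flow rate and a channel;
    a missing flow rate in non-interactive mode is a hard error because
    volume cannot be derived without it.
    """
    sources = sources or MetaSources()
    per_file = dict(sources.per_file.get(parsed.source_path, {}))
    if parsed.source_path:
        base = os.path.basename(parsed.source_path)
        for key, val in sources.per_file.get(base, {}).items():
            per_file.setdefault(key, val)
    chain = [per_file, dict(sources.batch)]
    for key in (parsed.dialect, parsed.instrument_kind):
        if key and key in sources.defaults_db:
            chain.append(dict(sources.defaults_db[key]))
    resolved = replace(parsed)
    for fieldname in _RESOLVABLE:
        if getattr(resolved, fieldname) not in (None, ""):
            continue
        for source in chain:
            value = source.get(fieldname)
            if value not in (None, ""):
                setattr(resolved, fieldname, value)
                break
        else:
            if interactive and prompt is not None:
                value = prompt(fieldname)
                if value not in (None, ""):
                    setattr(resolved, fieldname, value)
    if resolved.flow_rate is not None:
        resolved.flow_rate = float(resolved.flow_rate)
        if resolved.flow_rate <= 0:
            raise ValidationError(f"flow_rate must be > 0, got {resolved.flow_rate}")
    if resolved.instrument_kind == "hplc":
        if resolved.flow_rate is None:
            raise MetadataError(
                f"flow rate required for {resolved.source_path or 'run'} "
                "and no source provides it"
            )
        if resolved.channel in (None, ""):
            raise MetadataError(
                f"channel name required for {resolved.source_path or 'run'} "
                "and no source provides it"
            )
    return resolved
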