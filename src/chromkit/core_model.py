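"""Canonical tidy and wide chromatogram representations.

The interchange form throughout the package is the *tidy* (long) table: one
row per observation, i.e. one detector reading of one sample on one channel
at one x position (retention time in minutes or elution volume in mL).  The
*wide* form pivots each (sample, channel) trace into its own column over a
shared x column; it is what spreadsheet-style tools consume.  Conversion
between the two is lossless for the x/signal content.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Column order of the tidy table. ``time_min``/``volume_mL`` hold the x
#: variable depending on ``x_unit``; the inactive one may be all-NaN.
TIDY_COLUMNS = [
    "experiment",
    "sample",
    "channel",
    "time_min",
    "volume_mL",
    "signal",
    "signal_norm",
]

_STRING_COLUMNS = ("experiment", "sample", "channel")
_NUMERIC_COLUMNS = ("time_min", "volume_mL", "signal", "signal_norm")

#: Separator used to build wide column headers "<sample> | <channel>".
#: Sample and channel names containing it are rejected at ingest so the
#: wide -> tidy direction is unambiguous.
WIDE_SEP = " | "

X_COLUMN = {"time": "time_min", "volume": "volume_mL"}

#: x values are compared on a grid rounded to this many decimals when
#: unioning sampling grids; stored values are never modified.
_GRID_DECIMALS = 9


@dataclass
class ChannelMeta:
    """A detector channel and the unit of its signal (e.g. mAU, RFU)."""

    name: str
    unit: str = "mAU"

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("channel name must be non-empty")


def empty_records() -> pd.DataFrame:
    """An empty tidy records frame with the canonical columns."""
    df = pd.DataFrame({c: pd.Series(dtype=object) for c in _STRING_COLUMNS})
    for c in _NUMERIC_COLUMNS:
        df[c] = pd.Series(dtype=float)
    return df[TIDY_COLUMNS]


@dataclass
class TidyTable:
    """Long-form observation table plus the unit of its x axis.

    ``records`` is a DataFrame with the :data:`TIDY_COLUMNS` layout; missing
    optional columns are added as NaN on construction.  ``x_unit`` is
    ``"time"`` (minutes, analytic HPLC runs) or ``"volume"`` (mL,
    preparative FPLC runs).
    """

    records: pd.DataFrame = field(default_factory=empty_records)
    x_unit: str = "time"

    def __post_init__(self) -> None:
        if self.x_unit not in X_COLUMN:
            raise ValidationError(f"unknown x_unit {self.x_unit!r}")
        df = self.records.copy()
        for col in _STRING_COLUMNS:
            if col not in df.columns:
                raise ValidationError(f"tidy records missing column {col!r}")
        if "signal" not in df.columns:
            raise ValidationError("tidy records missing column 'signal'")
        for col in _NUMERIC_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
            df[col] = df[col].astype(float)
        for col in _STRING_COLUMNS:
            df[col] = df[col].astype(object)
        self.records = df[TIDY_COLUMNS].reset_index(drop=True)

    # -- accessors ---------------------------------------------------------

    @property
    def x_column(self) -> str:
        return X_COLUMN[self.x_unit]

    @property
    def is_empty(self) -> bool:
        return len(self.records) == 0

    def samples(self) -> list[str]:
        return sorted(self.records["sample"].unique())

    def channels(self) -> list[str]:
        return sorted(self.records["channel"].unique())

    def groups(self) -> Iterator[tuple[tuple[str, str], pd.DataFrame]]:
        """Yield ((sample, channel), sub-frame sorted by x) per trace."""
        if self.is_empty:
            return
        for key, sub in self.records.groupby(["sample", "channel"], sort=True):
            yield key, sub.sort_values(self.x_column, kind="mergesort")

    def copy(self) -> "TidyTable":
        return TidyTable(self.records.copy(), self.x_unit)

    def canonical(self) -> pd.DataFrame:
        """Records sorted by (experiment, sample, channel, x) — the order
        under which two tables are compared."""
        return self.records.sort_values(
            ["experiment", "sample", "channel", self.x_column],
            kind="mergesort",
        ).reset_index(drop=True)

    def equals(self, other: "TidyTable") -> bool:
        """Equality up to row order; numeric columns compared bit-exactly
        (NaN == NaN)."""
        if self.x_unit != other.x_unit:
            return False
        a, b = self.canonical(), other.canonical()
        if len(a) != len(b):
            return False
        for col in _STRING_COLUMNS:
            if not (a[col].to_numpy() == b[col].to_numpy()).all():
                return False
        for col in _NUMERIC_COLUMNS:
            if not np.array_equal(
                a[col].to_numpy(), b[col].to_numpy(), equal_nan=True
            ):
                return False
        return True


def concat_tables(tables: list[TidyTable], x_unit: str) -> TidyTable:
    frames = [t.records for t in tables if not t.is_empty]
    if not frames:
        return TidyTable(empty_records(), x_unit)
    return TidyTable(pd.concat(frames, ignore_index=True), x_unit)


@dataclass
class WideTable:
    """Pivot of a TidyTable: shared x column + one signal series per trace.

    ``series`` maps a header built with :data:`WIDE_SEP` to a float array
    aligned to ``x``; NaN marks cells where that trace has no reading.
    """

    x: np.ndarray
    series: dict[str, np.ndarray]
    x_unit: str = "time"

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.series = {k: np.asarray(v, dtype=float) for k, v in self.series.items()}
        for header, values in self.series.items():
            if len(values) != len(self.x):
                raise ValidationError(
                    f"series {header!r} length {len(values)} != x length {len(self.x)}"
                )
        if self.x_unit not in X_COLUMN:
            raise ValidationError(f"unknown x_unit {self.x_unit!r}")


def _check_separator_free(df: pd.DataFrame) -> None:
    for col in ("sample", "channel"):
        bad = [v for v in df[col].unique() if WIDE_SEP in str(v)]
        if bad:
            raise ValidationError(
                f"{col} names may not contain {WIDE_SEP!r}: {bad!r}"
            )


def tidy_to_wide(table: TidyTable) -> WideTable:
    """Pivot a tidy table into wide form.

    The wide x is the sorted union of every trace's sampling grid (grids are
    unioned after rounding to 9 decimals to absorb parser float noise; the
    emitted x values themselves are unrounded).  Signal values are carried
    over unchanged; traces with no reading at a grid point get NaN there.
    """
    if table.is_empty:
        return WideTable(np.empty(0), {}, table.x_unit)
    df = table.records.copy()
    _check_separator_free(df)
    xcol = table.x_column
    df["_xr"] = df[xcol].round(_GRID_DECIMALS)
    dup = df.duplicated(["sample", "channel", "_xr"], keep=False)
    if dup.any():
        row = df[dup].iloc[0]
        raise ValidationError(
            "duplicate reading for (sample={!r}, channel={!r}, x={!r})".format(
                row["sample"], row["channel"], row[xcol]
            )
        )
    df["_hdr"] = df["sample"].astype(str) + WIDE_SEP + df["channel"].astype(str)
    piv = df.pivot(index="_xr", columns="_hdr", values="signal").sort_index()
    # representative (unrounded) x per grid key: smallest original value
    xrep = df.sort_values(xcol, kind="mergesort").groupby("_xr")[xcol].first()
    x = xrep.loc[piv.index].to_numpy(dtype=float)
    series = {h: piv[h].to_numpy(dtype=float) for h in sorted(piv.columns)}
    return WideTable(x, series, table.x_unit)


def split_header(header: str) -> tuple[str, str]:
    """Split a wide column header into (sample, channel)."""
    parts = header.split(WIDE_SEP)
    if len(parts) != 2 or not parts[0] or not parts[1]:
        raise ValidationError(
            f"wide header {header!r} does not match '<sample>{WIDE_SEP}<channel>'"
        )
    return parts[0], parts[1]


def wide_to_tidy(table: WideTable, experiment_id: str) -> TidyTable:
    """Melt a wide table back to tidy form; NaN cells are dropped."""
    xcol = X_COLUMN[table.x_unit]
    rows: list[pd.DataFrame] = []
    for header in sorted(table.series):
        sample, channel = split_header(header)
        values = table.series[header]
        mask = ~np.isnan(values)
        sub = pd.DataFrame(
            {
                "experiment": experiment_id,
                "sample": sample,
                "channel": channel,
                "time_min": np.nan,
                "volume_mL": np.nan,
                "signal": values[mask],
                "signal_norm": np.nan,
            }
        )
        sub[xcol] = table.x[mask]
        rows.append(sub)
    if not rows:
        return TidyTable(empty_records(), table.x_unit)
    out = pd.concat(rows, ignore_index=True)
    return TidyTable(out, table.x_unit)


def validate_table(table: TidyTable) -> list[str]:
    """Check TidyTable invariants; return human-readable violations.

    Violations are returned (never raised) so callers can report them all
    at once.  An empty list means the table conforms.
    """
    violations: list[str] = []
    df = table.records
    xcol = table.x_column
    if df.empty:
        return violations
    for col in ("sample", "channel"):
        for v in df[col].unique():
            if WIDE_SEP in str(v):
                violations.append(
                    f"separator: {col} name {v!r} contains reserved {WIDE_SEP!r}"
                )
    if (df[xcol].to_numpy() < 0).any():
        violations.append(f"negative-x: {xcol} contains values < 0")
    vol = df["volume_mL"].to_numpy()
    if (vol[~np.isnan(vol)] < 0).any():
        violations.append("negative-volume: volume_mL contains values < 0")
    if df[xcol].isna().any():
        violations.append(f"missing-x: {xcol} contains NaN")
        return violations
    dup = df.duplicated(["experiment", "sample", "channel", xcol], keep=False)
    dup_groups: set[tuple] = set()
    if dup.any():
        row = df[dup].iloc[0]
        dup_groups = set(map(tuple, df.loc[dup, ["sample", "channel"]].to_numpy()))
        violations.append(
            "uniqueness: duplicate (experiment={!r}, sample={!r}, channel={!r}, "
            "x={!r})".format(row["experiment"], row["sample"], row["channel"], float(row[xcol]))
        )
    for (sample, channel), sub in df.groupby(["sample", "channel"], sort=True):
        if (sample, channel) in dup_groups:
            continue  # duplicate x already reported; it implies non-monotone
        x = sub[xcol].to_numpy()
        if len(x) > 1 and not (np.diff(x) > 0).all():
            violations.append(
                f"monotonicity: ({sample!r}, {channel!r}) x values are not "
                "strictly increasing in row order"
            )
    return violations


# -- CSV contracts ---------------------------------------------------------

TIDY_CSV_HEADER = "experiment,sample,channel,time_min,volume_mL,signal,signal_norm"


def _stringify_floats(df: pd.DataFrame, columns) -> pd.DataFrame:
    """Render float columns as shortest round-trip decimals (NaN -> empty),
    so written CSVs reproduce every signal bit-exactly when read back."""
    out = df.copy()
    for col in columns:
        out[col] = ["" if np.isnan(v) else repr(float(v)) for v in out[col]]
    return out


def write_tidy_csv(table: TidyTable, path) -> None:
    """Write the tidy CSV contract; absent values become empty cells."""
    _stringify_floats(table.records, _NUMERIC_COLUMNS).to_csv(
        path, index=False, na_rep=""
    )


def read_tidy_csv(path, x_unit: str | None = None) -> TidyTable:
    """Read a tidy CSV. If ``x_unit`` is None it is inferred: volume when
    the time column is entirely empty but volume is not, time otherwise."""
    df = pd.read_csv(
        path,
        dtype={c: object for c in _STRING_COLUMNS},
        float_precision="round_trip",
    )
    for col in TIDY_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    if x_unit is None:
        if df["time_min"].isna().all() and not df["volume_mL"].isna().all():
            x_unit = "volume"
        else:
            x_unit = "time"
    return TidyTable(df, x_unit)


def write_wide_csv(table: WideTable, path) -> None:
    """Write the wide CSV contract: x column first, one column per trace."""
    data = {X_COLUMN[table.x_unit]: table.x}
    data.update(table.series)
    df = pd.DataFrame(data)
    _stringify_floats(df, df.columns).to_csv(path, index=False, na_rep="")


def read_wide_csv(path) -> WideTable:
    df = pd.read_csv(path, float_precision="round_trip")
    if df.columns.empty or df.columns[0] not in ("time_min", "volume_mL"):
        raise ValidationError(
            "wide CSV must start with a 'time_min' or 'volume_mL' column"
        )
    x_unit = "time" if df.columns[0] == "time_min" else "volume"
    x = df.iloc[:, 0].to_numpy(dtype=float)
    series = {c: df[c].to_numpy(dtype=float) for c in df.columns[1:]}
    return WideTable(x, series, x_unit)
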