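"""Pipeline computations on tidy chromatography tables.

Volume derivation from flow rate, batch scaling, range-based normalization,
analytic/preparative run classification, experiment assembly and
combination, and the peak-height / percent-bound heuristics used to read
binding interactions off paired traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core_model import TidyTable, concat_tables, empty_records
from .errors import DegenerateTraceError, ValidationError

#: Characters an experiment id may not contain: they are reserved by the
#: share-URL codec ('+' joins ids, '?'/'&'/'=' delimit the query string)
#: and '/' by the filesystem store.
RESERVED_ID_CHARS = "+?&=/"


@dataclass
class FractionRecord:
    """A labeled interval of collected eluate on a preparative run.

    Intervals are half-open [start, end) except the final fraction of a
    run, which is closed at the end of the trace; successive fractions
    partition the collected region without overlap.
    """

    label: str
    start: float  # mL
    end: float  # mL

    def __post_init__(self) -> None:
        self.start = float(self.start)
        self.end = float(self.end)
        if not self.start < self.end:
            raise ValidationError(
                f"fraction {self.label!r}: start {self.start} must be < end {self.end}"
            )


@dataclass
class NormParams:
    """Normalization window on the trace's own x axis (minutes or mL).

    ``zero_min`` additionally anchors the in-range minimum at 0, mapping
    the in-range span of each trace onto [0, 1].
    """

    range_start: float
    range_end: float
    zero_min: bool = False

    def __post_init__(self) -> None:
        if not self.range_start < self.range_end:
            raise ValidationError(
                f"normalization range start {self.range_start} must be < end {self.range_end}"
            )


def validate_experiment_id(experiment_id: str) -> str:
    if not experiment_id:
        raise ValidationError("experiment id must be non-empty")
    bad = sorted(set(experiment_id) & set(RESERVED_ID_CHARS))
    if bad:
        raise ValidationError(
            f"experiment id {experiment_id!r} contains reserved characters {bad}"
        )
    return experiment_id


@dataclass
class Experiment:
    """A named set of processed traces ready for plotting and sharing.

    ``analytic`` holds time-indexed (HPLC) traces, ``preparative`` holds
    volume-indexed (FPLC) traces with their collected ``fractions``.
    Either table may be empty.
    """

    id: str
    analytic: TidyTable = field(default_factory=lambda: TidyTable(empty_records(), "time"))
    preparative: TidyTable = field(
        default_factory=lambda: TidyTable(empty_records(), "volume")
    )
    fractions: list[FractionRecord] = field(default_factory=list)
    version: int = 1

    def __post_init__(self) -> None:
        # a combined experiment's id is its constituent ids joined by '+',
        # so each '+'-separated segment must be a valid id on its own
        for segment in self.id.split("+"):
            validate_experiment_id(segment)
        if self.version < 1:
            raise ValidationError("experiment version must be >= 1")
        self.fractions = sorted(self.fractions, key=lambda f: f.start)
        for a, b in zip(self.fractions, self.fractions[1:]):
            if b.start < a.end - 1e-12:
                raise ValidationError(
                    f"fractions {a.label!r} and {b.label!r} overlap"
                )


# -- elementwise transforms ------------------------------------------------

def add_volume(table: TidyTable, flow_rate: float) -> TidyTable:
    """Derive elution volume as time × flow rate (mL = min × mL/min)."""
    if flow_rate is None or flow_rate <= 0:
        raise ValidationError(f"flow_rate must be > 0, got {flow_rate}")
    if table.x_unit != "time":
        raise ValidationError("add_volume requires a time-indexed table")
    out = table.copy()
    out.records["volume_mL"] = out.records["time_min"] * float(flow_rate)
    return out


def apply_scale(table: TidyTable, factor: float) -> TidyTable:
    """Multiply every raw signal by a batch scale factor (e.g. to account
    for differing flow-cell path lengths between instruments).  Applied
    before normalization, so only the raw column observes the order."""
    if factor is None or factor <= 0:
        raise ValidationError(f"scale factor must be > 0, got {factor}")
    out = table.copy()
    out.records["signal"] = out.records["signal"] * float(factor)
    return out


def normalize_range(table: TidyTable, params: NormParams) -> TidyTable:
    """Linearly rescale each trace so its maximum over the window is 1.0.

    Per (sample, channel) group independently: with M the maximum raw
    signal at x in [range_start, range_end], every point of the whole
    trace maps to s/M; with ``zero_min``, m is the in-range minimum and the
    map is (s − m)/(M − m).  Out-of-range points scale by the same line and
    may exceed 1.  Results go to ``signal_norm``; the raw column is never
    touched.
    """
    if table.is_empty:
        raise ValidationError("cannot normalize an empty table")
    out = table.copy()
    df = out.records
    xcol = out.x_column
    norm = np.full(len(df), np.nan)
    for (sample, channel), sub in df.groupby(["sample", "channel"], sort=True):
        x = sub[xcol].to_numpy()
        s = sub["signal"].to_numpy()
        in_range = (x >= params.range_start) & (x <= params.range_end)
        if not in_range.any():
            raise ValidationError(
                f"group ({sample!r}, {channel!r}) has no points in "
                f"[{params.range_start}, {params.range_end}]"
            )
        m_max = s[in_range].max()
        if params.zero_min:
            m_min = s[in_range].min()
            if m_max == m_min:
                raise DegenerateTraceError(
                    f"group ({sample!r}, {channel!r}) is flat over the range"
                )
            norm[sub.index] = (s - m_min) / (m_max - m_min)
        else:
            if m_max <= 0:
                raise DegenerateTraceError(
                    f"group ({sample!r}, {channel!r}) has non-positive maximum "
                    f"{m_max} over the range"
                )
            norm[sub.index] = s / m_max
    df["signal_norm"] = norm
    return out


# -- classification and assembly -------------------------------------------

def classify_run(meta, fractions=None) -> str:
    """Classify a parsed run as ``"analytic"`` or ``"preparative"``.

    FPLC instruments are preparative by definition; so is any run with
    collected fractions, whatever the instrument.
    """
    if getattr(meta, "instrument_kind", "hplc") == "fplc":
        return "preparative"
    if fractions:
        return "preparative"
    return "analytic"


def _disambiguate(seen: set[tuple[str, str]], sample: str, channels: list[str]) -> str:
    """Pick a free sample name for a run's trace set.

    A collision means another file already supplied one of this run's
    (sample, channel) traces; the same sample on a *different* channel is
    the normal multi-channel case and keeps its name.  Colliding samples
    get the smallest numeric suffix ("A (2)", "A (3)", ...) that frees
    every channel.
    """
    name = sample
    k = 1
    while any((name, c) in seen for c in channels):
        k += 1
        name = f"{sample} ({k})"
    seen.update((name, c) for c in channels)
    return name


def assemble_experiment(experiment_id: str, parsed_runs) -> Experiment:
    """Merge parsed runs into one Experiment.

    Runs are classified analytic/preparative; within each kind, a
    (sample, channel) trace claimed by more than one file gets its sample
    renamed with a numeric suffix ("A", then "A (2)", ...) so traces stay
    distinguishable.
    """
    validate_experiment_id(experiment_id)
    runs = list(parsed_runs)
    if not runs:
        raise ValidationError("nothing to assemble: empty run list")
    analytic_tables, preparative_tables = [], []
    fractions: list[FractionRecord] = []
    seen: dict[str, set[tuple[str, str]]] = {"analytic": set(), "preparative": set()}
    for run in runs:
        kind = classify_run(run.meta, getattr(run, "fractions", None))
        table = run.table.copy()
        df = table.records
        df["experiment"] = experiment_id
        relabel = {}
        for sample in df["sample"].unique():
            channels = list(df.loc[df["sample"] == sample, "channel"].unique())
            relabel[sample] = _disambiguate(seen[kind], sample, channels)
        df["sample"] = df["sample"].map(relabel)
        if kind == "analytic":
            analytic_tables.append(table)
        else:
            preparative_tables.append(table)
            fractions.extend(getattr(run, "fractions", []) or [])
    return Experiment(
        id=experiment_id,
        analytic=concat_tables(analytic_tables, "time"),
        preparative=concat_tables(preparative_tables, "volume"),
        fractions=fractions,
    )


def combine_experiments(experiments) -> Experiment:
    """Merge experiments for side-by-side comparison.

    The combined id joins the constituent ids with "+" (the form share
    URLs use); every sample is relabeled "<experiment id>: <sample>" so
    lines remain attributable; fraction fills are dropped in combined
    views, so the combined fraction list is empty.
    """
    experiments = list(experiments)
    if len(experiments) < 2:
        raise ValidationError("combining requires at least two experiments")
    ids = [e.id for e in experiments]
    if len(set(ids)) != len(ids):
        raise ValidationError(f"duplicate experiment ids: {ids}")
    analytic_tables, preparative_tables = [], []
    for exp in experiments:
        for source, sink in (
            (exp.analytic, analytic_tables),
            (exp.preparative, preparative_tables),
        ):
            if source.is_empty:
                continue
            table = source.copy()
            df = table.records
            df["sample"] = exp.id + ": " + df["sample"].astype(str)
            sink.append(table)
    combined_id = "+".join(ids)
    return Experiment(
        id=combined_id,
        analytic=concat_tables(analytic_tables, "time"),
        preparative=concat_tables(preparative_tables, "volume"),
        fractions=[],
    )


# -- peak readouts ---------------------------------------------------------

def peak_height(
    table: TidyTable, sample: str, channel: str, x_range: tuple[float, float]
) -> float:
    """Maximum signal of one trace over an x window.

    Uses ``signal_norm`` when the trace has been normalized, otherwise the
    raw signal — matching what a user reads off the corresponding plot.
    """
    lo, hi = x_range
    if not lo < hi:
        raise ValidationError(f"range start {lo} must be < end {hi}")
    df = table.records
    xcol = table.x_column
    sub = df[(df["sample"] == sample) & (df["channel"] == channel)]
    if sub.empty:
        raise ValidationError(f"no trace for ({sample!r}, {channel!r})")
    x = sub[xcol].to_numpy()
    sel = sub[(x >= lo) & (x <= hi)]
    if sel.empty:
        raise ValidationError(
            f"trace ({sample!r}, {channel!r}) has no points in [{lo}, {hi}]"
        )
    norm = sel["signal_norm"].to_numpy()
    if not np.isnan(norm).all():
        return float(np.nanmax(norm))
    return float(sel["signal"].max())


def percent_bound(h_bound: float, h_unbound: float) -> float:
    """Fraction of a population in the bound state, from relative peak
    heights of bound and unbound species: 100 · h_b / (h_b + h_u).

    Peak height stands in for peak area here — the standard chromatography
    heuristic when both species elute with similar peak shapes.
    """
    if h_bound < 0 or h_unbound < 0:
        raise ValidationError("peak heights must be >= 0")
    if h_bound == 0 and h_unbound == 0:
        raise ValidationError("both peak heights are zero; ratio undefined")
    return 100.0 * h_bound / (h_bound + h_unbound)
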