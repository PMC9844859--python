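"""Parametric chromatogram simulator and vendor-dialect file emitter.

Generates traces with known ground truth — Gaussian or exponentially
modified Gaussian (EMG) peaks on a linear baseline with optional white
noise — and writes them in each supported vendor dialect, so every parser
and every downstream transform can be tested against exact expected
values.  This is a phenomenological peak model, not a physical column
simulator: no plate theory, no van Deemter dependence of width on flow.

Emitted files use the shortest round-trip decimal representation for every
number, so parse(emit(experiment)) reproduces signal values bit-identically.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml
from scipy.special import erfcx

from .core_model import TidyTable
from .errors import ValidationError
from .transform import Experiment, FractionRecord

_SQRT2 = np.sqrt(2.0)
_SQRT2PI = np.sqrt(2.0 * np.pi)

#: Default analytic grid: 3 min at 0.005 min (300 ms) sampling -> 601 points,
#: typical of a short FSEC run on a 5/150 SEC column at ~0.5 mL/min.
ANALYTIC_DURATION = 3.0
ANALYTIC_INTERVAL = 0.005
ANALYTIC_FLOW_RATE = 0.5

#: Default preparative grid: 24 mL (one 10/300 SEC column volume) at
#: 0.05 mL sampling -> 481 points.
PREP_DURATION = 24.0
PREP_INTERVAL = 0.05

_CHANNEL_POOL = ("280 nm", "GFP", "260 nm", "Trp")


@dataclass
class PeakSpec:
    """One chromatographic peak.

    ``center``/``sigma``/``tau`` share the trace's x unit (minutes or mL);
    ``height`` is the amplitude of the underlying Gaussian, and ``tau`` is
    the exponential tailing constant (0 = pure Gaussian).  The EMG is
    area-matched to the Gaussian, so peak area is height·sigma·sqrt(2*pi)
    in both cases.
    """

    center: float
    height: float
    sigma: float
    tau: float = 0.0

    def __post_init__(self) -> None:
        if self.height <= 0:
            raise ValidationError(f"peak height must be > 0, got {self.height}")
        if self.sigma <= 0:
            raise ValidationError(f"peak sigma must be > 0, got {self.sigma}")
        if self.tau < 0:
            raise ValidationError(f"peak tau must be >= 0, got {self.tau}")


@dataclass
class SimSpec:
    """One simulated trace: grid, peaks, baseline, drift, noise, seed."""

    duration: float
    interval: float
    peaks: list[PeakSpec] = field(default_factory=list)
    baseline: float = 0.0
    drift: float = 0.0  # signal units per x unit
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if self.interval <= 0:
            raise ValidationError(f"interval must be > 0, got {self.interval}")
        if self.noise_sd < 0:
            raise ValidationError(f"noise_sd must be >= 0, got {self.noise_sd}")

    @property
    def n_points(self) -> int:
        return int(np.floor(self.duration / self.interval + 1e-9)) + 1

    def grid(self) -> np.ndarray:
        return np.arange(self.n_points) * self.interval


def peak_profile(x: np.ndarray, peak: PeakSpec) -> np.ndarray:
    """Evaluate one peak on a grid.

    Pure Gaussian: h·exp(−(x−c)²/2σ²).  For tau > 0, the exponentially
    modified Gaussian with the same area A = h·σ·√(2π), in the
    numerically stable erfcx form:

        A/(2τ) · exp(−(x−c)²/2σ²) · erfcx((σ/τ − (x−c)/σ)/√2)

    Tiny tau (< σ·1e−6) falls back to the Gaussian to avoid overflow in
    the σ/τ terms.
    """
    x = np.asarray(x, dtype=float)
    z = (x - peak.center) / peak.sigma
    gauss = peak.height * np.exp(-0.5 * z * z)
    if peak.tau < peak.sigma * 1e-6:
        return gauss
    area = peak.height * peak.sigma * _SQRT2PI
    a = peak.sigma / peak.tau
    u = (a - z) / _SQRT2
    amp = area / (2.0 * peak.tau)
    out = np.empty_like(z)
    safe = u > -20.0  # erfcx overflows for very negative u (far right tail)
    out[safe] = amp * np.exp(-0.5 * z[safe] * z[safe]) * erfcx(u[safe])
    # far tail: erfc(u) == 2 to double precision, leaving pure exponential decay
    out[~safe] = 2.0 * amp * np.exp(0.5 * a * a - a * z[~safe])
    return out


def closed_form_signal(x: np.ndarray, spec: SimSpec) -> np.ndarray:
    """Noise-free signal: baseline + drift·x + sum of peaks."""
    x = np.asarray(x, dtype=float)
    y = np.full_like(x, float(spec.baseline)) + spec.drift * x
    for peak in spec.peaks:
        y = y + peak_profile(x, peak)
    return y


def simulate_xy(spec: SimSpec) -> tuple[np.ndarray, np.ndarray]:
    """Grid and signal, with seeded Gaussian noise when noise_sd > 0."""
    x = spec.grid()
    y = closed_form_signal(x, spec)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sd, size=len(x))
    return x, y


def simulate_trace(
    spec: SimSpec,
    sample: str = "sample-1",
    channel: str = "280 nm",
    experiment_id: str = "sim",
    x_unit: str = "time",
) -> TidyTable:
    """Simulate one trace as a single-group TidyTable."""
    x, y = simulate_xy(spec)
    df = pd.DataFrame(
        {
            "experiment": experiment_id,
            "sample": sample,
            "channel": channel,
            "time_min": np.nan,
            "volume_mL": np.nan,
            "signal": y,
            "signal_norm": np.nan,
        }
    )
    df["time_min" if x_unit == "time" else "volume_mL"] = x
    return TidyTable(df, x_unit)


def _random_peaks(rng: np.random.Generator, x_lo: float, x_hi: float,
                  sigma_lo: float, sigma_hi: float) -> list[PeakSpec]:
    n = int(rng.integers(1, 3))
    peaks = []
    for _ in range(n):
        peaks.append(
            PeakSpec(
                center=float(rng.uniform(x_lo, x_hi)),
                height=float(rng.uniform(20.0, 200.0)),
                sigma=float(rng.uniform(sigma_lo, sigma_hi)),
                tau=0.0,
            )
        )
    return peaks


def make_experiment_fixture(
    name: str,
    n_samples: int = 2,
    n_channels: int = 2,
    preparative: bool = False,
    seed: int = 0,
    noise_sd: float = 0.5,
) -> tuple[Experiment, dict]:
    """Build a seeded Experiment with known peak layouts.

    Analytic fixtures get ``n_samples × n_channels`` time-indexed traces on
    the default 3-minute grid; preparative fixtures get one sample with
    ``n_channels`` volume-indexed traces on the 24 mL grid, plus 0.5 mL
    fractions covering the main peak region.  The returned ground-truth
    dict records every SimSpec and the flow rate, so tests can recover
    exact expected values.  Same seed → bit-identical experiment.
    """
    if n_samples < 1 or n_channels < 1:
        raise ValidationError("n_samples and n_channels must be >= 1")
    rng = np.random.default_rng(seed)
    channels = [_CHANNEL_POOL[i % len(_CHANNEL_POOL)] for i in range(n_channels)]
    truth: dict = {
        "name": name,
        "seed": int(seed),
        "preparative": bool(preparative),
        "flow_rate": ANALYTIC_FLOW_RATE,
        "groups": {},
        "fractions": [],
    }
    frames = []
    fractions: list[FractionRecord] = []
    if preparative:
        sample = f"{name}-prep"
        main_center = float(rng.uniform(10.0, 16.0))
        for channel in channels:
            spec = SimSpec(
                duration=PREP_DURATION,
                interval=PREP_INTERVAL,
                peaks=[
                    PeakSpec(
                        center=main_center,
                        height=float(rng.uniform(50.0, 500.0)),
                        sigma=float(rng.uniform(0.3, 0.6)),
                    )
                ],
                baseline=float(rng.uniform(0.0, 2.0)),
                noise_sd=noise_sd,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            frames.append(simulate_trace(spec, sample, channel, name, "volume"))
            truth["groups"][f"{sample}||{channel}"] = _spec_dict(spec)
        # six 0.5 mL fraction marks spanning the main peak; last fraction
        # runs to the end of the trace per the boundary convention
        first_mark = np.round(main_center - 1.5, 1)
        marks = [float(first_mark + 0.5 * k) for k in range(6)]
        trace_end = frames[0].records["volume_mL"].max()
        for k, start in enumerate(marks):
            end = marks[k + 1] if k + 1 < len(marks) else float(trace_end)
            fractions.append(FractionRecord(label=f"{k + 1}", start=start, end=end))
        truth["fractions"] = [asdict(f) for f in fractions]
        experiment = Experiment(
            id=name,
            preparative=_concat(frames, "volume"),
            fractions=fractions,
        )
    else:
        for i in range(n_samples):
            sample = f"sample-{i + 1}"
            for channel in channels:
                spec = SimSpec(
                    duration=ANALYTIC_DURATION,
                    interval=ANALYTIC_INTERVAL,
                    peaks=_random_peaks(rng, 0.8, 2.4, 0.05, 0.12),
                    baseline=float(rng.uniform(0.0, 2.0)),
                    noise_sd=noise_sd,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                frames.append(simulate_trace(spec, sample, channel, name, "time"))
                truth["groups"][f"{sample}||{channel}"] = _spec_dict(spec)
        experiment = Experiment(id=name, analytic=_concat(frames, "time"))
    return experiment, truth


def _concat(tables: list[TidyTable], x_unit: str) -> TidyTable:
    return TidyTable(
        pd.concat([t.records for t in tables], ignore_index=True), x_unit
    )


def _spec_dict(spec: SimSpec) -> dict:
    d = asdict(spec)
    d["peaks"] = [asdict(p) for p in spec.peaks]
    return d


# -- dialect emitters ------------------------------------------------------

def _fmt(v: float) -> str:
    """Shortest decimal that round-trips the float exactly."""
    return repr(float(v))


def _safe_name(name: str) -> str:
    return "".join(c if c.isalnum() or c in "-_ " else "_" for c in name)


def _uniform_interval(x: np.ndarray, where: str) -> float:
    if len(x) < 2:
        return ANALYTIC_INTERVAL
    interval = float(x[1] - x[0])
    if not np.array_equal(np.arange(len(x)) * interval, x):
        raise ValidationError(f"{where}: non-uniform grid cannot be emitted")
    return interval


def _emit_waters(experiment: Experiment, out_dir: Path, flow_rate: float) -> list[Path]:
    paths = []
    for (sample, channel), sub in experiment.analytic.groups():
        path = out_dir / f"{_safe_name(sample)}_{_safe_name(channel)}.arw"
        lines = [
            "SampleName\tChannel\tFlowRate",
            f"{sample}\t{channel}\t{_fmt(flow_rate)}",
        ]
        for t, s in zip(sub["time_min"], sub["signal"]):
            lines.append(f"{_fmt(t)}\t{_fmt(s)}")
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def _emit_shimadzu(experiment: Experiment, out_dir: Path) -> list[Path]:
    paths = []
    df = experiment.analytic.records
    for sample in sorted(df["sample"].unique()):
        path = out_dir / f"{_safe_name(sample)}.txt"
        lines = [
            "[Header]",
            "Application Name\tLabSolutions",
            f"Sample Name\t{sample}",
            "",
        ]
        sub_s = df[df["sample"] == sample]
        for channel in sorted(sub_s["channel"].unique()):
            sub = sub_s[sub_s["channel"] == channel].sort_values("time_min")
            x = sub["time_min"].to_numpy()
            interval = _uniform_interval(x, f"{sample}/{channel}")
            msec = interval * 60000.0
            msec_text = str(int(round(msec))) if abs(msec - round(msec)) < 1e-6 else _fmt(msec)
            if np.float64(float(msec_text)) / 60000.0 != interval:
                raise ValidationError(
                    f"{sample}/{channel}: interval {interval} not exactly "
                    "representable in the Interval(msec) field"
                )
            lines.append(f"[LC Chromatogram({channel})]")
            lines.append(f"Interval(msec)\t{msec_text}")
            lines.append(f"# of Points\t{len(x)}")
            lines.append("Intensity Units\tmAU")
            for s in sub["signal"]:
                lines.append(_fmt(s))
            lines.append("")
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def _emit_agilent(experiment: Experiment, out_dir: Path) -> list[Path]:
    paths = []
    for (sample, channel), sub in experiment.analytic.groups():
        path = out_dir / f"{_safe_name(sample)}_{_safe_name(channel)}.csv"
        lines = ["Time,Signal"]
        for t, s in zip(sub["time_min"], sub["signal"]):
            lines.append(f"{_fmt(t)},{_fmt(s)}")
        path.write_text("\n".join(lines) + "\n")
        paths.append(path)
    return paths


def _emit_akta(experiment: Experiment, out_dir: Path) -> list[Path]:
    df = experiment.preparative.records
    samples = sorted(df["sample"].unique())
    if len(samples) != 1:
        raise ValidationError(
            "akta-csv holds one preparative run per file; got samples "
            f"{samples!r}"
        )
    sample = samples[0]
    channels = sorted(df["channel"].unique())
    columns: list[tuple[list[str], list[str]]] = []
    names: list[str] = []
    for channel in channels:
        sub = df[df["channel"] == channel].sort_values("volume_mL")
        columns.append(
            ([_fmt(v) for v in sub["volume_mL"]], [_fmt(s) for s in sub["signal"]])
        )
        names.append(channel)
    if experiment.fractions:
        marks = sorted(experiment.fractions, key=lambda f: f.start)
        columns.append(
            ([_fmt(f.start) for f in marks], [str(f.label) for f in marks])
        )
        names.append("Fraction")
    header1 = ",".join(f"{n}," for n in names).rstrip(",") + ","
    # units row: mL + signal unit per pair; fractions have no unit
    units = []
    for n in names:
        units.append("mL")
        units.append("" if n == "Fraction" else "mAU")
    n_rows = max(len(col[0]) for col in columns)
    lines = [header1, ",".join(units)]
    for row in range(n_rows):
        cells = []
        for xs, ys in columns:
            if row < len(xs):
                cells.extend([xs[row], ys[row]])
            else:
                cells.extend(["", ""])
        lines.append(",".join(cells))
    path = out_dir / f"{_safe_name(sample)}.csv"
    path.write_text("\n".join(lines) + "\n")
    return [path]


def emit_dialect_files(
    experiment: Experiment,
    dialect: str,
    out_dir,
    flow_rate: float = ANALYTIC_FLOW_RATE,
) -> list[Path]:
    """Write an experiment's traces as vendor export files.

    ``akta-csv`` requires a preparative experiment; the three HPLC dialects
    require analytic traces.  Returns the written paths.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if dialect == "akta-csv":
        if experiment.preparative.is_empty:
            raise ValidationError("akta-csv requires a preparative experiment")
        return _emit_akta(experiment, out_dir)
    if experiment.analytic.is_empty:
        raise ValidationError(f"{dialect} requires analytic traces")
    if dialect == "waters-arw":
        return _emit_waters(experiment, out_dir, flow_rate)
    if dialect == "shimadzu-ascii":
        return _emit_shimadzu(experiment, out_dir)
    if dialect == "agilent-csv":
        return _emit_agilent(experiment, out_dir)
    raise ValidationError(f"unknown dialect {dialect!r}")


@dataclass
class FixtureSet:
    """A generated fixture: emitted files, ground truth, and sidecar path."""

    experiment: Experiment
    ground_truth: dict
    paths: list[Path]
    sidecar: Path


def generate_fixture_set(
    name: str,
    dialect: str,
    out_dir,
    n_samples: int = 2,
    n_channels: int = 2,
    seed: int = 0,
    preparative: Optional[bool] = None,
    noise_sd: float = 0.5,
) -> FixtureSet:
    """Simulate an experiment, emit it in one dialect, and write the
    ground-truth sidecar (YAML: specs, seeds, per-file metadata)."""
    if preparative is None:
        preparative = dialect == "akta-csv"
    experiment, truth = make_experiment_fixture(
        name, n_samples, n_channels, preparative=preparative, seed=seed,
        noise_sd=noise_sd,
    )
    paths = emit_dialect_files(
        experiment, dialect, out_dir, flow_rate=truth["flow_rate"]
    )
    files_meta = {}
    if dialect == "akta-csv":
        files_meta[paths[0].name] = {"sample": experiment.preparative.samples()[0]}
    else:
        for (sample, channel), _ in experiment.analytic.groups():
            fname = f"{_safe_name(sample)}_{_safe_name(channel)}"
            ext = {"waters-arw": ".arw", "agilent-csv": ".csv"}.get(dialect)
            if dialect == "shimadzu-ascii":
                # sample and channel are in-file; only flow rate is external
                files_meta[f"{_safe_name(sample)}.txt"] = {
                    "flow_rate": truth["flow_rate"]
                }
            else:
                files_meta[fname + ext] = {
                    "sample": sample,
                    "channel": channel,
                    "flow_rate": truth["flow_rate"],
                }
    truth = dict(truth, dialect=dialect, files=files_meta)
    sidecar = Path(out_dir) / f"{_safe_name(name)}_ground_truth.yaml"
    sidecar.write_text(yaml.safe_dump(truth, sort_keys=True))
    return FixtureSet(experiment, truth, paths, sidecar)
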