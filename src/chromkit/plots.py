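"""Automatic static plots of processed experiments.

Analytic experiments render one panel per detector channel with one line
per injection; preparative experiments render the volume-indexed trace
with each collected fraction filled in a distinct color beneath the curve.
Rendering is deterministic: a fixed style, a stable palette keyed by
sorted sample labels, a fixed SVG hash salt, and stripped SVG metadata,
so identical inputs produce byte-identical SVG output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .errors import ValidationError
from .transform import Experiment, combine_experiments

_PALETTE = plt.get_cmap("tab10").colors
_FRACTION_PALETTE = plt.get_cmap("tab20").colors
_PANEL_SIZE = (7.0, 2.6)
_X_LABEL = {"time": "Time (min)", "volume": "Volume (mL)"}


@dataclass
class PlotSpec:
    """What to render and where."""

    experiment: Experiment
    normalized: bool = False
    view_range: Optional[tuple[float, float]] = None
    overlay_preparative: bool = False
    out_format: str = "svg"
    out_path: str = "plot.svg"

    def __post_init__(self) -> None:
        if self.out_format not in ("png", "svg"):
            raise ValidationError(f"out_format must be png or svg, got {self.out_format!r}")
        if self.view_range is not None and not self.view_range[0] < self.view_range[1]:
            raise ValidationError(f"view_range start must be < end, got {self.view_range}")


def _color_map(labels: list[str]) -> dict[str, tuple]:
    return {lab: _PALETTE[i % len(_PALETTE)] for i, lab in enumerate(sorted(labels))}


def _save(fig, spec: PlotSpec) -> str:
    path = Path(spec.out_path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with matplotlib.rc_context({"svg.hashsalt": "chromkit", "svg.fonttype": "none"}):
        if spec.out_format == "svg":
            fig.savefig(path, format="svg", metadata={"Date": None})
        else:
            fig.savefig(path, format="png", dpi=150)
    plt.close(fig)
    return str(path)


def build_analytic_figure(spec: PlotSpec):
    """Figure for the analytic table: one row per channel; with
    ``normalized``, a second column shows the normalized traces alongside
    the raw panels."""
    table = spec.experiment.analytic
    if table.is_empty:
        raise ValidationError("experiment has no analytic traces to plot")
    if spec.normalized and table.records["signal_norm"].isna().all():
        raise ValidationError("normalized plot requested but signal_norm is absent")
    channels = table.channels()
    colors = _color_map(table.samples())
    ncols = 2 if spec.normalized else 1
    overlay = spec.overlay_preparative and not spec.experiment.preparative.is_empty
    if overlay and table.records["volume_mL"].isna().all():
        raise ValidationError(
            "overlaying preparative traces requires analytic volumes "
            "(run add_volume first)"
        )
    xcol = "volume_mL" if overlay else table.x_column
    x_unit = "volume" if overlay else table.x_unit
    fig, axes = plt.subplots(
        len(channels),
        ncols,
        figsize=(_PANEL_SIZE[0] * ncols, _PANEL_SIZE[1] * len(channels)),
        squeeze=False,
    )
    df = table.records
    for row, channel in enumerate(channels):
        sub_c = df[df["channel"] == channel]
        for col, value_col in enumerate(
            ["signal", "signal_norm"][: ncols]
        ):
            ax = axes[row][col]
            for sample in sorted(sub_c["sample"].unique()):
                sub = sub_c[sub_c["sample"] == sample].sort_values(xcol)
                ax.plot(
                    sub[xcol], sub[value_col],
                    color=colors[sample], linewidth=1.0, label=sample,
                )
            if overlay and col == 0:
                prep = spec.experiment.preparative.records
                prep_c = prep[prep["channel"] == channel]
                for sample in sorted(prep_c["sample"].unique()):
                    sub = prep_c[prep_c["sample"] == sample].sort_values("volume_mL")
                    ax.plot(
                        sub["volume_mL"], sub["signal"],
                        color="0.3", linewidth=0.8, linestyle="--",
                        label=f"{sample} (prep)",
                    )
            kind = "normalized" if value_col == "signal_norm" else "raw"
            ax.set_title(f"{channel} ({kind})", fontsize=9)
            ax.set_xlabel(_X_LABEL[x_unit], fontsize=8)
            ax.set_ylabel("Normalized signal" if kind == "normalized" else "Signal", fontsize=8)
            if spec.view_range is not None:
                ax.set_xlim(*spec.view_range)
            ax.legend(fontsize=6, loc="upper right")
    fig.suptitle(spec.experiment.id, fontsize=10)
    fig.tight_layout()
    return fig


def plot_analytic(spec: PlotSpec) -> str:
    """Render the analytic panels to ``spec.out_path``."""
    return _save(build_analytic_figure(spec), spec)


def build_preparative_figure(spec: PlotSpec):
    """Figure for the preparative table: one panel per channel; fraction
    intervals are filled under the curve of the first channel panel."""
    table = spec.experiment.preparative
    if table.is_empty:
        raise ValidationError("experiment has no preparative traces to plot")
    value_col = "signal_norm" if (
        spec.normalized and not table.records["signal_norm"].isna().all()
    ) else "signal"
    channels = table.channels()
    colors = _color_map(table.samples())
    fig, axes = plt.subplots(
        len(channels), 1,
        figsize=(_PANEL_SIZE[0], _PANEL_SIZE[1] * len(channels)),
        squeeze=False,
    )
    df = table.records
    for row, channel in enumerate(channels):
        ax = axes[row][0]
        sub_c = df[df["channel"] == channel]
        for sample in sorted(sub_c["sample"].unique()):
            sub = sub_c[sub_c["sample"] == sample].sort_values("volume_mL")
            ax.plot(
                sub["volume_mL"], sub[value_col],
                color=colors[sample], linewidth=1.0, label=sample,
            )
            if row == 0 and spec.experiment.fractions:
                x = sub["volume_mL"].to_numpy()
                y = sub[value_col].to_numpy()
                for k, fraction in enumerate(spec.experiment.fractions):
                    mask = (x >= fraction.start) & (x <= fraction.end)
                    if not mask.any():
                        continue
                    ax.fill_between(
                        x[mask], 0.0, y[mask],
                        color=_FRACTION_PALETTE[k % len(_FRACTION_PALETTE)],
                        alpha=0.5, linewidth=0,
                    )
                    ax.annotate(
                        str(fraction.label),
                        ((fraction.start + fraction.end) / 2.0, 0.0),
                        xytext=(0, -10), textcoords="offset points",
                        ha="center", fontsize=6,
                    )
        ax.set_title(channel, fontsize=9)
        ax.set_xlabel(_X_LABEL["volume"], fontsize=8)
        ax.set_ylabel("Signal", fontsize=8)
        if spec.view_range is not None:
            ax.set_xlim(*spec.view_range)
        ax.legend(fontsize=6, loc="upper right")
    fig.suptitle(spec.experiment.id, fontsize=10)
    fig.tight_layout()
    return fig


def plot_preparative(spec: PlotSpec) -> str:
    """Render the preparative trace with fraction fills to ``spec.out_path``."""
    return _save(build_preparative_figure(spec), spec)


def plot_combined(experiments, spec: PlotSpec) -> str:
    """Combine experiments, then plot analytic panels when any experiment
    has analytic traces, preparative otherwise (fills are dropped by the
    combination rule)."""
    combined = combine_experiments(experiments)
    merged = PlotSpec(
        experiment=combined,
        normalized=spec.normalized,
        view_range=spec.view_range,
        overlay_preparative=spec.overlay_preparative,
        out_format=spec.out_format,
        out_path=spec.out_path,
    )
    if not combined.analytic.is_empty:
        return plot_analytic(merged)
    return plot_preparative(merged)
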