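"""Shared fixtures: seeded random tidy tables and full pipeline round trips."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from chromkit.core_model import TidyTable
from chromkit.fixtures import make_experiment_fixture, emit_dialect_files
from chromkit.parsers import (
    MetaSources,
    apply_run_metadata,
    parse_file,
    resolve_metadata,
)
from chromkit.transform import assemble_experiment

ALL_DIALECTS = ("waters-arw", "shimadzu-ascii", "agilent-csv", "akta-csv")


def random_tidy_table(
    rng: np.random.Generator,
    n_samples: int | None = None,
    n_channels: int | None = None,
    x_unit: str = "time",
) -> TidyTable:
    """A small tidy table with random grids per trace (grids may differ
    between traces, as channels can be acquired at different rates)."""
    n_samples = n_samples or int(rng.integers(1, 4))
    n_channels = n_channels or int(rng.integers(1, 3))
    xcol = "time_min" if x_unit == "time" else "volume_mL"
    frames = []
    for i in range(n_samples):
        for j in range(n_channels):
            n = int(rng.integers(2, 12))
            interval = float(rng.choice([0.1, 0.2, 0.25, 0.5]))
            x = np.arange(n) * interval
            df = pd.DataFrame(
                {
                    "experiment": "fixture",
                    "sample": f"S{i + 1}",
                    "channel": f"C{j + 1}",
                    "time_min": np.nan,
                    "volume_mL": np.nan,
                    "signal": rng.normal(10.0, 3.0, size=n),
                    "signal_norm": np.nan,
                }
            )
            df[xcol] = x
            frames.append(df)
    return TidyTable(pd.concat(frames, ignore_index=True), x_unit)


def pipeline_roundtrip(name: str, dialect: str, seed: int, tmp_path):
    """emit → detect → parse → resolve → assemble; returns (original
    experiment, reassembled experiment, ground truth)."""
    preparative = dialect == "akta-csv"
    experiment, truth = make_experiment_fixture(
        name, n_samples=2, n_channels=2, preparative=preparative, seed=seed
    )
    out_dir = tmp_path / f"{dialect}-{seed}"
    paths = emit_dialect_files(experiment, dialect, out_dir)
    # the agilent dialect is metadata-free by design: sample/channel come
    # back through the resolution chain, here fed from the emitter's
    # per-file ground truth (what a user would type in)
    per_file = {}
    if dialect == "agilent-csv":
        from chromkit.fixtures import _safe_name

        for key in truth["groups"]:
            sample, channel = key.split("||")
            per_file[f"{_safe_name(sample)}_{_safe_name(channel)}.csv"] = {
                "sample": sample,
                "channel": channel,
                "flow_rate": truth["flow_rate"],
            }
    sources = MetaSources(per_file=per_file, batch={"flow_rate": truth["flow_rate"]})
    runs = []
    for path in paths:
        for run in parse_file(path):
            if run.meta.instrument_kind == "hplc":
                run.meta = resolve_metadata(run.meta, sources)
            apply_run_metadata(run)
            runs.append(run)
    rebuilt = assemble_experiment(name, runs)
    return experiment, rebuilt, truth


def assert_tables_bit_identical(reference: TidyTable, rebuilt: TidyTable) -> None:
    """Signal and x values must survive emission and parsing bit-exactly."""
    a, b = reference.canonical(), rebuilt.canonical()
    assert len(a) == len(b)
    assert (a["sample"].to_numpy() == b["sample"].to_numpy()).all()
    assert (a["channel"].to_numpy() == b["channel"].to_numpy()).all()
    xcol = reference.x_column
    assert np.array_equal(a[xcol].to_numpy(), b[xcol].to_numpy())
    assert np.array_equal(a["signal"].to_numpy(), b["signal"].to_numpy())


@pytest.fixture
def rng():
    return np.random.default_rng(20230117)


@pytest.fixture
def analytic_experiment():
    experiment, truth = make_experiment_fixture("ana", 2, 2, seed=7)
    return experiment, truth


@pytest.fixture
def preparative_experiment():
    experiment, truth = make_experiment_fixture("prep", preparative=True, seed=11)
    return experiment, truth
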