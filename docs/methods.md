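# Methods

## Data model

The canonical in-memory form is a long ("tidy") table: one row per detector
reading of one injection on one channel at one x position. Time is in
minutes, volume in mL — the conventional units for HPLC/FPLC work. A table
carries an `x_unit` of `time` (analytic HPLC runs) or `volume` (preparative
FPLC runs); the inactive x column may be absent (NaN). For volume-indexed
AKTA data no acquisition time exists in the export, so `time_min` is left
absent there. Uniqueness and strict monotonicity of x are enforced per
(sample, channel) trace on the active x column.

The wide pivot uses the header convention `<sample> | <channel>`; names
containing the reserved separator `" | "` are rejected at ingest so the
reverse mapping is unambiguous. The wide x axis is the sorted union of all
traces' sampling grids; grids are unioned after rounding x to 9 decimals to
absorb float noise introduced by text parsing, while the emitted x values
themselves are taken unrounded from the data. Cells where a trace has no
reading are empty (NaN in memory, empty string in CSV). The pivot carries
only x and the raw signal: auxiliary columns (derived volume on a time axis,
`signal_norm`) belong to the tidy form. Within that content the round trip
tidy → wide → tidy is lossless and bit-exact; CSVs are written with
shortest-round-trip decimal representations and read back with
`float_precision="round_trip"` so file round trips are bit-exact too.

## Vendor dialects

The supported instrument families export text in characteristically
different shapes, and the package defines one canonical dialect per family:

* **waters-arw** — two tab-delimited header rows (field names, then values,
  including `SampleName`, `Channel`, and optionally `FlowRate`), then
  two-column time/signal rows. One file per (sample, channel).
* **shimadzu-ascii** — a `[Header]` section holding the sample name, then one
  `[LC Chromatogram(<channel>)]` block per detector with `Interval(msec)`
  and `# of Points` followed by one intensity per line. Times are
  reconstructed as `index × interval`; a declared point count that differs
  from the actual count is a parse error. Multi-detector blocks are treated
  as channels of one sample, not separate samples.
* **agilent-csv** — a bare two-column (time, signal) CSV, optionally headed
  by a `Time,Signal` line. The dialect carries no metadata at all: the file
  stem serves as a placeholder sample name, and channel and flow rate must
  be supplied through metadata resolution.
* **akta-csv** — a two-row header (curve names over units) above
  (volume, signal) column pairs, one pair per channel, optionally ending in
  a (volume, label) pair named `Fraction` whose rows mark fraction starts.
  Fractions are half-open `[start, next start)`; the last fraction closes at
  the end of the trace, partitioning the collected region without overlap.

Detection is by extension for `.arw` and otherwise by first-line sentinel
(`[Header]` → Shimadzu; the paired-name header pattern → AKTA; two numeric
columns → Agilent), with sentinels taking precedence over extension for
`.csv`/`.txt` files. Emitters in the fixture module write exactly these
layouts with shortest-round-trip number formatting, and the test suite
requires `parse(emit(experiment))` to reproduce every signal bit-identically —
the agreement property that anchors both sides. The Shimadzu emitter writes
`Interval(msec)` as an integer when the nominal value is integral and
verifies the parse-back division reproduces the original interval exactly.

Metadata resolution fills absent fields from the highest-precedence source:
file content, then per-file overrides, then batch overrides, then a
persisted YAML defaults file keyed by dialect name
(`$XDG_CONFIG_HOME/chromkit/defaults.yaml` by default). Interactive
prompting is injected as a callback so library code never touches a
terminal. An analytic run that ends resolution without a flow rate (needed
to derive volume) or a channel name is a hard error in non-interactive mode.

## Transforms

`add_volume` sets `volume = time × flow_rate` elementwise, retaining time.
`apply_scale` multiplies raw signals by a positive batch factor (to
reconcile e.g. flow-cell path lengths) and is applied before normalization,
so the order is observable only in the raw column.

`normalize_range` operates per (sample, channel) trace independently. With
`M` the maximum raw signal at x in the window and, in min-zero mode, `m` the
window minimum, every point of the whole trace maps to `s/M` or
`(s−m)/(M−m)`. The extrema come from the window but the mapping covers the
full trace, so out-of-window values can exceed 1 — which is what makes
peak-to-reference comparison meaningful. Degenerate traces (flat over the
window in min-zero mode, or non-positive maximum in max-only mode) raise a
named error rather than emitting NaN/Inf that would silently poison plots.
Results land in `signal_norm`; the raw column is bit-identical before and
after. The window minimum (not the whole-trace minimum) anchors min-zero
mode, mirroring the window-maximum rule. Ties for the maximum need no
tie-break since only the value is used.

Classification is rule-based: FPLC instrument → preparative; collected
fractions → preparative; otherwise analytic. Assembly merges runs of each
kind, renaming samples only on a true collision — the same (sample, channel)
trace claimed by two files — with a numeric suffix ("A (2)"); the same
sample on different channels is the ordinary multi-channel case and keeps
its name. Combination joins experiment ids with `+` (the share-URL form),
prefixes every sample with `"<experiment id>: "`, and drops fraction fills.

`percent_bound` is a peak-height heuristic, not a binding isotherm: height
stands in for area, which is adequate when bound and free species elute with
similar peak shapes, and the result is an approximate population split.

## Simulator

Traces are `baseline + drift·x + Σ peaks + N(0, noise_sd²)` on a uniform
grid of `floor(duration/interval) + 1` points. A peak is a Gaussian of
amplitude `height` and width `sigma`, or, with tailing constant `tau > 0`,
an exponentially modified Gaussian area-matched to that Gaussian
(area `h·σ·√(2π)` in both cases), evaluated in the numerically stable
`erfcx` form with an asymptotic pure-exponential branch in the far right
tail and a fallback to the pure Gaussian for `tau < σ·1e−6`. Noise comes
from a named, seeded `numpy` generator; every seed is recorded in the
ground-truth sidecar, so fixtures are bit-reproducible.

Default study conditions: analytic traces run 3 min at 300 ms sampling
(601 points) with flow 0.5 mL/min — a short FSEC run on a 5/150 SEC column;
preparative traces run 24 mL (one 10/300 column volume) at 0.05 mL sampling
with six 0.5 mL fractions spanning the main peak. Peak centers, heights
(20–200 signal units over a 0–2 unit baseline), widths, and a noise SD of
0.5 are drawn per seed within ranges typical of protein SEC data.

The simulator is phenomenological: peaks are ideal Gaussian/EMG shapes with
no plate-theory width dependence, no detector saturation, no injection
artifacts, and white (uncorrelated) noise. Passing tests therefore
demonstrate the correctness of parsing, bookkeeping, and arithmetic on
realistic-shaped data — not robustness to every pathology of real
chromatograms (ghost peaks, pressure spikes, drifting baselines beyond the
linear term).

## Plots and sharing

Analytic figures have one row per channel, one colored line per injection,
with a second column of normalized panels alongside the raw ones when
requested; preparative figures fill each fraction interval under the curve
with a distinct color and its label. Colors come from a fixed palette keyed
by sorted sample labels; SVG output fixes the hash salt, keeps text as text,
and strips date metadata, so identical inputs render byte-identical files —
which the determinism tests exploit. A `view_range` only crops the x axis;
normalization is always an explicit transform, never a side effect of
zooming.

Documents are column-oriented JSON (arrays per field, NaN as null) with a
`schema_version` for forward compatibility; reading an unknown version is a
versioned error. The filesystem store writes one canonical JSON file
(sorted keys, fixed indentation) per document, giving byte-stable round
trips; a remote CouchDB-style backend could implement the same
put/get/list contract but is not modeled. The URL codec renders range
bounds as minimal positional decimals (`view-range=1.93-2.13`); experiment
ids therefore may not contain `+ ? & = /`. The `norm-range` query key
parallels `view-range` for the normalization window. Unknown query keys are
ignored on decode.

## CLI

`chromkit process` chains detect → parse → resolve → volume/scale →
classify → assemble → normalize → CSV/plots/store and reports a summary
(optionally as JSON). The single `--normalize START END` window is in the
target table's own x unit and applies to the analytic table when present,
otherwise to the preparative table — one window cannot meaningfully span a
minutes axis and an mL axis at once. `--scale` and other parameter checks
run before any file is opened. A YAML config file can pre-populate options;
explicit flags win.

## Problem sizes in tests

The test suite exercises 200 randomized tidy↔wide round trips, 50 seeded
experiments per dialect through the full emit→parse pipeline, and
property-based checks (seeded/derandomized) of the codec; the acceptance
script uses 12-trace normalization sweeps, 200 round-trip tables, and 5
experiments per dialect. These sizes give exact (bit-identity) or
tight-tolerance checks while keeping the whole suite fast on one CPU.

## Known limitations

* Text exports only; proprietary binary formats (Empower projects, `.ch`,
  UNICORN result archives) are out of scope.
* One signal per channel per x — no PDA spectra or other 2D detector data.
* No peak calling, fitting, integration, or baseline correction beyond the
  min-to-zero normalization option.
* The wide form does not carry `signal_norm` or the derived volume column;
  use the tidy CSV for those.
* No HTTP server or live database; the document store is a directory.
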