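# chromkit

Chromatography export files are trapped in vendor-specific formats, each
readable only by the instrument's own software. For the day-to-day assays of
protein biochemistry — FSEC screens of expression constructs, preparative SEC
with fraction collection, binding shifts read off fluorescence traces — all a
scientist needs is the peak position, height, and shape, compared across
injections and instruments. `chromkit` converts the text exports of the four
major instrument families into one tidy data model, applies the simple
transforms those assays need, renders comparison plots automatically, and
packages everything into a shareable document with a URL-encoded view state.

## What it does

* **Parses four vendor dialects**, auto-detected per file:
  Waters/Empower-style tab-delimited ASCII (`.arw`), Shimadzu sectioned ASCII,
  bare two-column Agilent CSV, and AKTA/UNICORN paired-column CSV with
  fraction marks. Missing metadata (flow rate, channel name) is resolved
  through a precedence chain: file content → per-file overrides → batch
  overrides → a persisted per-user defaults file.
* **One canonical data model.** Every reading is a row of a *tidy* table
  `(experiment, sample, channel, time_min, volume_mL, signal, signal_norm)`;
  a lossless pivot produces the *wide* form (shared x column, one column per
  trace) for spreadsheet tools. Elution volume is derived as
  `volume = time × flow rate`.
* **Range-based normalization.** For each (sample, channel) trace
  independently, the signal is linearly rescaled so its maximum over a chosen
  x window is exactly 1.0; optionally the in-window minimum is anchored at 0:

  `s_norm = s / M` or `s_norm = (s − m) / (M − m)`,

  with `M` (`m`) the in-window maximum (minimum). The whole trace is mapped by
  the same line, so out-of-window values may exceed 1. Raw values are never
  overwritten — normalized and raw columns live side by side. No peak fitting
  or baseline subtraction is attempted beyond this.
* **Analytic vs preparative classification.** FPLC sources and any run with
  collected fractions are preparative (volume axis, fraction fills in plots);
  HPLC sources are analytic (one line per injection, one panel per channel).
* **Peak-ratio binding heuristic.** With a trace normalized to the free-species
  peak, `percent_bound(h_b, h_u) = 100·h_b/(h_b + h_u)` estimates the bound
  share of a population from relative peak heights (e.g. an unbound peak 4×
  the bound peak → 20% bound).
* **Shareable documents.** Experiments serialize to versioned JSON documents
  in a filesystem store, and a view (experiment list + zoom + normalization
  window) round-trips through a URL fragment such as
  `HPLC_Example_1+HPLC_Example_2?view-range=1.93-2.13`.
* **A built-in simulator** generates chromatograms with known Gaussian/EMG
  peaks and emits them in any vendor dialect, so the whole pipeline is
  testable without proprietary sample files.

## Worked example

Generate a simulated FSEC screen (3 injections, Waters export) and a
preparative SEC run (AKTA export with fractions), then process them into one
experiment:

```sh
chromkit fixture --dialect waters-arw --samples 3 --channels 1 --seed 8 \
    --name fsec-screen --out-dir raw
chromkit fixture --dialect akta-csv --seed 9 --name sec-prep --out-dir raw
chromkit process raw/*.arw raw/sec-prep-prep.csv --id SEC_demo \
    --normalize 0.5 2.5 --plots --out-dir out --store db --no-interactive
```

which prints:

```
processed 4 file(s): 3 analytic sample(s), 1 preparative sample(s), 2 channel(s), 6 fraction(s)
  wrote out/SEC_demo_analytic_tidy.csv
  wrote out/SEC_demo_analytic_wide.csv
  wrote out/SEC_demo_preparative_tidy.csv
  wrote out/SEC_demo_preparative_wide.csv
  wrote out/SEC_demo_fractions.csv
  wrote out/SEC_demo_analytic.svg
  wrote out/SEC_demo_preparative.svg
  wrote db/SEC_demo.json
```

The four export files were detected as their dialects, the three HPLC
injections became the analytic table (normalized over 0.5–2.5 min, raw and
normalized panels side by side in the SVG), and the AKTA run became the
preparative table with its six fractions filled under the trace. The tidy CSV
holds one observation per row:

```
experiment,sample,channel,time_min,volume_mL,signal,signal_norm
SEC_demo,sample-1,280 nm,0.0,0.0,0.9981199637484075,0.009057051884608404
SEC_demo,sample-1,280 nm,0.005,0.0025,1.4101780669321116,0.012796113075201773
```

`signal_norm` peaks at exactly 1.0 inside the normalization window for every
trace. The stored document in `db/` can be re-plotted with
`chromkit plot SEC_demo --store db` or listed with `chromkit db --store db
list`. Every subcommand documents its flags under `--help`.

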