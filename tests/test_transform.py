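"""Volume/scale/normalization transforms, classification, assembly, and
the peak-height / percent-bound readouts."""

import numpy as np
import pandas as pd
import pytest

from chromkit.core_model import TidyTable
from chromkit.errors import DegenerateTraceError, ValidationError
from chromkit.fixtures import PeakSpec, SimSpec, make_experiment_fixture, simulate_trace
from chromkit.parsers import ParsedRun, RunMeta
from chromkit.transform import (
    Experiment,
    FractionRecord,
    NormParams,
    add_volume,
    apply_scale,
    assemble_experiment,
    classify_run,
    combine_experiments,
    normalize_range,
    peak_height,
    percent_bound,
)

from conftest import random_tidy_table


def _single_trace(signals, x=None, x_unit="time"):
    x = np.arange(len(signals), dtype=float) if x is None else np.asarray(x, float)
    df = pd.DataFrame(
        {
            "experiment": "e",
            "sample": "A",
            "channel": "C",
            "time_min": np.nan,
            "volume_mL": np.nan,
            "signal": np.asarray(signals, float),
            "signal_norm": np.nan,
        }
    )
    df["time_min" if x_unit == "time" else "volume_mL"] = x
    return TidyTable(df, x_unit)


class TestAddVolume:
    def test_volume_is_time_times_flow(self):
        table = _single_trace([1.0, 2.0], x=[0.0, 2.0])
        out = add_volume(table, 0.5)
        assert list(out.records["volume_mL"]) == [0.0, 1.0]
        assert list(out.records["time_min"]) == [0.0, 2.0]  # time retained

    def test_elementwise_against_loop_oracle(self, rng):
        table = random_tidy_table(rng)
        out = add_volume(table, 0.73)
        for i, row in out.records.iterrows():
            assert row["volume_mL"] == row["time_min"] * 0.73

    def test_linearity_in_flow_rate(self, rng):
        table = random_tidy_table(rng)
        v1 = add_volume(table, 0.4).records["volume_mL"].to_numpy()
        v2 = add_volume(table, 0.8).records["volume_mL"].to_numpy()
        assert np.allclose(v2, 2 * v1)

    def test_nonpositive_flow_rejected(self):
        with pytest.raises(ValidationError, match="flow_rate"):
            add_volume(_single_trace([1.0]), 0.0)


class TestApplyScale:
    def test_identity_and_doubling(self):
        table = _single_trace([1.0, 3.0])
        assert apply_scale(table, 1.0).equals(table)
        assert list(apply_scale(table, 2.0).records["signal"]) == [2.0, 6.0]

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValidationError, match="factor"):
            apply_scale(_single_trace([1.0]), -1.0)


class TestNormalizeRange:
    FULL = NormParams(0.0, 10.0)

    def test_max_only_divides_by_range_max(self):
        out = normalize_range(_single_trace([2.0, 4.0, 8.0, 6.0]), self.FULL)
        assert list(out.records["signal_norm"]) == [0.25, 0.5, 1.0, 0.75]

    def test_zero_min_affine_map(self):
        out = normalize_range(
            _single_trace([2.0, 4.0, 8.0, 6.0]), NormParams(0.0, 10.0, zero_min=True)
        )
        assert out.records["signal_norm"].to_numpy() == pytest.approx(
            [0.0, 1 / 3, 1.0, 2 / 3]
        )

    def test_range_max_is_exactly_one(self, analytic_experiment):
        experiment, _ = analytic_experiment
        out = normalize_range(experiment.analytic, NormParams(0.5, 2.5))
        df = out.records
        for _, sub in df.groupby(["sample", "channel"]):
            in_range = sub[(sub["time_min"] >= 0.5) & (sub["time_min"] <= 2.5)]
            assert in_range["signal_norm"].max() == 1.0

    def test_raw_signal_untouched(self, analytic_experiment):
        experiment, _ = analytic_experiment
        before = experiment.analytic.records["signal"].to_numpy().copy()
        out = normalize_range(experiment.analytic, NormParams(0.5, 2.5))
        assert np.array_equal(out.records["signal"].to_numpy(), before)
        assert np.array_equal(
            experiment.analytic.records["signal"].to_numpy(), before
        )

    def test_out_of_range_points_scale_by_the_same_line(self):
        # max over the window only; the later larger value exceeds 1
        out = normalize_range(
            _single_trace([1.0, 4.0, 8.0], x=[0.0, 1.0, 2.0]), NormParams(0.0, 1.0)
        )
        assert list(out.records["signal_norm"]) == [0.25, 1.0, 2.0]

    def test_groups_normalized_independently(self, analytic_experiment):
        experiment, _ = analytic_experiment
        params = NormParams(0.5, 2.5)
        base = normalize_range(experiment.analytic, params)
        scaled = experiment.analytic.copy()
        mask = scaled.records["sample"] == "sample-1"
        scaled.records.loc[mask, "signal"] *= 10.0
        out = normalize_range(scaled, params)
        assert np.allclose(
            out.records["signal_norm"].to_numpy(),
            base.records["signal_norm"].to_numpy(),
        )

    @pytest.mark.parametrize("zero_min", [False, True])
    def test_scale_invariance(self, analytic_experiment, zero_min):
        experiment, _ = analytic_experiment
        params = NormParams(0.5, 2.5, zero_min=zero_min)
        direct = normalize_range(experiment.analytic, params)
        scaled = normalize_range(apply_scale(experiment.analytic, 7.0), params)
        assert np.allclose(
            direct.records["signal_norm"].to_numpy(),
            scaled.records["signal_norm"].to_numpy(),
        )

    def test_idempotence_max_only(self):
        table = _single_trace([2.0, 4.0, 8.0, 6.0])
        once = normalize_range(table, self.FULL)
        renorm_input = once.copy()
        renorm_input.records["signal"] = renorm_input.records["signal_norm"]
        twice = normalize_range(renorm_input, self.FULL)
        assert np.array_equal(
            twice.records["signal_norm"].to_numpy(),
            once.records["signal_norm"].to_numpy(),
        )

    def test_no_points_in_range_names_group(self):
        with pytest.raises(ValidationError, match="'A'.*'C'"):
            normalize_range(_single_trace([1.0, 2.0]), NormParams(5.0, 6.0))

    def test_flat_trace_is_degenerate_with_zero_min(self):
        with pytest.raises(DegenerateTraceError):
            normalize_range(
                _single_trace([3.0, 3.0, 3.0]), NormParams(0.0, 10.0, zero_min=True)
            )

    def test_nonpositive_max_is_degenerate(self):
        with pytest.raises(DegenerateTraceError):
            normalize_range(_single_trace([-1.0, -2.0]), self.FULL)


class TestClassifyRun:
    def test_fplc_is_preparative_even_without_fractions(self):
        assert classify_run(RunMeta(instrument_kind="fplc"), []) == "preparative"

    def test_fractions_force_preparative(self):
        meta = RunMeta(instrument_kind="hplc")
        assert classify_run(meta, [FractionRecord("1", 0.0, 1.0)]) == "preparative"

    def test_hplc_without_fractions_is_analytic(self):
        assert classify_run(RunMeta(instrument_kind="hplc"), []) == "analytic"


def _run(sample="A", channel="C", kind="hplc", fractions=()):
    table = _single_trace([1.0, 2.0], x_unit="time" if kind == "hplc" else "volume")
    table.records["sample"] = sample
    table.records["channel"] = channel
    meta = RunMeta(sample=sample, channel=channel, flow_rate=0.5, instrument_kind=kind)
    return ParsedRun(table, meta, list(fractions))


class TestAssembleExperiment:
    def test_mixed_runs_populate_both_tables(self):
        runs = [_run(f"S{i}") for i in range(3)] + [
            _run("P", "UV", "fplc", [FractionRecord("1", 0.0, 1.0)])
        ]
        experiment = assemble_experiment("mix", runs)
        assert len(experiment.analytic.samples()) == 3
        assert experiment.preparative.samples() == ["P"]
        assert len(experiment.fractions) == 1

    def test_duplicate_sample_and_channel_gets_suffix(self):
        experiment = assemble_experiment("dup", [_run("A"), _run("A")])
        assert experiment.analytic.samples() == ["A", "A (2)"]

    def test_same_sample_different_channel_is_not_a_duplicate(self):
        experiment = assemble_experiment(
            "multi", [_run("A", "280 nm"), _run("A", "GFP")]
        )
        assert experiment.analytic.samples() == ["A"]
        assert experiment.analytic.channels() == ["280 nm", "GFP"]

    def test_empty_run_list_rejected(self):
        with pytest.raises(ValidationError, match="nothing to assemble"):
            assemble_experiment("e", [])

    def test_reserved_characters_in_id_rejected(self):
        with pytest.raises(ValidationError, match="reserved"):
            assemble_experiment("a+b", [_run()])


class TestCombineExperiments:
    def _experiments(self):
        e1 = assemble_experiment("HPLC_Example_1", [_run("S1")])
        e2 = assemble_experiment("HPLC_Example_2", [_run("S1")])
        return e1, e2

    def test_combined_id_joined_with_plus(self):
        combined = combine_experiments(self._experiments())
        assert combined.id == "HPLC_Example_1+HPLC_Example_2"

    def test_samples_relabeled_with_experiment_prefix(self):
        combined = combine_experiments(self._experiments())
        assert combined.analytic.samples() == [
            "HPLC_Example_1: S1",
            "HPLC_Example_2: S1",
        ]

    def test_combined_preparative_drops_fractions(self):
        runs = lambda name: [
            _run(name, "UV", "fplc", [FractionRecord("1", 0.0, 1.0)])
        ]
        e1 = assemble_experiment("E1", runs("P1"))
        e2 = assemble_experiment("E2", runs("P2"))
        combined = combine_experiments([e1, e2])
        assert combined.fractions == []
        assert len(combined.preparative.samples()) == 2

    def test_single_experiment_rejected(self):
        with pytest.raises(ValidationError, match="at least two"):
            combine_experiments([self._experiments()[0]])

    def test_duplicate_ids_rejected(self):
        e1, _ = self._experiments()
        with pytest.raises(ValidationError, match="duplicate"):
            combine_experiments([e1, e1])


class TestPeakReadouts:
    def test_peak_height_recovers_simulator_ground_truth(self):
        spec = SimSpec(
            duration=3.0, interval=0.005,
            peaks=[PeakSpec(center=1.5, height=120.0, sigma=0.08)],
            noise_sd=0.0,
        )
        table = simulate_trace(spec)
        assert peak_height(table, "sample-1", "280 nm", (1.0, 2.0)) == pytest.approx(
            120.0, rel=1e-9
        )

    def test_range_excluding_peak_on_flat_baseline_is_zero(self):
        spec = SimSpec(
            duration=3.0, interval=0.01,
            peaks=[PeakSpec(center=1.0, height=50.0, sigma=0.01)],
        )
        table = simulate_trace(spec)
        assert peak_height(table, "sample-1", "280 nm", (2.5, 3.0)) == pytest.approx(
            0.0, abs=1e-9
        )

    def test_normalized_trace_height_over_norm_range_is_one(self):
        table = normalize_range(_single_trace([2.0, 4.0, 8.0, 6.0]), NormParams(0, 10))
        assert peak_height(table, "A", "C", (0.0, 10.0)) == 1.0

    def test_empty_selection_rejected(self):
        with pytest.raises(ValidationError, match="no points"):
            peak_height(_single_trace([1.0]), "A", "C", (5.0, 6.0))

    def test_percent_bound_matches_four_to_one_heuristic(self):
        # unbound peak 4x higher than bound -> ~20% of the population bound
        assert percent_bound(0.25, 1.0) == pytest.approx(20.0)

    def test_percent_bound_edge_cases(self):
        assert percent_bound(0.0, 1.0) == 0.0
        assert percent_bound(0.7, 0.7) == 50.0
        with pytest.raises(ValidationError):
            percent_bound(0.0, 0.0)


class TestExperimentInvariants:
    def test_overlapping_fractions_rejected(self):
        with pytest.raises(ValidationError, match="overlap"):
            Experiment(
                id="e",
                fractions=[FractionRecord("1", 0.0, 2.0), FractionRecord("2", 1.0, 3.0)],
            )

    def test_fractions_sorted_on_construction(self):
        experiment = Experiment(
            id="e",
            fractions=[FractionRecord("2", 1.0, 2.0), FractionRecord("1", 0.0, 1.0)],
        )
        assert [f.label for f in experiment.fractions] == ["1", "2"]

    def test_inverted_fraction_rejected(self):
        with pytest.raises(ValidationError, match="start"):
            FractionRecord("1", 2.0, 1.0)
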