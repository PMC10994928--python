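"""Stimulation masking, baseline normalization, aggregates, statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from meapipe.bursts import WellMetrics, well_metrics
from meapipe.core import SpikeTrain, WellRecording
from meapipe.spikes import mean_firing_rate
from meapipe.timecourse import (
    StimulationSchedule,
    aggregate_condition,
    bonferroni,
    compare_conditions,
    mask_stimulation_windows,
    normalize_to_baseline,
    tidy_table,
)


def metrics(well_id="w00", condition="untreated", t=0.0, mfr=1.0, nbr=2.0, nbd=1.0):
    return WellMetrics(
        well_id=well_id, condition=condition, timepoint_h=t, mfr=mfr, nbr=nbr, nbd=nbd,
        n_active=12, n_bursting=10, n_network_bursts=int(nbr * 10), analyzed_duration=600.0,
    )


class TestMasking:
    def test_three_minute_epoch_leaves_seven_analyzed_minutes(self):
        trains = {"e00": SpikeTrain(np.linspace(1, 599, 100), 600.0, "e00")}
        well = WellRecording(trains, 600.0, stimulation_epochs=[(0.0, 180.0)])
        masked = mask_stimulation_windows(well, StimulationSchedule(((0.0, 180.0),)))
        assert masked.duration == pytest.approx(420.0)
        assert masked.stimulation_epochs == []

    def test_empty_schedule_is_identity(self):
        trains = {"e00": SpikeTrain([1.0, 2.0], 600.0, "e00")}
        well = WellRecording(trains, 600.0)
        assert mask_stimulation_windows(well, StimulationSchedule()) is well

    def test_homogeneous_rate_invariant_under_masking(self):
        times = np.arange(0.5, 600.0, 1.0)  # uniform 1 /s
        well = WellRecording({"e00": SpikeTrain(times, 600.0, "e00")}, 600.0)
        masked = mask_stimulation_windows(well, StimulationSchedule(((0.0, 180.0),)))
        assert mean_firing_rate(masked) == pytest.approx(1.0, abs=0.01)

    def test_full_coverage_rejected(self):
        well = WellRecording({"e00": SpikeTrain([1.0], 10.0, "e00")}, 10.0)
        with pytest.raises(ValueError):
            mask_stimulation_windows(well, StimulationSchedule(((0.0, 10.0),)))

    def test_overlapping_epochs_rejected(self):
        with pytest.raises(ValueError):
            StimulationSchedule(((0.0, 10.0), (5.0, 15.0)))

    def test_masking_equals_concatenation_of_unmasked_segments(self, rng):
        """Spike trains after masking match an independently built
        concatenation of the unmasked segments, for random schedules."""
        for _ in range(20):
            duration = 100.0
            times = np.sort(rng.uniform(0, duration, 300))
            times = times[np.concatenate(([True], np.diff(times) > 0))]
            n_ep = rng.integers(1, 4)
            edges = np.sort(rng.uniform(0, duration, 2 * n_ep))
            epochs = tuple((edges[2 * i], edges[2 * i + 1]) for i in range(n_ep))
            if sum(b - a for a, b in epochs) >= duration - 1.0:
                continue
            well = WellRecording({"e00": SpikeTrain(times, duration, "e00")}, duration)
            masked = mask_stimulation_windows(well, StimulationSchedule(epochs))
            # oracle: concatenate segments between epochs
            segs, cursor, expected = [], 0.0, []
            bounds = [e for ep in epochs for e in ep] + [duration]
            offset = 0.0
            prev = 0.0
            keep_start = 0.0
            cut = 0.0
            pieces = []
            last = 0.0
            for a, b in epochs:
                pieces.append((last, a))
                last = b
            pieces.append((last, duration))
            shifted = []
            acc = 0.0
            for a, b in pieces:
                seg = times[(times >= a) & (times < b)]
                shifted.append(seg - a + acc)
                acc += b - a
            oracle = np.concatenate(shifted)
            assert masked.duration == pytest.approx(acc)
            np.testing.assert_allclose(masked.trains["e00"].times, oracle, atol=1e-9)


class TestNormalization:
    def test_division_by_baseline(self):
        series = [metrics(t=0.0, mfr=2.0, nbr=4.0), metrics(t=2.0, mfr=1.0, nbr=2.0)]
        ns = normalize_to_baseline(series)
        assert ns.values["mfr"][0] == pytest.approx(1.0)
        assert ns.values["mfr"][1] == pytest.approx(0.5)
        assert ns.values["nbr"][1] == pytest.approx(0.5)

    def test_zero_baseline_metric_flagged_excluded(self):
        series = [metrics(t=0.0, nbr=0.0, mfr=2.0), metrics(t=2.0, nbr=1.0, mfr=1.0)]
        ns = normalize_to_baseline(series)
        assert "nbr" in ns.excluded_metrics
        assert np.isnan(ns.values["nbr"]).all()
        assert ns.values["mfr"][1] == pytest.approx(0.5)

    def test_missing_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_to_baseline([metrics(t=2.0)])

    def test_scale_invariance(self):
        base = [metrics(t=0.0, mfr=2.0, nbr=4.0, nbd=1.0), metrics(t=2.0, mfr=1.0, nbr=3.0, nbd=0.5)]
        c = 3.7
        scaled = [
            metrics(t=m.timepoint_h, mfr=c * m.mfr, nbr=c * m.nbr, nbd=c * m.nbd) for m in base
        ]
        a, b = normalize_to_baseline(base), normalize_to_baseline(scaled)
        for k in ("mfr", "nbr", "nbd"):
            np.testing.assert_allclose(a.values[k], b.values[k])


class TestAggregation:
    def _series(self, well_id, vals):
        ms = [metrics(well_id=well_id, t=2.0 * i, nbr=v * 2.0) for i, v in enumerate(vals)]
        ms[0] = metrics(well_id=well_id, t=0.0, nbr=2.0)
        return normalize_to_baseline(ms)

    def test_mean_and_sem(self):
        agg = aggregate_condition([self._series("w00", [1.0, 0.4]), self._series("w01", [1.0, 0.6])])
        assert agg.mean["nbr"][1] == pytest.approx(0.5)
        assert agg.sem["nbr"][1] == pytest.approx(0.1)
        assert agg.n_wells["nbr"][1] == 2

    def test_single_well_sem_undefined(self):
        agg = aggregate_condition([self._series("w00", [1.0, 0.4])])
        assert np.isnan(agg.sem["nbr"][1])

    def test_identical_wells_sem_zero(self):
        agg = aggregate_condition([self._series(f"w{i}", [1.0, 0.5]) for i in range(4)])
        assert agg.sem["nbr"][1] == pytest.approx(0.0)

    def test_mixed_conditions_rejected(self):
        a = self._series("w00", [1.0, 0.4])
        b = self._series("w01", [1.0, 0.4])
        b.condition = "other"
        with pytest.raises(ValueError):
            aggregate_condition([a, b])


def two_group_frame(a, b, t=2.0):
    rows = []
    for i, v in enumerate(a):
        rows.append({"condition": "untreated", "well_id": f"u{i}", "timepoint_h": t, "value": v})
    for i, v in enumerate(b):
        rows.append({"condition": "treated", "well_id": f"t{i}", "timepoint_h": t, "value": v})
    return pd.DataFrame(rows)


class TestComparisons:
    def test_identical_groups_not_significant(self, rng):
        x = rng.normal(0, 1, 10)
        res = compare_conditions(two_group_frame(x, x))
        assert res[0].p_value > 0.05

    def test_separated_groups_highly_significant(self, rng):
        a = rng.normal(0, 1, 10)
        b = rng.normal(5, 1, 10)
        res = compare_conditions(two_group_frame(a, b))
        assert res[0].p_value < 0.001

    def test_two_group_p_matches_reference_routine(self, rng):
        """Wrapper p-values agree with direct scipy calls to 1e-10."""
        a = rng.normal(0, 1, 12)
        b = rng.normal(0.5, 1, 12)
        res = compare_conditions(two_group_frame(a, b))[0]
        if res.test == "t-test":
            ref = stats.ttest_ind(a, b).pvalue
        else:
            ref = stats.mannwhitneyu(a, b, alternative="two-sided").pvalue
        assert res.p_value == pytest.approx(ref, abs=1e-10)

    def test_bonferroni_formula(self):
        assert bonferroni(0.02, 12) == pytest.approx(0.24)
        assert bonferroni(0.2, 12) == 1.0

    def test_adjustment_uses_timepoint_family(self, rng):
        frames = [two_group_frame(rng.normal(0, 1, 6), rng.normal(0, 1, 6), t=2.0 * k) for k in range(12)]
        df = pd.concat(frames, ignore_index=True)
        res = compare_conditions(df)
        assert len(res) == 12
        for r in res:
            assert r.adjusted_p == pytest.approx(min(1.0, 12 * r.p_value))
            assert r.adjusted_p >= r.p_value

    def test_small_group_rejected(self):
        df = two_group_frame([1.0], [2.0, 3.0])
        with pytest.raises(ValueError):
            compare_conditions(df)

    def test_factorial_design_reports_anova_terms(self, rng):
        frames = [
            two_group_frame(rng.normal(1 - 0.1 * k, 0.2, 6), rng.normal(1.0, 0.2, 6), t=2.0 * k)
            for k in range(4)
        ]
        df = pd.concat(frames, ignore_index=True)
        res = compare_conditions(df, design="factorial")
        labels = [r.label for r in res]
        assert "anova:C(condition)" in labels
        assert "anova:C(condition):C(timepoint_h)" in labels


def test_tidy_table_roundtrip_columns():
    series = normalize_to_baseline([metrics(t=0.0), metrics(t=2.0, mfr=0.5)])
    df = tidy_table([series])
    assert set(df.columns) == {"condition", "well_id", "timepoint_h", "metric", "value"}
    assert len(df) == 2 * 3
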