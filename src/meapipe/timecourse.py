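"""Hypoxia time-course assembly: stimulation masking, baseline
normalization, condition aggregates and statistical comparisons.

Each well is recorded at baseline (normoxia) and every 2 h of hypoxia.  Per
timepoint metrics (MFR, NBR, NBD) are divided by the same well's baseline
values; wells with a zero (or undefined) baseline for a metric are excluded
from that metric's aggregate.  In optogenetic-activation conditions the
3-minute stimulation windows are removed before any metric is computed, and
all rates use the reduced analyzed duration.

Statistical comparisons are thin wrappers over established routines
(scipy / statsmodels): Kolmogorov--Smirnov normality screen, unpaired
t-test or Mann-Whitney for two groups, two-way ANOVA plus per-timepoint
Bonferroni-corrected pairwise tests for factorial designs.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .bursts import WellMetrics
from .core import SpikeTrain, WellRecording

__all__ = [
    "StimulationSchedule",
    "NormalizedSeries",
    "ConditionAggregate",
    "StatResult",
    "mask_stimulation_windows",
    "normalize_to_baseline",
    "aggregate_condition",
    "tidy_table",
    "compare_conditions",
]

METRICS = ("mfr", "nbr", "nbd")


@dataclass(frozen=True)
class StimulationSchedule:
    """Stimulation epochs within each recording, plus the recording period."""

    epochs: Tuple[Tuple[float, float], ...] = ()
    period_h: float = 2.0

    def __post_init__(self) -> None:
        eps = sorted(self.epochs)
        object.__setattr__(self, "epochs", tuple((float(a), float(b)) for a, b in eps))
        for (a, b) in self.epochs:
            if b <= a or a < 0:
                raise ValueError("epochs must be non-empty forward intervals")
        for (_, b1), (a2, _) in zip(self.epochs, self.epochs[1:]):
            if a2 < b1:
                raise ValueError("epochs must be disjoint")

    @property
    def total_length(self) -> float:
        return sum(b - a for a, b in self.epochs)

    @classmethod
    def activation_default(cls) -> "StimulationSchedule":
        """Light for the first 3 minutes of each recording, every 2 h."""
        return cls(epochs=((0.0, 180.0),), period_h=2.0)


def _compress_times(times: np.ndarray, epochs: Sequence[Tuple[float, float]]) -> np.ndarray:
    """Drop spikes inside epochs; map the rest onto the concatenated
    timeline of the unmasked segments."""
    keep = np.ones(times.size, dtype=bool)
    shift = np.zeros(times.size)
    offset = 0.0
    for a, b in epochs:
        inside = (times >= a) & (times < b)
        keep &= ~inside
        shift[times >= b] += b - a
        offset += b - a
    return times[keep] - shift[keep]


def mask_stimulation_windows(well: WellRecording, sched: StimulationSchedule) -> WellRecording:
    """Remove stimulation windows from a recording.

    Spikes inside the epochs are dropped and the remaining spikes are placed
    on the concatenation of the unmasked segments, so downstream burst and
    rate computations see a single contiguous recording of the analyzed
    duration.  Metrics computed after masking are therefore identical to
    metrics computed on the concatenated unmasked segments.
    """
    epochs = [e for e in sched.epochs if e[0] < well.duration]
    epochs = [(a, min(b, well.duration)) for a, b in epochs]
    total = sum(b - a for a, b in epochs)
    analyzed = well.duration - total
    if analyzed <= 0:
        raise ValueError("stimulation epochs cover the whole recording")
    if not epochs:
        return well
    trains = {
        eid: SpikeTrain(_compress_times(t.times, epochs), analyzed, eid)
        for eid, t in well.trains.items()
    }
    return WellRecording(
        trains=trains,
        duration=analyzed,
        well_id=well.well_id,
        condition=well.condition,
        timepoint_h=well.timepoint_h,
        stimulation_epochs=[],
    )


@dataclass
class NormalizedSeries:
    """Baseline-normalized metric time-course of one well.

    Metrics with a zero or undefined baseline are NaN at every timepoint
    and carry a flag in ``excluded_metrics``; they are skipped by
    :func:`aggregate_condition` for this well only.
    """

    well_id: str
    condition: str
    timepoints: np.ndarray  # hours
    values: Dict[str, np.ndarray]  # metric -> normalized sequence
    baseline: WellMetrics
    excluded_metrics: set = field(default_factory=set)


def normalize_to_baseline(
    series: Sequence[WellMetrics], baseline: Optional[WellMetrics] = None
) -> NormalizedSeries:
    """Divide each metric by the same well's normoxia value.

    If ``baseline`` is omitted, the entry of ``series`` at timepoint 0 is
    used.  NBD values that are NaN (no network bursts at that timepoint)
    stay NaN without excluding the whole metric.
    """
    series = sorted(series, key=lambda m: m.timepoint_h)
    if baseline is None:
        at_zero = [m for m in series if m.timepoint_h == 0]
        if not at_zero:
            raise ValueError("no baseline (timepoint 0) recording in series")
        baseline = at_zero[0]
    tp = np.array([m.timepoint_h for m in series], dtype=float)
    values: Dict[str, np.ndarray] = {}
    excluded = set()
    for metric in METRICS:
        base = getattr(baseline, metric)
        raw = np.array([getattr(m, metric) for m in series], dtype=float)
        if not np.isfinite(base) or base == 0:
            values[metric] = np.full(tp.size, np.nan)
            excluded.add(metric)
        else:
            values[metric] = raw / base
    return NormalizedSeries(
        well_id=baseline.well_id,
        condition=baseline.condition,
        timepoints=tp,
        values=values,
        baseline=baseline,
        excluded_metrics=excluded,
    )


@dataclass
class ConditionAggregate:
    """Mean +/- SEM of normalized metrics across wells of one condition."""

    condition: str
    timepoints: np.ndarray
    mean: Dict[str, np.ndarray]
    sem: Dict[str, np.ndarray]
    n_wells: Dict[str, np.ndarray]


def _sem(x: np.ndarray) -> float:
    x = x[np.isfinite(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / math.sqrt(x.size))


def aggregate_condition(series_list: Sequence[NormalizedSeries]) -> ConditionAggregate:
    """Per-timepoint mean and SEM over wells; excluded metrics are skipped
    per well, and n reflects the wells actually contributing."""
    if not series_list:
        raise ValueError("need at least one well")
    conditions = {s.condition for s in series_list}
    if len(conditions) != 1:
        raise ValueError(f"series span several conditions: {sorted(conditions)}")
    tp = series_list[0].timepoints
    for s in series_list[1:]:
        if not np.array_equal(s.timepoints, tp):
            raise ValueError("wells have mismatched timepoint grids")
    mean, sem, n_wells = {}, {}, {}
    for metric in METRICS:
        stack = np.vstack([s.values[metric] for s in series_list])
        finite = np.isfinite(stack)
        n = finite.sum(axis=0)
        with np.errstate(invalid="ignore"):
            mu = np.where(n > 0, np.nansum(np.where(finite, stack, 0.0), axis=0) / np.maximum(n, 1), np.nan)
        mean[metric] = mu
        sem[metric] = np.array([_sem(stack[:, j]) for j in range(tp.size)])
        n_wells[metric] = n
    return ConditionAggregate(conditions.pop(), tp, mean, sem, n_wells)


def tidy_table(series_list: Sequence[NormalizedSeries]) -> pd.DataFrame:
    """Long-format table: condition, well_id, timepoint_h, metric, value."""
    rows = []
    for s in series_list:
        for metric in METRICS:
            for t, v in zip(s.timepoints, s.values[metric]):
                rows.append(
                    {
                        "condition": s.condition,
                        "well_id": s.well_id,
                        "timepoint_h": float(t),
                        "metric": metric,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows)


@dataclass
class StatResult:
    label: str
    test: str
    statistic: float
    p_value: float
    adjusted_p: float
    timepoint: Optional[float] = None


def _two_group_test(a: np.ndarray, b: np.ndarray, alpha: float = 0.05):
    """KS-normality-screened two-group test.

    Both groups normal (Lilliefors-corrected KS, p > alpha) -> unpaired
    t-test; otherwise Mann-Whitney.  Groups too small to screen (< 5) fall
    back to Mann-Whitney.
    """
    from statsmodels.stats.diagnostic import kstest_normal

    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs n >= 2")
    normal = False
    if a.size >= 5 and b.size >= 5 and np.std(a) > 0 and np.std(b) > 0:
        pa = kstest_normal(a, dist="norm")[1]
        pb = kstest_normal(b, dist="norm")[1]
        normal = pa > alpha and pb > alpha
    if normal:
        stat, p = stats.ttest_ind(a, b)
        return "t-test", float(stat), float(p)
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return "mann-whitney", float(stat), float(p)


def bonferroni(p: float, m: int) -> float:
    """Bonferroni-adjusted p-value: min(1, m * p)."""
    return min(1.0, m * p)


def compare_conditions(df: pd.DataFrame, design: str = "two_group") -> List[StatResult]:
    """Compare conditions at every timepoint on raw per-well values.

    ``df`` is a long-format table with columns ``condition``, ``well_id``,
    ``timepoint_h`` and ``value`` (one metric at a time; filter a
    :func:`tidy_table` first).  The Bonferroni family for each condition
    pair is the set of per-timepoint comparisons.

    ``design="two_group"`` runs the normality-screened two-group test per
    timepoint.  ``design="factorial"`` first fits a two-way ANOVA
    (condition x timepoint, statsmodels OLS) and reports its factor
    p-values, then the per-timepoint pairwise comparisons.
    """
    required = {"condition", "well_id", "timepoint_h", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"table must have columns {sorted(required)}")
    df = df.dropna(subset=["value"])
    conditions = sorted(df["condition"].unique())
    timepoints = sorted(df["timepoint_h"].unique())
    results: List[StatResult] = []

    if design == "factorial":
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        model = smf.ols("value ~ C(condition) * C(timepoint_h)", data=df).fit()
        table = sm.stats.anova_lm(model, typ=2)
        for term in ("C(condition)", "C(timepoint_h)", "C(condition):C(timepoint_h)"):
            if term in table.index:
                p = float(table.loc[term, "PR(>F)"])
                results.append(
                    StatResult(
                        label=f"anova:{term}",
                        test="two-way ANOVA",
                        statistic=float(table.loc[term, "F"]),
                        p_value=p,
                        adjusted_p=p,
                    )
                )
    elif design != "two_group":
        raise ValueError(f"unknown design {design!r}")

    m = len(timepoints)
    for c1, c2 in itertools.combinations(conditions, 2):
        for t in timepoints:
            a = df.query("condition == @c1 and timepoint_h == @t")["value"].to_numpy()
            b = df.query("condition == @c2 and timepoint_h == @t")["value"].to_numpy()
            if a.size < 2 or b.size < 2:
                raise ValueError(f"n < 2 for {c1} vs {c2} at t={t}")
            test, stat, p = _two_group_test(a, b)
            results.append(
                StatResult(
                    label=f"{c1} vs {c2}",
                    test=test,
                    statistic=stat,
                    p_value=p,
                    adjusted_p=bonferroni(p, m),
                    timepoint=float(t),
                )
            )
    return results
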