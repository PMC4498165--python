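"""Firing-rate dynamics across timescales.

Feeding-related rate changes are quantified three ways, all on 5-s binned
rates: (i) an auROC timecourse — the discriminability of each sliding 1-min
window's rate distribution from the 5-min pre-lickspout baseline (0.5 = no
change, 1 = all window rates above all baseline rates, 0 = all below);
(ii) two-sample KS tests of each feeding epoch (cue, 0-5, 5-15, 15-45 min
post food) against baseline at alpha = 0.025; (iii) a bounded modulation
index (a - b)/(a + b).  Slower diurnal effects use per-unit session means
(AM vs PM t-test) and the rate of short-ISI (< 50 ms) burst-like events;
ISI structure is summarized by the CV of log10(ISI) and Hartigan's dip test
of unimodality.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import DynamicsConfig
from .dip import dip_test
from .types import SessionTimeline, SpikeTrain

EPOCH_NAMES = ("CUE", "EARLY", "MID", "LATE")


@dataclass
class RateSeries:
    """Binned firing rate on contiguous half-open bins."""

    bin_width: float
    start_times: np.ndarray
    rates: np.ndarray

    def __post_init__(self) -> None:
        self.start_times = np.asarray(self.start_times, dtype=float)
        self.rates = np.asarray(self.rates, dtype=float)
        if np.any(self.rates < 0):
            raise ValueError("rates must be >= 0")

    @property
    def n_bins(self) -> int:
        return self.rates.size

    def select(self, t0: float, t1: float) -> np.ndarray:
        """Rates of bins whose start time falls in [t0, t1)."""
        mask = (self.start_times >= t0) & (self.start_times < t1)
        return self.rates[mask]


def bin_rates(train: SpikeTrain, bin_width: float,
              span: Tuple[float, float]) -> RateSeries:
    """Spike count in [t, t + bin) divided by the bin width."""
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    t0, t1 = span
    if t1 - t0 < bin_width:
        raise ValueError("span shorter than one bin")
    n_bins = int(np.floor((t1 - t0) / bin_width))
    edges = t0 + np.arange(n_bins + 1) * bin_width
    counts = np.diff(np.searchsorted(train.times, edges))
    return RateSeries(bin_width, edges[:-1], counts / bin_width)


def auroc(baseline: np.ndarray, test: np.ndarray) -> float:
    """P(random test value > random baseline value), ties counted half.

    Equals the Mann-Whitney U statistic divided by n1*n2 (midrank ties), so
    auroc(A, B) + auroc(B, A) = 1 and the value is invariant under strictly
    monotone transforms applied to both samples.
    """
    baseline = np.asarray(baseline, dtype=float)
    test = np.asarray(test, dtype=float)
    if baseline.size == 0 or test.size == 0:
        raise ValueError("both samples must be nonempty")
    ranks = stats.rankdata(np.concatenate([test, baseline]))
    r_test = ranks[: test.size].sum()
    u = r_test - test.size * (test.size + 1) / 2.0
    return float(u / (test.size * baseline.size))


def baseline_window(timeline: SessionTimeline,
                    config: Optional[DynamicsConfig] = None) -> Tuple[float, float]:
    """Up to 5 min immediately before lickspout placement."""
    config = config or DynamicsConfig()
    start = max(timeline.baseline_start,
                timeline.lickspout_time - config.baseline_span_s)
    return start, timeline.lickspout_time


@dataclass
class AurocTimecourse:
    """Sliding-window auROC vs the fixed pre-lickspout baseline."""

    window_starts: np.ndarray
    auroc: np.ndarray
    window_s: float
    baseline_span: Tuple[float, float]


def lick_mask(series: RateSeries, lick_times: np.ndarray,
              window_s: float) -> np.ndarray:
    """True for bins with no lick within ``window_s`` of the bin start.

    Used for the lick-exclusive re-analysis: bins near licks are dropped so
    feeding-epoch effects cannot be an artifact of lick-locked modulation.
    """
    if lick_times.size == 0:
        return np.ones(series.n_bins, dtype=bool)
    idx = np.searchsorted(lick_times, series.start_times)
    d_prev = np.where(idx > 0,
                      series.start_times - lick_times[np.maximum(idx - 1, 0)],
                      np.inf)
    d_next = np.where(idx < lick_times.size,
                      lick_times[np.minimum(idx, lick_times.size - 1)]
                      - series.start_times,
                      np.inf)
    return np.minimum(d_prev, d_next) > window_s


def auroc_timecourse(series: RateSeries, timeline: SessionTimeline,
                     config: Optional[DynamicsConfig] = None,
                     bin_mask: Optional[np.ndarray] = None) -> AurocTimecourse:
    """auROC of each sliding 1-min window (5-s bins) vs baseline.

    The window slides in one-bin (5 s) steps from lickspout placement to
    the end of the series.  With under 5 min of recorded baseline the
    available shorter baseline is used (warned via the returned span).
    """
    import warnings

    config = config or DynamicsConfig()
    b0, b1 = baseline_window(timeline, config)
    if b1 - b0 < config.baseline_span_s:
        warnings.warn(f"baseline shorter than {config.baseline_span_s} s; "
                      f"using {b1 - b0:.0f} s")
    mask = np.ones(series.n_bins, dtype=bool) if bin_mask is None else bin_mask
    in_base = (series.start_times >= b0) & (series.start_times < b1) & mask
    base = series.rates[in_base]
    if base.size == 0:
        raise ValueError("no baseline bins available")
    t_end = series.start_times[-1] + series.bin_width
    starts = np.arange(timeline.lickspout_time,
                       t_end - config.auroc_window_s + 1e-9,
                       config.auroc_step_s)
    values = np.full(starts.size, np.nan)
    for i, w0 in enumerate(starts):
        in_win = ((series.start_times >= w0)
                  & (series.start_times < w0 + config.auroc_window_s) & mask)
        if in_win.any():
            values[i] = auroc(base, series.rates[in_win])
    return AurocTimecourse(starts, values, config.auroc_window_s, (b0, b1))


@dataclass
class EpochTestResult:
    epoch: str
    span: Tuple[float, float]
    ks_p: float
    significant: bool
    direction: int          # sign of (epoch mean - baseline mean)
    mean_rate: float
    baseline_mean: float
    modulation_index: float
    n_bins: int
    skipped: bool = False


def epoch_spans(timeline: SessionTimeline,
                config: Optional[DynamicsConfig] = None) -> dict:
    """CUE: lickspout -> min(lickspout + 5 min, food); EARLY/MID/LATE:
    0-5 / 5-15 / 15-45 min after food availability."""
    config = config or DynamicsConfig()
    e = [m * 60.0 for m in config.epoch_edges_min]
    cue_end = min(timeline.lickspout_time + config.baseline_span_s,
                  timeline.food_time)
    return {
        "CUE": (timeline.lickspout_time, cue_end),
        "EARLY": (timeline.food_time + e[0], timeline.food_time + e[1]),
        "MID": (timeline.food_time + e[1], timeline.food_time + e[2]),
        "LATE": (timeline.food_time + e[2], timeline.food_time + e[3]),
    }


def modulation_index(rate_epoch: float, rate_baseline: float) -> float:
    """(a - b)/(a + b), in [-1, 1]; NaN (flagged) when both are zero."""
    if rate_epoch < 0 or rate_baseline < 0:
        raise ValueError("rates must be >= 0")
    denom = rate_epoch + rate_baseline
    if denom == 0:
        return float("nan")
    return float((rate_epoch - rate_baseline) / denom)


def epoch_tests(series: RateSeries, timeline: SessionTimeline,
                config: Optional[DynamicsConfig] = None,
                bin_mask: Optional[np.ndarray] = None) -> List[EpochTestResult]:
    """Two-sample KS of each epoch's 5-s-bin rates vs baseline.

    Bins are assigned to epochs by bin start time; an epoch without bins is
    returned skipped.  Significance at p < 0.025.
    """
    config = config or DynamicsConfig()
    mask = np.ones(series.n_bins, dtype=bool) if bin_mask is None else bin_mask
    b0, b1 = baseline_window(timeline, config)
    in_base = (series.start_times >= b0) & (series.start_times < b1) & mask
    base = series.rates[in_base]
    if base.size == 0:
        raise ValueError("no baseline bins available")
    out = []
    for name, (t0, t1) in epoch_spans(timeline, config).items():
        in_epoch = ((series.start_times >= t0) & (series.start_times < t1)
                    & mask)
        vals = series.rates[in_epoch]
        if vals.size == 0 or t1 <= t0:
            out.append(EpochTestResult(name, (t0, t1), np.nan, False, 0,
                                       np.nan, float(base.mean()), np.nan, 0,
                                       skipped=True))
            continue
        p = float(stats.ks_2samp(base, vals).pvalue)
        diff = vals.mean() - base.mean()
        out.append(EpochTestResult(
            epoch=name, span=(t0, t1), ks_p=p,
            significant=p < config.alpha_epoch,
            direction=int(np.sign(diff)),
            mean_rate=float(vals.mean()),
            baseline_mean=float(base.mean()),
            modulation_index=modulation_index(float(vals.mean()),
                                              float(base.mean())),
            n_bins=int(vals.size),
        ))
    return out


def short_isi_rate(train: SpikeTrain, span: Tuple[float, float],
                   cutoff: float = 0.050) -> float:
    """Rate of burst-like events: ISIs shorter than ``cutoff`` per second.

    Counts ISIs whose terminating spike lies within the span.
    """
    t0, t1 = span
    if t1 <= t0:
        raise ValueError("span must have positive duration")
    inside = (train.times >= t0) & (train.times < t1)
    isis = np.diff(train.times)
    ended_inside = inside[1:]
    return float(np.sum((isis < cutoff) & ended_inside) / (t1 - t0))


@dataclass
class ISIStatistics:
    unit_id: str
    n_isis: int
    cv_log10_isi: float          # SD/mean of log10(ISI)
    cv_inverse: float            # mean/SD, reported alongside
    dip: float
    dip_p: float
    degenerate: bool = False


def isi_statistics(train: SpikeTrain,
                   config: Optional[DynamicsConfig] = None,
                   seed: int = 0) -> ISIStatistics:
    """CV of the log10 ISI distribution plus Hartigan's dip test.

    The CV is reported as SD/mean (the standard definition) with the
    inverse alongside.  The dip p-value uses a seeded uniform-reference
    bootstrap and needs >= 50 ISIs; identical ISIs are degenerate (zero
    spread) and flagged.
    """
    config = config or DynamicsConfig()
    isis = train.isis()
    if isis.size < 2:
        raise ValueError("need >= 2 ISIs")
    log_isi = np.log10(isis)
    mean, sd = float(np.mean(log_isi)), float(np.std(log_isi))
    degenerate = np.ptp(log_isi) < 1e-10
    if degenerate:
        sd = 0.0
    cv = sd / mean if mean != 0 else float("nan")
    cv_inv = mean / sd if sd != 0 else float("nan")
    dip_val, dip_p = float("nan"), float("nan")
    if isis.size >= config.dip_min_isis and not degenerate:
        dip_val, dip_p = dip_test(log_isi, n_boot=config.dip_n_boot,
                                  seed=seed)
    return ISIStatistics(train.unit_id, int(isis.size), cv, cv_inv,
                         dip_val, dip_p, degenerate)


@dataclass
class GroupComparison:
    t_stat: float
    p_value: float
    mean_a: float
    sem_a: float
    n_a: int
    mean_b: float
    sem_b: float
    n_b: int


def group_compare(values_a: np.ndarray, values_b: np.ndarray) -> GroupComparison:
    """Two-sample t-test with group means +/- SEM (e.g. AM vs PM rates)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per group")
    res = stats.ttest_ind(a, b)
    return GroupComparison(
        t_stat=float(res.statistic), p_value=float(res.pvalue),
        mean_a=float(a.mean()), sem_a=float(stats.sem(a)), n_a=int(a.size),
        mean_b=float(b.mean()), sem_b=float(stats.sem(b)), n_b=int(b.size),
    )


def epoch_table(unit_id: str, results: List[EpochTestResult]) -> pd.DataFrame:
    rows = [{
        "unit_id": unit_id, "epoch": r.epoch, "t_start": r.span[0],
        "t_end": r.span[1], "ks_p": r.ks_p, "significant": r.significant,
        "direction": r.direction, "mean_rate": r.mean_rate,
        "baseline_mean": r.baseline_mean,
        "modulation_index": r.modulation_index, "n_bins": r.n_bins,
        "skipped": r.skipped,
    } for r in results]
    return pd.DataFrame(rows)
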