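"""Synthetic optetrode sessions with known ground truth.

Every downstream stage (detection, QC, optogenetic tagging, rate dynamics,
kernel regression, pair correlations) is exercised against sessions produced
here, so each generator records the parameters it drew ("ground truth") for
recovery tests.

Spike trains are inhomogeneous gamma-renewal processes sampled by time
rescaling: in operational time ``L(t) = integral of rate``, inter-event
intervals are Gamma(shape, scale=1/shape) so that shape=1 recovers an
inhomogeneous Poisson process and larger shapes give more regular firing
(CV of ISI = 1/sqrt(shape) at constant rate).

Rate modulation is multiplicative for the slow terms
(baseline x diurnal ramp x cue step x food step x photostimulation gain)
with an additive event-kernel drive for lick/bout coupling, matching the
linear model the kernel regression fits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .config import StimProtocol
from .types import EventKind, EventSeries, RawTrace, SessionTimeline, SpikeTrain, UnitLabel

KERNEL_LAGS = np.arange(-4.5, 4.51, 0.5)  # 19 bins, 0.5-s resolution
KERNEL_BIN = 0.5


# ---------------------------------------------------------------------------
# spike trains by time rescaling
# ---------------------------------------------------------------------------

def simulate_spike_train(
    rate_fn: Callable[[np.ndarray], np.ndarray],
    isi_shape: float,
    t_span: Tuple[float, float],
    rng: np.random.Generator,
    dt: float = 1e-3,
    unit_id: str = "u0",
    refractory_s: float = 0.0,
) -> SpikeTrain:
    """Sample a spike train from an inhomogeneous gamma-renewal process.

    Parameters
    ----------
    rate_fn : callable
        Vectorized instantaneous rate (spikes/s), must be >= 0 on ``t_span``.
    isi_shape : float
        Gamma shape of the rescaled-time renewal density; 1 = Poisson.
    t_span : (t0, t1)
        Simulation interval (s).
    rng : numpy Generator
    dt : float
        Grid step for integrating the rate (s).
    refractory_s : float
        Absolute refractory period imposed by greedy thinning (a spike
        closer than this to the previously kept spike is deleted).  Real
        units never show sub-millisecond intervals, and the downstream QC
        rules assume that.
    """
    if isi_shape <= 0:
        raise ValueError("isi_shape must be > 0")
    t0, t1 = t_span
    if t1 <= t0:
        return SpikeTrain(unit_id, np.empty(0))
    grid = np.arange(t0, t1 + dt, dt)
    lam = np.asarray(rate_fn(grid), dtype=float)
    if np.any(lam < 0):
        raise ValueError("rate_fn is negative within t_span")
    # cumulative operational time via trapezoid rule
    big_lambda = np.concatenate(
        [[0.0], np.cumsum(0.5 * (lam[1:] + lam[:-1]) * np.diff(grid))]
    )
    total = big_lambda[-1]
    if total == 0:
        return SpikeTrain(unit_id, np.empty(0))
    # draw unit-mean gamma intervals until the operational span is covered
    intervals: List[np.ndarray] = []
    consumed = 0.0
    expect = max(16, int(total * 1.3))
    while consumed <= total:
        chunk = rng.gamma(isi_shape, 1.0 / isi_shape, size=expect)
        intervals.append(chunk)
        consumed += chunk.sum()
        expect = max(16, int((total - consumed) * 1.3))
    rescaled = np.cumsum(np.concatenate(intervals))
    rescaled = rescaled[rescaled <= total]
    times = np.interp(rescaled, big_lambda, grid)
    times = times[(times >= t0) & (times < t1)]
    # strictly increasing guard against interp ties on zero-rate plateaus
    keep = np.concatenate([[True], np.diff(times) > 0])
    times = times[keep]
    if refractory_s > 0 and times.size:
        kept = [times[0]]
        for t in times[1:]:
            if t - kept[-1] >= refractory_s:
                kept.append(t)
        times = np.asarray(kept)
    return SpikeTrain(unit_id, times)


# ---------------------------------------------------------------------------
# behavior: lick bouts and reward thinning
# ---------------------------------------------------------------------------

@dataclass
class BoutParams:
    """Licking microstructure parameters.

    Bouts are separated by silent gaps of ``min_gap_s`` plus an exponential
    excess with mean ``mean_extra_gap_s``; each bout contains
    ``min_licks + Poisson(mean_extra_licks)`` licks at ``intra_interval_s``
    spacing (with small jitter).  Consecutive rewards are spaced >= 2.5 s.
    """

    min_gap_s: float = 10.0
    mean_extra_gap_s: float = 20.0
    min_licks: int = 4
    mean_extra_licks: float = 8.0
    intra_interval_s: float = 0.15
    jitter_s: float = 0.01
    reward_refractory_s: float = 2.5

    def __post_init__(self) -> None:
        if self.intra_interval_s >= 8.0:
            raise ValueError(
                "intra-bout lick interval must be < 8 s or bouts would merge"
            )
        if self.min_gap_s <= 8.0:
            raise ValueError("inter-bout gap must exceed the 8-s bout "
                             "definition to keep bouts separable")


def simulate_behavior(
    params: BoutParams,
    t_span: Tuple[float, float],
    rng: np.random.Generator,
) -> Dict[EventKind, EventSeries]:
    """Generate lick, reward and ground-truth bout-onset event series."""
    t0, t1 = t_span
    licks: List[float] = []
    bout_onsets: List[float] = []
    t = t0 + rng.exponential(params.mean_extra_gap_s)
    while t < t1:
        n_licks = params.min_licks + rng.poisson(params.mean_extra_licks)
        gaps = params.intra_interval_s + rng.uniform(
            -params.jitter_s, params.jitter_s, size=n_licks - 1
        )
        bout = t + np.concatenate([[0.0], np.cumsum(gaps)])
        bout = bout[bout < t1]
        if bout.size:
            bout_onsets.append(bout[0])
            licks.extend(bout.tolist())
        t = (bout[-1] if bout.size else t) + params.min_gap_s + rng.exponential(
            params.mean_extra_gap_s
        )
    lick_times = np.asarray(licks)
    # rewards: one per lick, thinned so consecutive deliveries are >= 2.5 s apart
    rewards: List[float] = []
    last = -np.inf
    for lt in lick_times:
        if lt - last >= params.reward_refractory_s:
            rewards.append(lt)
            last = lt
    return {
        EventKind.LICK: EventSeries(EventKind.LICK, lick_times),
        EventKind.REWARD: EventSeries(EventKind.REWARD, np.asarray(rewards)),
        EventKind.BOUT_ONSET: EventSeries(
            EventKind.BOUT_ONSET, np.asarray(bout_onsets)
        ),
    }


# ---------------------------------------------------------------------------
# photostimulation
# ---------------------------------------------------------------------------

def simulate_photostim(
    protocol: StimProtocol, t0: float = 0.0
) -> Dict[EventKind, EventSeries]:
    """Lay out pulse trains: ``n_trains`` trains of 20-ms pulses at 20 Hz,
    onset-to-onset spacing ``train_duration + inter_train_gap`` (4 s)."""
    onsets = t0 + np.arange(protocol.n_trains) * protocol.train_period
    within = np.arange(protocol.pulses_per_train) * protocol.cycle_length
    pulses = (onsets[:, None] + within[None, :]).ravel()
    return {
        EventKind.TRAIN_ONSET: EventSeries(
            EventKind.TRAIN_ONSET, onsets,
            np.full(onsets.size, protocol.train_duration)),
        EventKind.PULSE: EventSeries(
            EventKind.PULSE, pulses, np.full(pulses.size, protocol.pulse_width)),
    }


# ---------------------------------------------------------------------------
# raw-trace synthesis
# ---------------------------------------------------------------------------

def make_template(
    peak_uv: Sequence[float], fs: float, width_s: float = 1e-3
) -> np.ndarray:
    """Biphasic extracellular spike template, shape (n_channels, n_samples).

    A negative-leading damped sinusoid scaled so the absolute extremum on
    each channel equals ``peak_uv[channel]``.
    """
    n = int(round(width_s * fs))
    t = np.arange(n) / fs
    shape = -np.sin(2 * np.pi * t / width_s) * np.exp(-((t - width_s / 4)
                                                        / (width_s / 3)) ** 2)
    shape /= np.abs(shape).max()
    return np.asarray(peak_uv, dtype=float)[:, None] * shape[None, :]


def synthesize_trace(
    spike_trains: Sequence[SpikeTrain],
    templates: Sequence[np.ndarray],
    noise_sigma: float,
    fs: float,
    rng: np.random.Generator,
    duration: float,
    n_channels: int = 4,
    t0: float = 0.0,
) -> RawTrace:
    """Additive model: Gaussian noise plus unit templates at spike times."""
    n_samples = int(round(duration * fs))
    samples = rng.normal(0.0, noise_sigma, size=(n_channels, n_samples))
    for train, template in zip(spike_trains, templates):
        template = np.atleast_2d(template)
        if template.shape[1] > int(round(2e-3 * fs)):
            raise ValueError("template longer than 2 ms")
        if template.shape[0] != n_channels:
            raise ValueError("template channel count mismatch")
        # align the template so its extremum lands on the spike time
        ext = int(np.argmax(np.abs(template).max(axis=0)))
        idx = np.round((train.times - t0) * fs).astype(int) - ext
        idx = idx[(idx >= 0) & (idx + template.shape[1] <= n_samples)]
        for i in idx:
            samples[:, i:i + template.shape[1]] += template
    channel_ids = [f"ch{c}" for c in range(n_channels)]
    return RawTrace(samples, fs, channel_ids, t0=t0)


# ---------------------------------------------------------------------------
# ground truth and full sessions
# ---------------------------------------------------------------------------

@dataclass
class UnitTruth:
    """Generative parameters for one synthetic unit."""

    unit_id: str
    label: UnitLabel
    baseline_rate: float              # lambda0, spikes/s
    ramp_per_hr: float = 0.0          # additive diurnal drift, spikes/s per hr
    cue_mult: float = 1.0             # step at lickspout placement
    food_mult: float = 1.0            # step at food availability
    stim_gain: float = 1.0            # multiplier while the laser train is on
    isi_shape: float = 2.0
    refractory_s: float = 0.0015      # absolute refractory period (s)
    lick_kernel: np.ndarray = field(
        default_factory=lambda: np.zeros(KERNEL_LAGS.size))
    bout_kernel: np.ndarray = field(
        default_factory=lambda: np.zeros(KERNEL_LAGS.size))

    def __post_init__(self) -> None:
        self.label = UnitLabel(self.label)
        self.lick_kernel = np.asarray(self.lick_kernel, dtype=float)
        self.bout_kernel = np.asarray(self.bout_kernel, dtype=float)
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        for m in (self.cue_mult, self.food_mult, self.stim_gain):
            if m <= 0:
                raise ValueError("rate multipliers must be > 0")
        if not (np.all(np.isfinite(self.lick_kernel))
                and np.all(np.isfinite(self.bout_kernel))):
            raise ValueError("kernels must be finite")


@dataclass
class GroundTruth:
    """Everything the generator drew for one session."""

    seed: int
    units: List[UnitTruth]
    bout_params: BoutParams
    stim: StimProtocol

    def to_json(self, path: str | Path) -> None:
        payload = {
            "seed": self.seed,
            "bout_params": dataclasses.asdict(self.bout_params),
            "stim": dataclasses.asdict(self.stim),
            "units": [
                {**dataclasses.asdict(u),
                 "label": u.label.value,
                 "lick_kernel": u.lick_kernel.tolist(),
                 "bout_kernel": u.bout_kernel.tolist()}
                for u in self.units
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        with open(path) as fh:
            raw = json.load(fh)
        units = [UnitTruth(**u) for u in raw["units"]]
        return cls(seed=raw["seed"], units=units,
                   bout_params=BoutParams(**raw["bout_params"]),
                   stim=StimProtocol(**raw["stim"]))


def _kernel_drive(
    grid: np.ndarray, event_times: np.ndarray, kernel: np.ndarray
) -> np.ndarray:
    """Piecewise-constant additive drive: kernel bin j (centered on
    KERNEL_LAGS[j]) applies over lag interval [lag - 0.25, lag + 0.25)."""
    if event_times.size == 0 or not np.any(kernel):
        return np.zeros(grid.size)
    dt = grid[1] - grid[0]
    diff = np.zeros(grid.size + 1)
    for lag, coef in zip(KERNEL_LAGS, kernel):
        if coef == 0:
            continue
        starts = np.searchsorted(grid, event_times + lag - KERNEL_BIN / 2)
        stops = np.searchsorted(grid, event_times + lag + KERNEL_BIN / 2)
        np.add.at(diff, starts, coef)
        np.add.at(diff, stops, -coef)
    return np.cumsum(diff[:-1])


def build_rate_fn(
    unit: UnitTruth,
    timeline: SessionTimeline,
    lick_times: Optional[np.ndarray] = None,
    bout_times: Optional[np.ndarray] = None,
    train_onsets: Optional[np.ndarray] = None,
    train_duration: float = 1.0,
) -> Callable[[np.ndarray], np.ndarray]:
    """Compose the ground-truth rate: (lambda0 + ramp t) x cue step x food
    step x stim gain, plus the additive lick/bout kernel drive, floored at 0.
    """

    def rate(t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        lam = unit.baseline_rate + unit.ramp_per_hr * (t - timeline.baseline_start) / 3600.0
        lam = np.maximum(lam, 0.0)
        mult = np.ones_like(t)
        mult[t >= timeline.lickspout_time] *= unit.cue_mult
        mult[t >= timeline.food_time] *= unit.food_mult
        lam = lam * mult
        if train_onsets is not None and train_onsets.size and unit.stim_gain != 1.0:
            starts = np.searchsorted(train_onsets, t, side="right") - 1
            valid = starts >= 0
            in_train = np.zeros_like(t, dtype=bool)
            in_train[valid] = (
                t[valid] - train_onsets[starts[valid]] < train_duration
            )
            lam[in_train] *= unit.stim_gain
        if lick_times is not None:
            lam = lam + _kernel_drive(t, lick_times, unit.lick_kernel)
        if bout_times is not None:
            lam = lam + _kernel_drive(t, bout_times, unit.bout_kernel)
        return np.maximum(lam, 0.0)

    return rate


@dataclass
class SyntheticSession:
    """A complete generated session plus its ground truth."""

    spike_trains: List[SpikeTrain]
    events: List[EventSeries]
    timeline: SessionTimeline
    truth: GroundTruth
    stim_block: Tuple[float, float]   # [first train onset, last train end]


_DEFAULT_KERNEL_PEAKS = {
    # bout kernels up to roughly 3x baseline; lick kernels a fraction of it
    UnitLabel.AGRP: (-0.6, -1.5),
    UnitLabel.ARC_INH: (1.0, 2.5),
    UnitLabel.ARC_OTHER: (0.0, 0.0),
}


def _smooth_kernel(peak: float, center_s: float = 0.5,
                   width_s: float = 1.0) -> np.ndarray:
    """Gaussian-bump kernel on the 19 lag bins, peak value ``peak``."""
    return peak * np.exp(-0.5 * ((KERNEL_LAGS - center_s) / width_s) ** 2)


def make_session(
    seed: int,
    n_agrp: int = 3,
    n_inh: int = 2,
    n_other: int = 2,
    baseline_start: float = 0.0,
    lickspout_time: float = 600.0,
    food_time: float = 900.0,
    feeding_span: float = 2700.0,
    stim: Optional[StimProtocol] = None,
    bout_params: Optional[BoutParams] = None,
    rate_range: Tuple[float, float] = (2.0, 10.0),
    stim_gains: Tuple[float, float, float] = (2.0, 0.5, 1.0),
    food_mults: Tuple[float, float, float] = (0.4, 2.0, 1.0),
    cue_mults: Tuple[float, float, float] = (0.7, 1.3, 1.0),
    with_kernels: bool = True,
    isi_shape: float = 2.0,
    refractory_s: float = 0.0015,
    dt: float = 1e-3,
) -> SyntheticSession:
    """Generate a feeding session followed by a photostimulation block.

    Defaults emulate the study conditions: >= 5 min baseline (10 min here),
    a cue period between lickspout placement and food availability (5 min,
    within the 0.5-15 min range used experimentally), 45 min of feeding with
    licking organized into bouts, then 1-s / 20-Hz / 20-ms pulse trains with
    3-s gaps for tagging.  Ground-truth effect sizes: photostimulation gains
    (2.0 driven, 0.5 suppressed, 1.0 unaffected), feeding steps (0.4 drop for
    AgRP units, 2.0 rise for inhibited units) and bout kernels up to ~3x
    baseline, matching the reported magnitudes.
    """
    stim = stim or StimProtocol()
    bout_params = bout_params or BoutParams()
    ss = np.random.SeedSequence(seed)
    rng_session, rng_units = [np.random.default_rng(s) for s in ss.spawn(2)]

    timeline = SessionTimeline(
        baseline_start=baseline_start,
        lickspout_time=lickspout_time,
        food_time=food_time,
        session_end=food_time + feeding_span,
    )
    stim_start = timeline.session_end + 120.0
    stim_events = simulate_photostim(stim, t0=stim_start)
    train_onsets = stim_events[EventKind.TRAIN_ONSET].times
    stim_block = (train_onsets[0], train_onsets[-1] + stim.train_duration)
    session_stop = stim_block[1] + 180.0

    behavior = simulate_behavior(
        bout_params, (timeline.food_time, timeline.session_end), rng_session
    )
    lick_times = behavior[EventKind.LICK].times
    bout_times = behavior[EventKind.BOUT_ONSET].times

    labels = ([UnitLabel.AGRP] * n_agrp + [UnitLabel.ARC_INH] * n_inh
              + [UnitLabel.ARC_OTHER] * n_other)
    gain = dict(zip((UnitLabel.AGRP, UnitLabel.ARC_INH, UnitLabel.ARC_OTHER),
                    stim_gains))
    fmult = dict(zip((UnitLabel.AGRP, UnitLabel.ARC_INH, UnitLabel.ARC_OTHER),
                     food_mults))
    cmult = dict(zip((UnitLabel.AGRP, UnitLabel.ARC_INH, UnitLabel.ARC_OTHER),
                     cue_mults))

    units: List[UnitTruth] = []
    trains: List[SpikeTrain] = []
    unit_seeds = ss.spawn(len(labels))
    for k, (label, useed) in enumerate(zip(labels, unit_seeds)):
        lam0 = rng_units.uniform(*rate_range)
        lick_peak, bout_peak = _DEFAULT_KERNEL_PEAKS[label]
        unit = UnitTruth(
            unit_id=f"u{k:02d}",
            label=label,
            baseline_rate=lam0,
            cue_mult=cmult[label],
            food_mult=fmult[label],
            stim_gain=gain[label],
            isi_shape=isi_shape,
            refractory_s=refractory_s,
            lick_kernel=(_smooth_kernel(lick_peak, 0.25, 0.75)
                         if with_kernels else np.zeros(KERNEL_LAGS.size)),
            bout_kernel=(_smooth_kernel(bout_peak, 0.5, 1.0)
                         if with_kernels else np.zeros(KERNEL_LAGS.size)),
        )
        units.append(unit)
        rate_fn = build_rate_fn(
            unit, timeline,
            lick_times=lick_times if with_kernels else None,
            bout_times=bout_times if with_kernels else None,
            train_onsets=train_onsets,
            train_duration=stim.train_duration,
        )
        train = simulate_spike_train(
            rate_fn, unit.isi_shape, (baseline_start, session_stop),
            np.random.default_rng(useed), dt=dt, unit_id=unit.unit_id,
            refractory_s=unit.refractory_s,
        )
        trains.append(train)

    events = list(behavior.values()) + list(stim_events.values())
    truth = GroundTruth(seed=seed, units=units, bout_params=bout_params,
                        stim=stim)
    return SyntheticSession(trains, events, timeline, truth, stim_block)
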