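"""Pipeline configuration: every analysis threshold as a named parameter.

Defaults reproduce the published analysis settings (4-sigma detection with the
MAD/0.6745 noise estimate, 0.95 waveform-correlation QC, the >20% suppression
rule, alpha = 0.025 epoch tests, 5000-shuffle entrainment test at 1e-4, the
0.05/19 Bonferroni kernel threshold, the >8 s / >3 licks bout definition,
the 50-ms short-ISI cutoff, the 0.01-Hz detrending cutoff and the +/-20 s
correlation lag range).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import yaml


@dataclass
class DetectionConfig:
    """Spike-detection settings."""

    detect_band: Tuple[float, float] = (400.0, 6000.0)  # Hz, threshold signal
    wave_band: Tuple[float, float] = (300.0, 9000.0)    # Hz, waveform signal
    threshold_mult: float = 4.0       # threshold = mult * sigma
    mad_const: float = 0.6745         # median|x| / mad_const estimates sigma
    snippet_s: float = 1e-3           # waveform window, also the dead time
    filter_order: int = 3             # zero-phase Butterworth, filtfilt

    def validate(self, fs: float) -> None:
        for lo, hi in (self.detect_band, self.wave_band):
            if not (0 < lo < hi < fs / 2):
                raise ValueError(
                    f"band ({lo}, {hi}) Hz must lie within (0, fs/2)="
                    f"(0, {fs / 2}) Hz"
                )
        if self.threshold_mult <= 0:
            raise ValueError("threshold_mult must be > 0")


@dataclass
class QCConfig:
    """Single-unit inclusion criteria."""

    max_frac_isi_lt_1ms: float = 0.0   # no ISI below 1 ms
    max_frac_isi_lt_5ms: float = 0.05  # < 5% of ISIs below 5 ms
    min_waveform_xcorr: float = 0.95   # mean spike-vs-mean-waveform r
    stability_alpha: float = 0.05      # first/last-5-min KS stability test
    stability_window_s: float = 300.0


@dataclass
class StimProtocol:
    """Photostimulation protocol: 1-s trains of 20-ms pulses at 20 Hz,
    3 s between trains (4 s onset-to-onset)."""

    train_duration: float = 1.0
    pulse_width: float = 0.020
    pulse_rate: float = 20.0
    inter_train_gap: float = 3.0
    n_trains: int = 100

    def __post_init__(self) -> None:
        if self.pulse_width * self.pulse_rate > 1:
            raise ValueError("pulse_width * pulse_rate must be <= 1")

    @property
    def cycle_length(self) -> float:
        return 1.0 / self.pulse_rate

    @property
    def pulses_per_train(self) -> int:
        return int(round(self.train_duration * self.pulse_rate))

    @property
    def train_period(self) -> float:
        return self.train_duration + self.inter_train_gap


@dataclass
class TaggingConfig:
    """Optogenetic classification thresholds."""

    alpha_train: float = 0.025        # per paired t-test (two tests)
    min_suppression: float = 0.20     # ARC_INH requires > 20% suppression
    alpha_sustained: float = 0.05     # KS test on flanking rates
    n_shuffles: int = 5000            # cycle-entrainment shuffles
    alpha_entrainment: float = 1e-4   # per-unit, before bin correction
    pre_window_s: float = 2.0         # baseline before each train
    min_trains: int = 10
    min_spont_evoked_xcorr: float = 0.95


@dataclass
class DynamicsConfig:
    """Rate-dynamics settings."""

    rate_bin_s: float = 5.0           # epoch tests & auROC use 5-s bins
    baseline_span_s: float = 300.0    # up to 5 min pre-lickspout
    auroc_window_s: float = 60.0      # sliding window length
    auroc_step_s: float = 5.0         # slide by one bin
    alpha_epoch: float = 0.025        # two-sample KS
    short_isi_cutoff_s: float = 0.050
    dip_min_isis: int = 50
    dip_n_boot: int = 2000
    lick_mask_window_s: float = 8.0   # lick-exclusive re-analysis window
    epoch_edges_min: Tuple[float, float, float, float] = (0.0, 5.0, 15.0, 45.0)


@dataclass
class LickRegConfig:
    """Lick/bout kernel-regression settings."""

    bin_s: float = 0.5
    kernel_halfwidth_s: float = 4.5   # lags from -4.5 to +4.5 s (19 bins)
    bout_gap_s: float = 8.0           # silence required before a bout
    bout_min_licks: int = 4           # "> 3 licks" read as >= 4
    alpha: float = 0.05
    n_kernel_bins: int = 19           # Bonferroni: alpha / 19
    epoch_start_min: float = 15.0     # analysis epoch, minutes post food
    epoch_end_min: float = 45.0
    exclude_stim_blocks: bool = True
    rel_mod_halfwidth_s: float = 2.0  # window for relative modulation

    @property
    def alpha_corrected(self) -> float:
        return self.alpha / self.n_kernel_bins


@dataclass
class PairCorrConfig:
    """Pairwise lagged-correlation settings."""

    bin_s: float = 1.0
    highpass_hz: float = 0.01         # removes trends slower than ~100 s
    max_lag_s: float = 20.0
    filter_order: int = 2
    alpha: float = 0.05


@dataclass
class PipelineConfig:
    """Bundle of all stage configurations plus the run seed."""

    seed: int = 0
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    qc: QCConfig = field(default_factory=QCConfig)
    stim: StimProtocol = field(default_factory=StimProtocol)
    tagging: TaggingConfig = field(default_factory=TaggingConfig)
    dynamics: DynamicsConfig = field(default_factory=DynamicsConfig)
    lickreg: LickRegConfig = field(default_factory=LickRegConfig)
    paircorr: PairCorrConfig = field(default_factory=PairCorrConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: Optional[str | Path]) -> "PipelineConfig":
        if path is None:
            return cls()
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        kwargs: dict = {}
        sub = {
            "detection": DetectionConfig,
            "qc": QCConfig,
            "stim": StimProtocol,
            "tagging": TaggingConfig,
            "dynamics": DynamicsConfig,
            "lickreg": LickRegConfig,
            "paircorr": PairCorrConfig,
        }
        for key, val in raw.items():
            if key in sub:
                d = dict(val)
                # YAML round-trips tuples as lists
                for k, v in d.items():
                    if isinstance(v, list):
                        d[k] = tuple(v)
                kwargs[key] = sub[key](**d)
            elif key == "seed":
                kwargs["seed"] = int(val)
            else:
                raise ValueError(f"unknown config section {key!r}")
        return cls(**kwargs)
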