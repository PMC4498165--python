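# arcpipe

Analysis pipeline for extracellular **optetrode** recordings from the
arcuate nucleus (ARC) of awake, behaving mice — the experiment in which
hunger-promoting AgRP neurons are identified *in vivo* by their response to
channelrhodopsin photostimulation and then followed across feeding
behavior.  The package is aimed at systems-neuroscience users who want the
full chain from raw voltage to population statistics as reusable, tested
code:

1. **detect** — band-pass filtering (400–6000 Hz), robust noise estimation
   `σ = median(|x|)/0.6745`, 4σ threshold crossing, 1-ms waveforms and
   per-channel peak/valley features;
2. **qc** — single-unit criteria: no ISI < 1 ms, < 5% of ISIs < 5 ms, mean
   spike-to-mean-waveform correlation > 0.95, waveform stability over the
   recording;
3. **tag** — optogenetic classification with paired t-tests (2 s pre-train
   vs each half of a 1-s, 20-Hz pulse train; α = 0.025 each):
   **AGRP** = driven (plus waveform match), **ARC_INH** = significantly
   suppressed by > 20%, **ARC_OTHER** = the rest; plus a 5000-shuffle
   cycle-histogram test of pulse entrainment;
4. **dynamics** — 5-s-bin rates, sliding-window (1 min) auROC timecourses
   against the pre-cue baseline, feeding-epoch KS tests (p < 0.025),
   modulation index, short-ISI (< 50 ms) event rates, CV of log₁₀ ISI and
   Hartigan's dip test of unimodality;
5. **lickreg** — lick-bout detection (> 8 s silence then ≥ 4 licks) and a
   multiple linear regression of 0.5-s-binned firing on lagged lick counts
   and bout onsets (19 lags, −4.5…+4.5 s), per-coefficient partial F-tests
   at p < 0.05/19;
6. **corr** — pairwise Pearson correlations of 1-s rates at lags up to
   ±20 s after removing trends slower than ~100 s (0.01-Hz high-pass).

The central discriminability statistic is the **auROC**: for baseline rate
bins B and test-window bins T,

    auROC = P(t > b) + ½·P(t = b),   t ~ T, b ~ B

(the Mann–Whitney U statistic normalized by n₁n₂): 0.5 means the window is
indistinguishable from baseline, 1 means every window rate exceeds every
baseline rate, 0 the reverse.

Since raw recordings for this kind of experiment are not publicly
deposited, the package includes a synthetic-session generator
(`arcpipe.synth`) producing spike trains (inhomogeneous gamma-renewal via
time rescaling, with refractory period), lick/bout/reward streams,
photostimulation protocols, raw traces and a session timeline — all with
recorded ground truth, so every stage has parameter-recovery and
calibration tests.  See `docs/methods.md` for the model details and design
choices.

## Worked example

```python
import numpy as np
from arcpipe.synth import make_session
from arcpipe.io import events_by_kind
from arcpipe.types import EventKind
from arcpipe.optotag import tag_units
from arcpipe.ratedyn import bin_rates, auroc_timecourse
from arcpipe.lickreg import KernelModel, regression_epoch

session = make_session(seed=7, n_agrp=1, n_inh=1, n_other=1)
events = events_by_kind(session.events)
onsets = events[EventKind.TRAIN_ONSET].times

labels = tag_units(session.spike_trains, onsets,
                   events[EventKind.PULSE].times, session.stim_block)
for res in labels:
    print(f"{res.unit_id}: {res.label.value:9s} "
          f"suppression={res.suppression_fraction:+.2f} "
          f"min_p={min(res.p_first_half, res.p_second_half):.2g}")

tl = session.timeline
series = bin_rates(session.spike_trains[0], 5.0,
                   (tl.baseline_start, tl.session_end))
tc = auroc_timecourse(series, tl)
print(f"u00 mean post-feeding auROC: "
      f"{np.nanmean(tc.auroc[tc.window_starts >= tl.food_time]):.3f}")

span = regression_epoch(tl.food_time)
span = (span[0], min(span[1], tl.session_end))
model = KernelModel.from_events(session.spike_trains[1],
                                events[EventKind.LICK], None, span)
print(model.fit().summary())
```

Output:

```
u00: AGRP      suppression=-0.85 min_p=1e-11
u01: ARC_INH   suppression=+0.50 min_p=9.3e-26
u02: ARC_OTHER suppression=-0.03 min_p=0.21
u00 mean post-feeding auROC: 0.000
Event-kernel regression (0.5-s bins, lags -4.5..+4.5 s)
offset = 6.474 spikes/s   R^2 = 0.488   df_resid = 3561
per-coefficient threshold p < 0.0026 (0.05 Bonferroni-corrected over 19 lags)
lick kernel: 4 significant lag(s): -0.5s=0.67, +0.0s=1.23, +0.5s=1.07, +1.0s=0.61
bout kernel: 1 significant lag(s): -0.5s=2.45
```

Reading the numbers: the photostimulation-driven unit is labeled AGRP
(negative "suppression" = facilitation; its train-response p is ~10⁻¹¹),
the 50%-suppressed unit is ARC_INH, and the unaffected unit stays
ARC_OTHER.  The AgRP unit's post-feeding auROC of 0.0 means every
post-feeding 1-min rate window sits entirely below its baseline rate
distribution — the step drop at food access built into the simulation.
The inhibited-class unit's fitted lick kernel peaks at +1.23 spikes/s per
lick at lag 0 and its bout kernel at +2.45 spikes/s at −0.5 s (firing
rises just *before* bout onset), recovering the generator's kernels at
the Bonferroni-corrected significance threshold.

## Command-line pipeline

```bash
arcpipe simulate --seed 7 --out session/        # synthetic session + truth
arcpipe report --session session/ --seed 7 --out results/
# or stage by stage:
arcpipe detect --trace trace.bin --sidecar trace.json --out spikes.csv
arcpipe qc --spikes spikes.csv --out qc.csv
arcpipe tag --spikes spikes.csv --stim events.csv --out class.csv
arcpipe dynamics --spikes spikes.csv --events events.csv \
    --timeline timeline.json --out dyn/
arcpipe lickreg --spikes spikes.csv --licks events.csv \
    --timeline timeline.json --out kernels.csv
arcpipe corr --spikes spikes.csv --out pairs.csv
```

`report` chains QC → tagging → dynamics → kernels → correlations, writes
one CSV per result family plus a JSON manifest (config hash and seed; same
seed and config reproduce result CSVs byte-identically), and an auROC
population map figure.  Every analysis threshold is a named parameter in a
single YAML config (`PipelineConfig`) with the published defaults.

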