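# Methods

`arcpipe` re-implements, as a tested pipeline, the single-unit analysis of
extracellular optetrode recordings from the arcuate nucleus (ARC) of awake
mice: spike detection and unit quality control, optogenetic classification
of units into AgRP / photo-inhibited (ARC_inh) / other classes, firing-rate
statistics across timescales (diurnal means, sliding-window auROC,
feeding-epoch tests), an event-kernel regression of firing on licking
behavior, and detrended pairwise lagged correlations.  Because the raw
recordings behind this style of experiment are generally not deposited, the
package ships a first-class synthetic-session generator with recorded
ground truth; every stage has recovery and calibration tests against it.

## Spike detection and unit QC

The detection signal is the broadband trace band-passed 400–6000 Hz; the
waveform signal uses a wider 300–9000 Hz band so that 1-ms snippets are
minimally distorted for correlation-based QC.  The filter realization is a
3rd-order Butterworth applied forward–backward (zero phase): phase-neutral
waveforms are required for spike-to-mean correlations, and the zero-phase
choice costs nothing for threshold detection.

Per channel, the noise SD is estimated as `median(|x|)/0.6745` — the
MAD-based estimator, consistent for σ under Gaussian noise and nearly
unaffected by the spikes themselves — and the detection threshold is 4σ.
Polarity is unspecified in this style of acquisition, so detection fires on
`|x| > 4σ`; crossings within one snippet window are merged across channels
(dead time = the 1-ms snippet) and each event is aligned to the extremum on
the largest-amplitude channel.  Features are the per-channel waveform peak
and valley (8 numbers per event on a tetrode).

A unit is accepted when: no ISI < 1 ms; fewer than 5% of ISIs < 5 ms; the
mean correlation of each spike with the unit's mean waveform exceeds 0.95;
and waveform stability holds — the spike-to-mean correlations of the first
and last 5 minutes are compared with those of an equal number of randomly
chosen spikes by a two-sample KS test at α = 0.05 (the stability criterion
names no specific test; KS on the correlation distributions is the least
parametric choice).  Without waveform data the ISI rules alone decide and
the waveform flags are reported as not evaluated.

Cluster cutting is out of scope (done manually in vendor software in the
original workflow); `cluster_events` is k-means on the 8 amplitude features
with k supplied from ground truth, provided only so synthetic detector
output can flow into the downstream stages.

## Optogenetic classification

Stimulation is 1-s trains of 20-ms pulses at 20 Hz with 3 s between trains
(50–100 trains typical; 100 default).  Per train we form three rates: the
2 s before onset, train seconds [0, 0.5) and [0.5, 1.0) — some driven
cells respond only after a few hundred milliseconds, hence the two halves.
Two paired t-tests (pre vs each half) at α = 0.025 each encode the
Bonferroni pair.  Labels:

* **AGRP** — significant increase, and (when waveforms exist) spontaneous
  vs light-evoked mean-waveform correlation > 0.95;
* **ARC_INH** — significant decrease *and* suppression
  `1 − rate_in/rate_pre > 0.20`;
* **ARC_OTHER** — everything else.  Significantly but weakly (≤ 20%)
  suppressed units stay ARC_OTHER with an explicit `weak_inhibition_flag`
  rather than being dropped, preserving countability.

Two auxiliary statistics are computed but never relabel a unit on their
own: a two-sample KS test (α = 0.05) on 5-s-bin rates flanking the whole
stimulation block, which detects rare slow laser-evoked shifts that do not
recover between trains (`sustained_flag` marks such units for review —
the precise promotion rule is not specifiable from the available
description, so the package surfaces the evidence instead of guessing);
and a within-cycle shuffle test of entrainment to individual pulses.

For entrainment, spikes are histogrammed in ten 5-ms bins of the 50-ms
pulse cycle.  The null re-places every spike uniformly within its own
cycle, preserving per-cycle counts exactly; summed over cycles each
shuffled histogram is therefore a multinomial draw of the total spike
count over ten equiprobable bins, which is how the 5000 shuffles are
sampled (exactly equivalent, and fast).  A bin's p-value is the plain
exceedance fraction over shuffles — with 5000 shuffles a bin that beats
every shuffle gets p = 0, which is what makes a corrected threshold of
10⁻⁴ reachable at all.  Correction: Bonferroni over the 10 bins within a
unit; any cross-unit correction is left to report level, and the exact
correction factor is a config parameter (`alpha_entrainment`) because the
source procedure does not pin it down.

## Firing-rate dynamics

All epoch statistics use 5-s bins (half-open `[t, t+Δ)`, bins assigned to
epochs by start time).  The baseline is up to 5 min immediately before
lickspout placement.

* **auROC timecourse** — for each sliding 60-s window (stepping one bin,
  5 s, matching the displayed resolution) the auROC between the baseline
  rate distribution and the window's: the probability that a random window
  bin exceeds a random baseline bin, ties counted ½ (equals Mann–Whitney
  U/(n₁n₂)).  0.5 = indistinguishable, 1 = all window rates above all
  baseline rates, 0 = all below.
* **Epoch KS tests** — two-sample KS of baseline rates vs the cue epoch
  (lickspout → min(+5 min, food)) and the early/mid/late feeding epochs
  (0–5, 5–15, 15–45 min post food), significant at p < 0.025, with a
  bounded modulation index (a − b)/(a + b).
* **Lick-exclusive re-analysis** — an optional bin mask drops bins within
  a window of any lick (default 8 s, the midpoint of the 5–10-s range used
  for this control; configurable) so feeding effects can be shown not to
  be lick artifacts.
* **Short-ISI events** — the rate of ISIs < 50 ms, a burst-proxy.
* **ISI structure** — the CV of log₁₀(ISI).  The CV is reported as
  SD/mean (the standard definition) with mean/SD alongside, because the
  two conventions both appear in the field's descriptions of this
  quantity.  Unimodality is tested with Hartigan's dip (below), requiring
  ≥ 50 ISIs; zero-spread log-ISIs are flagged degenerate.
* **Group comparison** — plain two-sample t-test with means ± SEM for
  AM vs PM session-mean rates.

### Hartigan's dip

No installed package provides the dip, so it is implemented from the
definition: the dip of a sample is the smallest sup-norm distance between
its ECDF and any unimodal CDF (convex below the mode, concave above,
optional jump at the mode).  For a candidate distance d, such a CDF exists
iff for some mode position a convex nondecreasing function threads the
per-point bands `[F(xᵢ)−d, F(xᵢ⁻)+d]` left of the mode and a concave one
threads them right of it; band feasibility is an exact hull condition (the
lower convex hull of the band upper bounds must clear every lower bound),
checked in one monotone-chain pass per side.  Feasibility is monotone in
d, so the dip is found by bisection (tolerance 10⁻¹⁰).  The implementation
is verified exactly against an independent linear-programming oracle (the
same definition written as an LP over mode placements) on hundreds of
small samples, including ties; the kernel is numba-JIT-compiled when
available, with an identical pure-Python path.  p-values are a seeded
bootstrap against the uniform reference (the asymptotically
least-favorable unimodal null), 2000 replicates by default, cached per
sample size.

## Lick-bout detection and event-kernel regression

A lick bout is a burst of at least 4 licks (">3 licks", read strictly;
configurable) preceded by more than 8 s without licking; the first lick of
the series counts as gap-preceded, and pauses ≤ 8 s never split a bout.

The regression models the 0.5-s-binned firing rate as
`y(t) = offset + Σ_τ k_lick(τ)·licks(t−τ) + Σ_τ k_bout(τ)·bouts(t−τ) + ε`
with 19 lags each from −4.5 to +4.5 s, an intercept, lick *counts* per bin
and binary bout-onset indicators per bin (the lick stream is a count
process; bout onsets are point events).  The default analysis epoch is
15–45 min after feeding onset, when licking has settled into discrete
bouts, and photostimulation blocks are excluded.  All-zero predictor
columns are dropped with a flag; remaining rank deficiency is an error.
Each coefficient gets a partial (extra-sum-of-squares) F-test — for a
single column this equals t², with p from F(1, df_resid) — against the
Bonferroni threshold 0.05/19 ≈ 0.0026.  Relative modulation is the
largest-magnitude significant coefficient within ±2 s of onset divided by
the offset.  The API follows the statsmodels idiom (`KernelModel.fit()` →
`KernelResults` with `summary()`), with OLS itself delegated to
statsmodels.

## Pairwise lagged correlations

Rates are binned at 1 s, and slow co-fluctuations are removed with a
zero-phase 2nd-order Butterworth high-pass at 0.01 Hz (components slower
than ~100 s), so correlations reflect the ~1-s timescale.  Pearson r is
computed at every integer-bin lag up to ±20 s; r(τ) for (A, B) equals
r(−τ) for (B, A) exactly.  The zero-lag p-value uses the t distribution of
the correlation coefficient; zero-variance series are flagged undefined.

## Synthetic sessions

Spike trains are inhomogeneous gamma-renewal processes sampled by time
rescaling: in operational time Λ(t) = ∫λ, intervals are Gamma(shape,
1/shape), so shape 1 recovers an inhomogeneous Poisson process and the ISI
CV at constant rate is 1/√shape.  Full-session units default to shape 2
with an absolute refractory period of 1.5 ms (greedy thinning): real
accepted units show refractory-clean ISI histograms, and without this a
Poisson unit violates the 1-ms QC rule with probability approaching one —
the generator must emulate units that the QC stage would keep.

The rate is composed multiplicatively for slow terms — baseline λ₀ (drawn
2–10 spikes/s) × cue step at lickspout placement (defaults 0.7 for AgRP
units, 1.3 for inhibited-class units) × food step at feeding onset (0.4
and 2.0 — a 60% drop / twofold rise, matching the reported effect
direction and size class) × photostimulation gain while a train is on
(2.0 / 0.5 / 1.0 for the three classes) — plus an *additive* event-kernel
drive for lick and bout coupling, floored at zero.  The additive choice
for kernels mirrors the linearity of the regression being tested; bout
kernels peak at up to ~2.5 spikes/s (about 3× a low baseline, the top of
the reported range) and lick kernels at ~1 spikes/s.  Timeline defaults:
10-min baseline, 5-min cue period (within the 0.5–15-min experimental
range), 45 min of feeding, then a 100-train tagging block.  Licking is
organized into bouts (≥ 4 licks at ~150-ms spacing, inter-bout gaps
> 10 s), and rewards are thinned so consecutive deliveries are ≥ 2.5 s
apart.  Raw traces are additive: Gaussian noise plus biphasic per-channel
templates inserted so the template extremum lands on the spike time.

One master seed drives everything; per-unit streams are spawned from a
`SeedSequence`, so identical seeds and parameters reproduce event tables
bitwise.

What the generator does **not** emulate: electrode drift, overlapping
spikes and collision artifacts, non-stationary noise, bursty ISI serial
correlations, lick-rate nonstationarity within bouts, and real waveform
diversity.  Passing tests therefore demonstrate that the statistics are
implemented correctly and calibrated on in-model data — not that the
pipeline is robust to every pathology of real recordings.

## Calibration notes and known limitations

* The two-sample KS test is conservative on 5-s-binned rates at these
  sample sizes (60 baseline bins; integer counts produce ties, and the
  asymptotic p-value is itself conservative): the measured null rejection
  at p < 0.025 is ~1–2%, not 2.5%.  The calibration suite asserts type-I
  control (rejection ≤ nominal within binomial error, and nonzero), which
  is the property that matters for the epoch tests' validity.
* The unaffected class is labeled by *failure* to reject at α = 0.025 per
  t-test, so ~2.5% of truly unaffected units are expected to be falsely
  labeled driven — an irreducible property of the published decision rule
  that the classification-accuracy suite makes visible.
* Problem sizes in the test suite (e.g., 60-s traces for detection, 900-s
  regression spans, 500 null units for the shuffle calibration, 2000
  replicate fits for F-test calibration) were chosen as the smallest sizes
  at which the targeted effects and calibration bands are statistically
  decisive.
* Dip p-values are bootstrap-based and cached per sample size; with very
  large ISI counts the per-unit cost is dominated by the 2000 bootstrap
  dips (configurable via `dynamics.dip_n_boot`).
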