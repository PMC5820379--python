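# Methods

`slicephys` implements the analysis chain used to characterize epileptiform
network phenotypes in hippocampal slice electrophysiology and synaptic
FM1-43 imaging, together with a synthetic-data generator that reproduces the
hierarchical structure of such a study so that every stage is testable
without instrument data. This note documents the models, the estimators, the
numerical choices, and what the synthetic data do and do not emulate.

## Study design modeled

A cohort contains two genotypes (wild-type `wt` and mutant `mut`), several
animals per genotype, several slices per animal, and 64 array channels per
slice assigned to hippocampal sub-regions (DG, CA3, CA1). Each slice is
recorded under two conditions: normal ACSF, then a high-K⁺ challenge whose
perfusion switch occurs 20 s into the second acquisition. An acquisition is
600 consecutive one-second traces. Observations are therefore nested —
channels in slices in animals — and the inferential layer is built around
that nesting.

## Synthetic MEA recordings

**Firing regimes.** Wild-type channels fire as homogeneous Poisson processes
(default tonic rate 2 sp/s). Mutant channels fire as a two-state interrupted
Poisson process: exponentially distributed burst states (mean 0.3 s) with a
high within-burst rate (20 sp/s) alternate with exponentially distributed
silent gaps (mean 5.7 s). The process starts in its stationary state
distribution. These defaults put the mutant overall rate at 1 sp/s (below
wild type) while its rate *during activity* is an order of magnitude higher
— the qualitative phenotype the network statistics are designed to detect:
burst-like firing with a lower overall event rate, a higher active
frequency, and shorter inter-spike intervals. The simplest generative model
with these properties was chosen deliberately; no biophysical (conductance)
modeling is attempted.

**Random effects.** Animal and slice log-rate intercepts are Gaussian with
SD 0.15 and 0.10 respectively, shared by all channels of a slice and across
both conditions of that slice (the conditions are recorded from the same
tissue). These magnitudes give between-animal coefficients of variation of
roughly 15%, a realistic scale for slice electrophysiology.

**High-K⁺ response.** From the 20 s switch onward, rates are multiplied by a
region × genotype factor. Wild-type responses (×2, all regions) relax back
toward baseline with a 90 s time constant; mutant responses are sustained
(no relaxation) and graded along the trisynaptic circuit (DG ×2.5, CA3 ×3.5,
CA1 ×4.5), emulating uncontrolled downstream spread of depolarization-evoked
activity. Time-varying rates are realized by thinning.

**Waveforms and noise.** Each spike is a 1 ms biphasic template (positive
lobe then negative lobe; peaks +0.05/−0.04 mV for wild type, +0.04/−0.032 mV
for the mutant, giving the mutant the smaller extracellular amplitudes).
Noise is Gaussian with total SD `noise_sd` (default 0.003 mV) split between
a white electrode/thermal component (25% of variance) and a band-limited
low-frequency component (75% of variance; white noise low-passed at 150 Hz,
generated at 1 kHz and linearly interpolated to the acquisition rate). Raw
extracellular signals are dominated by low-frequency field potentials — that
is precisely why the detection pipeline begins with a 1 kHz high-pass — so a
composite spectrum is the realistic choice; with it, a quarter-threshold
total noise SD still leaves threshold crossings of filtered noise
vanishingly rare. At the defaults, P(|raw noise| > 0.021 mV) ≈ 2.6 × 10⁻¹²
per sample.

**Sampling rate.** The acquisition hardware's rate is not a protocol
constant; the default is 20 kHz and it is configurable. All windows are
specified in milliseconds and converted at the actual rate. Recordings are
stored as float32; a full-default recording is 64 × 12 × 10⁶ samples
(~3 GB), so cohort generation is exposed as a streaming iterator
(`iter_cohort`) and detection runs channel by channel.

**Determinism.** Every random stream is derived from the config seed plus
the (genotype, animal, slice, condition) coordinates, so identical configs
give bit-identical recordings regardless of generation order, and any single
recording can be regenerated in isolation.

## Spike extraction

1. **Bessel high-pass**: causal single-pass 2-pole Bessel at 1000 Hz,
   designed from the magnitude-normalized analog prototype (gain −3 dB at
   the cutoff) via the bilinear transform with cutoff pre-warping. The
   digital gain matches the analytic analog magnitude within 2% at 0.1×, 1×
   and 5× the cutoff at a 20 kHz rate. Causal filtering mirrors on-line
   acquisition; event times therefore carry a small systematic delay
   (~0.3 ms to first threshold crossing), which is irrelevant for
   within-pipeline comparisons, and waveform amplitudes are filter-shaped
   (a 1 ms biphasic wave loses roughly 45% of its positive lobe). Amplitude
   statistics are defined on the filtered signal.
2. **DC removal**: a running-median baseline with a 10 ms window — long
   relative to the 1 ms spike so spikes are preserved (a 1 ms pulse retains
   ≥ 95% of its peak) while offsets and drift are removed. The median is
   evaluated on a sparse grid (non-overlapping windows, odd length, so the
   median is a single order statistic) and linearly interpolated; this is
   numerically indistinguishable from a dense running median for baselines
   varying on ≫10 ms scales and orders of magnitude faster on 12 × 10⁶
   samples per channel. The baseline window is centered (non-causal); only
   the Bessel stage models the on-line causal path.
3. **Detection**: an event begins at the first sample exceeding +0.021 mV or
   falling below −0.021 mV; all supra-threshold samples within a 1 ms dead
   time of the running event are merged into it (so a biphasic spike's
   positive and negative crossings form one event). Amplitudes are the
   signed extrema over the event span, reported per polarity only when that
   threshold was exceeded. Events are assigned to the 1 s trace containing
   their start.

At full recording scale (64 channels × 600 s, 20 kHz) with noise at a
quarter of the threshold, ≥ 99% of ground-truth spikes are recovered within
0.5 ms with ≈ 0.1 false events per channel-recording.

## Network variables

Per channel and condition: spike count, frequency (count / 600 s), mean
inter-spike interval (between consecutive events within the same 1 s trace
only — traces are separate acquisitions), mean amplitude (+) and mean
amplitude (−) per polarity, and the **active frequency**: count divided by
the duration of the *active* traces only, where a trace is active if it
contains at least one event. "Duration of activity" is operationalized
through the recording's native 1 s segmentation — the only segmentation the
protocol defines — so `active_frequency = N / (active_traces × 1 s)` and
`active_frequency ≥ frequency` with equality exactly when every trace is
active. Region summaries pool channels (the "total" pool is all channels,
not a mean of region means); condition deltas are per-channel high-K minus
normal values, with missingness propagated and flagged.

## Evoked input/output analysis

A sweep's fiber volley and fEPSP are negative-going deflections measured
relative to the mean over the 5 ms pre-stimulus baseline, in configurable
windows (defaults: volley 1–4 ms, fEPSP 4–20 ms post-stimulus). The stimulus
artifact is blanked (linear interpolation over the first 1 ms post-stimulus)
and each window is measured on a Savitzky–Golay-smoothed copy (quadratic,
0.75 ms window for the narrow volley, 3 ms for the broad fEPSP): a raw
window minimum is biased by the expected extremum of the noise, while
quadratic-preserving smoothing keeps the deflection peak, giving mean
amplitude errors ≈ 1% at signal-to-noise ratios of 10. The I/O ratio is
log₁₀(fEPSP/volley) — the base is a convention; any base change is monotone
— reported per current with the group-comparison summary restricted to
20–100 μA. The synthetic sweeps use Hill-type saturating amplitude–current
functions (half-max 40 μA, coefficient 2), a Gaussian volley (2.5 ms
latency) and a Gaussian fEPSP (13 ms latency), since the real curves are
sigmoid but no functional form is canonical.

## Nested mixed-effects contrasts

Each network variable is analyzed with a linear mixed model: fixed effects
per the contrast of interest (genotype, condition, genotype × condition),
random intercepts for animal and for slice-within-animal, and a channel-level
residual, fitted by REML (statsmodels `MixedLM`; slices are coded within
animal so the variance-component design stays low-dimensional; if L-BFGS
fails to converge — typical near σ → 0 boundaries — the fit is repeated with
Powell's method, which is reliable there). Responses are Box-Cox transformed
when a Shapiro–Wilk screen rejects normality (λ selected by profile
likelihood over [−2, 2] in steps of 0.01; non-positive data are shifted
first; λ is recorded with the model).

Wald 95% CIs and p-values use **containment degrees of freedom**: each fixed
effect is tested at the coarsest grouping level it is constant within — a
genotype contrast against (animals − between-animal parameters), a
within-slice effect against the observation-level df. This is simple,
conservative and reproducible. Simulation at 6 animals/genotype × 3 slices ×
8 channels with σ_animal = σ_slice = 0.2, σ_resid = 0.5: type-I error 0.06 at
α = 0.05 (100 replicates), 95% CI coverage 96/100, and with zero true
variance components the σ estimates fall below 0.03 while fixed effects
match OLS exactly on balanced designs.

## Temporal rate curves

Spike counts per channel per 1 s bin are summed within a group and smoothed
with a penalized cubic B-spline Poisson regression of log rate on time
(offset log(n_channels × bin width); estimates reported per channel-second).
Numerical design:

- **Knots**: 20 uniform interior knots over the recording by default.
- **Breakpoints**: the smooth can be allowed to *restart* at known
  intervention times (the 20 s perfusion switch): the curve is fitted
  independently on each segment with a knot budget proportional to segment
  length (minimum 4). This resolves an abrupt rate change exactly at the
  switch without smoothing leakage into the pre-switch baseline.
- **Penalty**: first-difference penalty on the coefficients, whose null
  space is the constant log rate — the homogeneous-Poisson reference that a
  featureless segment should collapse to under heavy smoothing.
- **Penalty selection**: generalized cross-validation over a fixed
  log-spaced grid (10⁻⁴…10⁶), with the effective-df term inflated by
  γ = 2 — the standard guard against GCV undersmoothing, which matters on
  short (20-bin) pre-switch segments.
- **Bands**: pointwise 95% from the Bayesian posterior covariance of the
  penalized estimator (the convention of GAM software), inflated by a
  channel-level Pearson overdispersion factor φ — channels differ through
  random effects the pooled smooth does not model, and φ propagates that
  extra variance into the bands instead of a full crossed random-smooth
  model (a deliberate simplification).
- **Difference intervals**: the difference of two group curves with the
  summed-variance band; significant intervals are maximal runs of bins whose
  band excludes zero. For *interval detection* the critical value is
  Šidák-adjusted for the summed effective df of the two smooths, holding the
  family-wise chance of flagging any interval under a null difference near
  α across the whole recording; pointwise bands are available by flag.
  Without this, a true-null pre-switch segment — whose fitted values are
  almost perfectly correlated — is flagged in toto in about 5% of
  replicates, an all-or-nothing artifact of pointwise bands.
- **Degenerate input**: an all-zero group yields a flagged floor curve with
  infinite-width bands.

On a simulated 1 → 5 sp/s step at 20 s (64 channels × 600 s), both plateaus
are recovered within 10% outside ±10 s of the step, the fitted curve's rate
integral matches the observed spike count within 5%, and the difference
intervals against a constant group cover ≥ 90% of the post-step region while
flagging ≤ 5% of the pre-step region (0 failures in 40 seeded replicates).

## FM1-43 destaining kinetics

Per-bouton traces are background-corrected (post-experiment background
subtracted; flagged if the corrected pre-stimulus mean is non-positive),
normalized so the mean pre-stimulus level is exactly 1, and fitted with
F(t) = plateau + A·exp(−k(t−t₀)) over the first release round only (later
rounds are kept for QC), by bounded nonlinear least squares
(k ∈ [10⁻⁴, 10] s⁻¹; initial values from the last window value and a
log-linear regression on the first third). Reported per bouton: k, t½ =
ln 2 / k, the recycling pool = 1 − plateau (total normalized fluorescence
released), residual sum of squares, and a `fit_ok` flag (false when the RSS
exceeds a noise-scaled bound, k sits at its box limits, or the released
amplitude is below 0.02 — no measurable decay). The "release rate" is not
given a formula by destaining experiments themselves; the single-exponential
rate constant of the first round is standard practice and monotone in any
reasonable alternative.

The destain simulator draws per-bouton rates from log-normal distributions:
wild type median 0.05 s⁻¹ (shape 0.35); the mutant is a two-component
mixture — half the synapses wild-type-like, half fast (median 0.18 s⁻¹) —
encoding selective acceleration of a synapse subset rather than a uniform
shift. The lipid-supplementation arms encode the rescue result as ground
truth: 28:0+30:0 restores the wild-type rate distribution, 24:0 does not,
and the recycling pool (wild type 0.75, all mutant-derived groups 0.55) is
not rescued by either. Four stimulus rounds at 30/150/270/390 s with 0.5 s
frames give the slowest simulated rate (0.02 s⁻¹) k·T ≈ 2.4 within the
fitted round. Recovery at imaging noise 0.01: mean |k̂/k − 1| ≈ 1% for
k ∈ {0.02, 0.05, 0.1, 0.2} s⁻¹.

Group comparison uses empirical CDFs and pairwise two-sample
Kolmogorov–Smirnov tests (D computed exactly over pooled points; p from the
asymptotic Kolmogorov distribution at √(n_eff)·D, n_eff = n_a·n_b/(n_a+n_b))
with Holm adjustment across pairs; groups with fewer than 10 usable boutons
are excluded with a warning.

## Problem sizes in the test and acceptance runs

Simulation sizes in the shipped tests and in `scripts/acceptance.py` are the
package's chosen verification scales: full-recording detection fidelity uses
one 64-channel × 600 s acquisition at the default 20 kHz; the end-to-end
cohort run uses 3 animals/genotype × 2 slices × both conditions at a 4 kHz
acquisition rate (the rate is a config-level assumption, not a protocol
constant, and the phenotype contrasts do not depend on it); mixed-model
calibration uses 100 replicates of 6 animals/group; the destaining
comparison uses the study-scale 2200 synapses per genotype (1600 and 900 in
the supplementation arms).

## What the synthetic data do not emulate

Passing tests demonstrate correct recovery of the generative models above,
not robustness to everything real recordings contain: electrode artifacts
and 50/60 Hz interference, spike-waveform diversity and overlap (no spike
sorting is attempted — events are threshold crossings, as in the modeled
acquisition chain), nonstationary drift of firing over tens of minutes,
photobleaching and focus drift in imaging, and non-exponential (multi-pool)
destaining. Burst structure is first-order Markov; real epileptiform
discharges have richer temporal organization. The mixed-model layer assumes
Gaussian random effects and residuals after transformation.

## Known limitations

- Event times carry the causal filter delay; absolute latencies should not
  be compared against other acquisition chains.
- The channel-level overdispersion factor is a variance inflation, not a
  full random-effects smooth; bands are approximate when channels are few.
- Containment df is conservative for effects whose information is split
  across levels.
- The KS p-value is asymptotic; for very small samples it is approximate
  (the D statistic itself is exact).
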