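# Methods

This note documents the models and procedures implemented in `devcortex`,
the parameters that matter, the design decisions taken where the published
analysis conventions leave the design open, and what the synthetic-data
generators do and do not emulate.

Units throughout: times in seconds, distances in µm, currents in pA,
voltages in mV, ΔF/F₀ as a dimensionless fraction (0.12, not 12%). Arrays
are indexed `(t, y, x)`, 0-based, with half-open ranges.

## Wide-field network events

ΔF/F₀ is computed per pixel as `(F − F₀)/F₀` with F₀ a **centered**
moving average across 500 frames, truncated symmetrically at the movie
edges. A trailing window would bias event onsets; centering is the
default and the window is configurable. Non-positive F₀ anywhere aborts
with the offending pixel named, since it indicates an invalid raw movie.

A network event is a connected component of voxels with ΔF/F₀ ≥ 0.12
containing at least 300 voxels. "Connected in time and/or space" is
implemented as 26-connectivity in `(t, y, x)` (the common 3D default),
with 6-connectivity selectable; no convention is authoritative, so both
are first-class and tested against an exhaustive flood-fill oracle.
Event amplitude is the maximum ΔF/F₀ over the event's voxels — note that
with per-voxel noise this maximum is biased upward by the extreme-value
statistics of the (many) voxels in an event.

Event area is restricted to pixels whose within-event maximum reaches 67%
of the event peak. Per-pixel area has a `"printed"` rounding mode (59 µm²,
the printed integer for a 7.68 µm pixel) and an `"exact"` mode (7.68² =
58.9824 µm²); the default is `"printed"` so printed worked examples
reproduce exactly. Events are assigned to a named region (e.g. V1, S1)
when the majority (> 50%) of their restricted footprint overlaps the
region mask. Frequency time courses count event onsets in 5-min bins.

The detected-event count is monotone non-increasing in `min_event_size`
always, and in the threshold for blob-shaped events whose suprathreshold
level sets shrink without fragmenting; on arbitrary binary stacks a higher
threshold can split one component into several, so the monotonicity
property is asserted in the event-like regime it describes.

For awake recordings, a 1D trace over a region is low-pass filtered
(4th-order zero-phase Butterworth, default cutoff 2 Hz — the published
description says only that high-frequency movement artifacts were
removed) and peaks are found with prominence and minimum-height
parameters that the caller must fix once per experiment.

## Population correlations

Correlations are Pearson coefficients of the **continuous** ΔF/F₀ traces,
not of binarized event rasters; event rasters serve frequency analyses
only. Windows are 7 minutes long and slide in 60-s steps (the step is not
specified by the source analyses; 60 s gives a smooth time course at
modest cost). Windows are constrained to lie entirely inside one epoch
when epochs are compared. Cells with zero variance inside a window are
excluded from that window with a logged count.

Per-cell event detection thresholds at `k·σ_noise` (default k = 2) with
σ_noise estimated robustly as `1.4826·MAD(diff(trace))/√2` — the first
difference suppresses slow transients, approximating the noise "in the
absence of events" without manual annotation. A crossing must stay
suprathreshold for 3 frames (calcium transients at 4–7 Hz last many
frames; single-sample noise excursions do not), and the trace must fall
below half threshold before a new onset is accepted. Without the duration
criterion a 2σ threshold would fire constantly on white noise.

**Distance dependence.** Per-pair epoch-averaged correlations give
`delta = post − base` and `pct_change = 100·delta/base` for pairs with
`|base| ≥ 0.01` (excluded pairs are counted). OLS lines of both against
pair distance are fitted, and the per-dataset Pearson r between distance
and percent change is the headline statistic; it is reported as 0 with a
flag when degenerate (identical epochs).

**MSD.** `MSD(t) = Σᵢⱼ (cᵢⱼᵗ − cᵢⱼᴮᴸ)²` summed over **all** N² entries
(the diagonal contributes zero; symmetric entries count twice — an i<j
mode is selectable and differs by exactly ×2 before normalization, which
is immaterial after z-scoring). The baseline matrix uses the full 45-min
baseline span. A line fitted by OLS on the baseline-epoch MSD values is
subtracted from all time points (skipped with a flag below 3 baseline
windows), then the series is z-scored by the baseline mean and SD (an
all-zero series with a flag when the baseline SD is 0).

**Subtractive vs divisive.** Both one-parameter models — `post = base − c`
and `post = a·base` — are fitted by least squares and compared by AIC
(`n·ln(RSS/n) + 2`); the label is the better model when ΔAIC > 2, `mixed`
otherwise, and `indeterminate` when baseline correlations are all equal.
Because the subtractive model fixes the slope at 1, errors-in-variables
attenuation of measured baseline correlations works against it; the
comparison is reliable when the true spread of baseline correlations is
large against per-pair sampling noise, which is the regime of the
recordings this package targets (and of its generator defaults).

Across-animal dispersion offers both the standard SEM (σ̂/√N, default) and
a σ̂/N convention that appears in some published figure legends.

## Patch-clamp features

PSC detection is template-free: a heavily smoothed derivative (Gaussian,
0.3 ms) must exceed 5 robust SDs for at least 0.2 ms, and the candidate's
local-baseline amplitude must exceed 5 robust SDs of the trace. Amplitude
and the 20–80% rise time (linear interpolation between fractional
crossings) are measured on a minimally smoothed copy (0.05 ms) so the
detection smoothing does not broaden the rise. The reported rise rate is
exactly amplitude/rise-time. Any detector satisfying the fixture-recovery
tests is conformant; this one is deliberately simple.

AP threshold is the first sample with dV/dt ≥ 20 mV/ms (a common
convention; configurable). Overshoot is the peak above 0 mV, amplitude is
peak − threshold, width is measured at half amplitude by interpolation,
ΔTime is pulse onset → threshold, and max dV/dt is taken on the rising
phase.

Ramp excitability uses the −100 → +140 pA at 96 pA/s protocol (2.5 s,
fourteen full 175-ms bins plus a flagged partial remainder). ISIs are
assigned to the bin containing the first spike of the pair (unspecified in
the source description); frequency is 1/mean ISI; empty bins are NaN. The
quasi-static comparison against the closed-form LIF rate is valid well
above rheobase, where the stationary rate changes slowly within a bin.

Membrane-potential timelines take the per-bin **median** after blanking a
window around each spike (robustness to residual spike samples); the
depolarization is the peak post-application bin minus the last baseline
bin. Series-resistance QC fails a cell when any Rs exceeds 30 MΩ or
deviates more than 30% from the first measurement.

## Spiking-network model

Current-based leaky integrate-and-fire neurons on a square sheet with
periodic boundaries (torus metric, avoiding edge effects). Membrane update
is the exact exponential step at dt = 0.1 ms; synapses are exponential
currents (τₑ = 5 ms, τᵢ = 10 ms) with a 1-ms conduction delay; each
neuron receives an Ornstein–Uhlenbeck current noise (SD 12 pA, τ = 5 ms).
Connection probability is `p₀·exp(−d²/2σ_c²)` per presynaptic class.

Printed, non-negotiable parameters: 25% of the inhibitory population is
SST+; external currents 50 pA to excitatory and 40 pA to SST+ cells; a
sinusoidal background to the excitatory population; 60 s per condition;
and the oxytocin perturbation itself — SST+ V_rest −60.8 → −56.3 mV
(+4.5 mV), changing nothing else, with the dynamical state and noise
stream continuous across the switch.

All other intrinsic parameters are free configuration. The defaults were
chosen to place the network in the intended operating regime, not to match
unpublished values:

* SST+ (C 25 pF, g_L 2.5 nS, V_th −44 mV) has rheobase 42 pA — just above
  the 40 pA drive — so baseline SST+ cells fire only when excitatory
  events recruit them, and the 4.5 mV depolarization (rheobase → 30.8 pA)
  makes them tonically active.
* Excitatory cells (C 30 pF, g_L 3 nS, V_th −46.5 mV) have rheobase
  55.5 pA, above the 50 pA drive, so firing is driven by the sinusoid
  peaks (±15 pA at 0.5 Hz), noise and recurrence: activity is episodic
  rather than tonic, and baseline voltage correlations are carried by
  recurrently amplified population events rather than by the shared
  sinusoid alone.
* Weights (Wₑ = +12 pA, Wᵢ = −40 pA per spike) and kernels (p₀ = 0.4
  excitatory / 0.8 inhibitory, σ_c = 200 µm) give dense enough local
  inhibition that tonic SST+ firing suppresses excitatory activity, while
  nearby excitatory cells share inhibitory sources. That shared inhibition
  is what makes the oxytocin-induced decorrelation grow with distance:
  distant pairs lose the long-range event correlation and gain independent
  inhibitory fluctuations, while near pairs retain common input.

Voltage correlations are Pearson coefficients of the recorded excitatory
membrane potentials (1 kHz, unclipped — spike resets included; clipping is
selectable), averaged within toroidal-distance bins; `delta` is oxytocin −
baseline. Isolated-neuron f–I curves use a dedicated single-neuron
integrator with interpolated threshold crossings, which matches the
closed-form LIF rate `f = [t_ref + τ ln((V∞−V_reset)/(V∞−V_th))]⁻¹` to
numerical precision; the network integrator quantizes spike times to dt.

Tests and the bundled acceptance script run the model at a reduced size
(500 neurons, 20 s per condition, 200 recorded excitatory cells), which
preserves the qualitative signatures; the full-size default (2000 neurons,
60 s) is the configuration users should start from. The perturbation
signatures are inherently stochastic across connectivity realizations and
are therefore asserted as directions holding in ≥ 4 of 5 seeds.

## Synthetic data generators

All generators draw from named, seeded RNG streams; identical spec + seed
gives bit-identical output.

**Wide-field movies.** Events are spatial Gaussians (σ = 90 µm)
multiplied by a one-frame rise and exponential decay; the raw movie is
`1000·(1 + ΔF/F₀) + noise` a.u., making the ΔF/F₀ round trip exact up to
the event's own contribution to the moving-average F₀. The default decay
(0.1 s) is faster than real indicator kinetics; it was chosen so that an
event's temporal integral is small against the 500-frame F₀ window, which
keeps that self-contribution under 1% of the peak and lets ground truth be
analytic (voxels where the injected ΔF/F₀ ≥ 0.12). Event times are
Poisson (0.042 Hz per region) thinned to a 2-s minimum separation, and
centers are uniform over the region mask eroded by the suprathreshold blob
radius — together these guarantee disjoint ground-truth voxel sets and
fully in-frame events. Consequences users should know: realized rates are
~4% below nominal (dead time), and the generator does not emulate slow
indicator decay, scattered light, vignetting, or hemodynamic artifacts —
passing tests show the detector recovers events of the assumed shape, not
robustness to those nuisances.

**ROI populations.** Cells are uniform in a 300-µm field. Two event
classes drive the traces: *local* events (0.15 Hz) with a center drawn
uniformly and recruitment probability `exp(−d²/2ℓ²)` (ℓ = 80 µm), and a
*coherent background* of low-amplitude (0.05 ΔF/F₀) transients shared by
all cells. Recruitment draws share one uniform variate per event
(comonotone coupling), so coincident cells participate identically and
the pair recruitment probability is `min(pᵢ, pⱼ)` — this yields the broad,
distance-decaying baseline correlation range (≈ 0.65 near → 0.35 far at
defaults) characteristic of developing-cortex populations. The
coherent-background rate is calibrated by a fixed-point iteration so the
mean pairwise correlation offset equals `sync_corr` (default 0.2),
accounting for noise dilution. The post-application subtractive shift
(default 0.1) replaces a fraction `shift/sync_corr` of the coherent train
with per-cell private trains of equal rate: per-cell rates and variances
are untouched while every pair's covariance drops by the same amount — an
exactly subtractive, non-divisive change. A `subgroup_fraction` option
instead reroutes that subgroup's coherent train to a private shared train
post-application, restructuring the correlation matrix at constant event
frequency (the sustained-MSD fixture). Local events are frequent,
spatially confined coactivations; the rarer large synchronized events of
in-vivo recordings are represented only through the coherent background,
and trace nonstationarities (drift, bleaching) are not emulated — the MSD
detrending step is exercised on a flat baseline.

**Ephys traces.** PSC trains are sums of unit-peak biexponentials
`exp(−t/τ_d) − exp(−t/τ_r)` at Poisson times with logged onsets and
amplitudes; the analytic 20–80% rise time comes from root-finding on the
closed form. APs are piecewise-linear: a subthreshold ramp reaching the
threshold exactly `ΔTime` after pulse onset, then a triangle with rise
slope twice the fall slope sized so the width at half amplitude equals the
requested value — every reported feature has a closed-form ground truth.

## Numerical choices and degenerate inputs

* Correlation of a zero-variance trace is undefined → excluded + counted,
  never NaN-propagated into means.
* `percent_change` rejects a zero baseline; pairs with |baseline
  correlation| < 0.01 are excluded from percent change.
* MSD normalization guards a zero baseline SD (flagged, zeros).
* The modulation classifier guards RSS = 0 (exact fits) and an all-equal
  baseline (`indeterminate`); ΔAIC < 2 is `mixed`.
* The network simulator aborts with diagnostics if |V| exceeds 200 mV.
* All detectors use half-open frame indexing; interpolated crossing times
  are used wherever sub-sample precision matters (PSC rise, AP half-width,
  spike times in f–I measurements).

## Known limitations

* The wide-field generator's short transients trade indicator realism for
  analytic ground truth (see above).
* The PSC detector is not the published (unpublished-algorithm) tool it
  stands in for; conformance is defined by fixture recovery.
* The network model implements only the single cortical sheet — no
  thalamic or retinal stages, no conductance synapses, no plasticity — and
  its unprinted intrinsic parameters are this package's own defaults, so
  only directions and closed-form properties are claims, never absolute
  rates.
* The subtractive/divisive classifier is attenuation-prone when per-pair
  sampling noise rivals the true spread of baseline correlations; with
  short epochs or few events expect `mixed`/`divisive` mislabels.
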