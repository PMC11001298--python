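# Methods

## The quantity being studied

A point sensor in a turbulent odor plume sees an intermittent signal:
whiffs of high concentration separated by blanks. The intermittency

γ = Prob[C ≥ 0.1·C₀]

summarizes this structure as the fraction of time the concentration C
sits at or above a tenth of the source concentration C₀. γ falls with
distance from the source, so an animal that can discriminate γ has a
cue for odor-source distance. The package quantifies γ at three levels:
the delivered stimulus, the stimulus as sampled by sniffing (estimated
perceived intermittency), and the response of olfactory-bulb glomeruli
(glomerular intermittency, GI).

All trials share one timeline: 2 s pre-odor, 6 s odor, 1 s post-odor.
γ-type statistics are always evaluated over the 6 s odor window, with
the threshold tied to the gain-1 C₀ — halving the delivered gain scales
the trace but not the threshold. Threshold comparisons are inclusive
(≥), and the CS bands are γ ≤ 0.15 (CS−, withhold), γ ≥ 0.2 (CS+,
lick); the open gap (0.15, 0.2) is labeled `excluded` rather than
silently assigned.

## Stimulus generation

Square-wave stimuli place n ∈ 1..8 equal pulses evenly across the 6 s
window with duty cycle d ∈ (0, 100); by construction γ = d/100, exact
to one sample (the generator uses integer phase arithmetic, so any duty
for which 6000·d/100 is whole is exact at the 1 kHz stimulus clock).

Plume-like stimuli are a two-state renewal (telegraph) process:
whiff and blank durations are exponential with means γ·T and (1−γ)·T on
a mean cycle of T = 1 s. Exponential durations are the simplest
memoryless choice; the mean cycle length is in the range of whiff rates
a walking rodent encounters meters from a source, and whiffs at γ = 0.2
still span ~5 imaging frames. The realized γ of the finished trace is
measured with the 0.1·C₀ threshold and the requested duty fraction is
re-adjusted (≤ 50 iterations) until it lands within ±0.02 of target;
non-convergence raises an error naming the target and the last realized
value. "Naturalistic" traces add per-whiff amplitude variation
(uniform 0.55–1 × C₀) and a 20 ms first-order smoothing before
renormalizing the peak to C₀; only γ is matched to real plumes — the
autocorrelation and whiff-duration law of measured plume data are not
reproduced, and no fluid dynamics is simulated.

## Sniffing

The synthetic pressure waveform is one cycle per breath: a positive
half-sine inhalation lobe (30% of the cycle), a negative exhalation
lobe (35%), then a pause; cycle periods optionally jitter (SD 10% of
the period). Detection finds local maxima with prominence above 1.5×
the MAD-based robust SD of the trace, at least 1/12 s apart, and takes
each onset as the last non-positive→positive sign change before the
peak; a peak with no such crossing is dropped. The trace is bracketed
with its global minimum before peak finding so that the first
inhalation of a recording, whose prominence is otherwise edge-limited,
is not lost. The 1.5× factor is the largest round value that still
detects every peak of a pure sinusoid (whose peak prominence is 2× its
amplitude while its robust SD is 1.048× — a 2× factor provably misses
them); for realistic waveforms with inter-breath pauses the margin is
several-fold.

Inhalation periods are half-open [onset, peak) intervals. Perceived
odor is the concentration restricted to inhalations intersected with
the odor window; perceived γ is the supra-threshold fraction of those
samples, NaN (and excluded from aggregates) when total inhalation time
is zero. The cumulative version evaluates the same fraction on inhaled
samples from odor onset up to each grid time; at the full window it
equals the final perceived γ exactly. For periodic stimuli the
perceived γ of any single trial depends on sniff phase, but its
expectation over uniformly random phase equals the stimulus γ — a
property the tests check by Monte Carlo at 3×SEM.

## Imaging preprocessing

Raw fluorescence at 25 frames/s is processed per glomerulus-trial:

1. ΔF/F with F₀ the mean of the 100 ms window ending at odor onset
   (error if F₀ ≤ 0);
2. zero-phase 4th-order Butterworth bandpass 0.075–10 Hz. Two numerical
   points matter at a 25 Hz clock: the filter is applied as second-order
   sections, and the forward–backward pass uses maximal odd-extension
   padding, because the 0.075 Hz corner has a ~2 s time constant and
   the default fraction-of-a-second padding leaves edge transients that
   visibly corrupt a 9 s trial. Zero-phase filtering doubles the
   effective order but keeps T75 latencies free of filter delay;
3. photobleaching correction: a quadratic is fit to the pre-odor and
   post-odor samples only and subtracted everywhere. The first 0.5 s of
   the post-odor window is excluded from the fit so the indicator's
   decay tail from responses ending near odor offset does not bias the
   drift estimate;
4. deconvolution of the GCaMP6f kernel with τ = 150 ms, as exact
   inversion of the discrete causal AR(1) kernel
   c_t = a·c_{t−1} + (1−a)·r_t, a = exp(−Δt/τ), with the signal assumed
   at steady state before the first sample. Forward and inverse are a
   strict pair: convolve(deconvolve(x)) = x to numerical precision, a
   constant maps to itself both ways, and no non-negativity or sparsity
   constraint is imposed;
5. z-scoring against the mean and SD of the 2 s pre-odor window of the
   deconvolved trace; σ_pre = 0 flags the glomerulus-trial invalid
   rather than propagating infinities.

The first-sniff response is measured in the window from the first sniff
onset at/after odor onset to the next onset, capped at 1 s (one
inter-sniff interval is the natural unit; the window is otherwise
unbounded in the source analyses). Amplitude is the trough-to-peak range
of the z trace in that window, measured after a 3-frame (120 ms) boxcar:
exact kernel inversion amplifies and anti-correlates frame noise, and
the pointwise range of that noise alone exceeds 2 z-units in a
half-second window most of the time, which would make the responder
criterion vacuous; the light smoothing collapses the noise range (to
≈ 0.9) while leaving response plateaus intact. T75 is the time from
sniff onset to 75% of the trough-to-peak response measured on the
ΔF/F-scale (bleach-corrected) trace. A trial responds iff amplitude
strictly exceeds 2; a glomerulus is a responder iff strictly more than
10% of its valid trials respond. Note the responder rule keys on the
*first* odor sniff: blank-activated units (cluster 1 below) are silent
during the first whiff by construction and are therefore not flagged by
it; encoding statistics use all units.

## Glomerular encoding statistics

GI is the fraction of odor-window samples with z ≥ 2 (inclusive,
matching the definition; responder detection uses strict >, and both
readings are kept as printed in their respective rules). The GI slope is
the OLS slope of per-trial GI on odor γ across all trials. Encoding is
tested with a one-way fixed-effects ANOVA over γ groups {0.2, 0.5,
0.8} — trials binned to the nearest target within ±0.05, out-of-band
trials excluded — and a unit is an encoder iff p < 0.001. The tests pin
the ANOVA to a hand-computed between/within decomposition and to a
10⁵-draw permutation oracle on a small instance.

Cross-correlograms use Pearson normalization per lag on mean-subtracted
traces over ±12 lags of 40 ms (±480 ms at the 25 Hz clock); reference
signals (PID or sniff pressure) are box-average downsampled first. The
shuffle control is the per-lag mean over 10 whole-trace random sample
permutations of the response — destroying temporal structure while
preserving the marginal — subtracted pointwise; the peak of the
corrected curve and its lag are reported, with positive lag meaning the
response lags the reference. Spatiotemporal maps correlate a
per-glomerulus scalar (amplitude, T75, odor correlation) with the
anterior–posterior pixel coordinate and the distance from midline, per
trial, averaging only defined values.

## Population analysis

Each glomerulus's GI profile is its mean GI per γ bin (0.1–0.8 in 0.1
steps, nearest-bin within ±0.05). Profiles are correlated pairwise
(zero-variance profiles flagged and excluded) and clustered
agglomeratively on the correlation distance d = 1 − r, cutting the tree
at 0.74. Single linkage is the default (MATLAB's `linkage()` default,
kept for comparability with analyses written there); average linkage is
available by argument. Clustering is invariant to input order, one glomerulus per
cluster as the cutoff → 0, and a single cluster at cutoff ≥ 2.

Decoding uses a linear discriminant with class means, pooled
within-class covariance and equal priors, written in-house and
cross-checked against scikit-learn's implementation on well-conditioned
data. When the pooled covariance is rank-deficient or ill-conditioned
(fewer training trials than glomeruli), the spectrum is ridged by
λ = 10⁻⁶·trace/dim and inverted only within the data subspace — naively
inverting the ridged matrix would amplify null-space noise by 1/λ; with
zero pooled covariance the model degenerates to nearest-mean.
Cross-validation follows the source protocol exactly: trials are
partitioned into three groups stratified by γ, the model trains on one
third and tests on the remaining two thirds, for each group in turn, 20
repeats with derived sub-seeds. Accuracy is #correct/#test trials and
the true-positive rate is #correctly-predicted-CS+/#CS+ test trials. A
fold whose training third lacks a class is re-drawn (logged) up to ten
times. Note that with train-on-1/3 the training set is small; accuracy
versus glomerulus count can dip once features approach the training
size, which is faithful to the protocol rather than a defect.

The shuffled-label control re-runs the identical pipeline on permuted
labels. The null should be read across permutations: any single
permutation's cross-validated accuracy has spread around 0.5 much wider
than its within-repeat SE (sampling without replacement anti-correlates
train and test label-feature associations), so the calibration tests
average ~20 permutations.

## Go/No-Go behavior

The trial timeline appends a 0.5 s tone and a 1.5 s decision window
after odor offset. Only decision-window licks determine the outcome;
earlier licks are recorded as anticipatory. Session metrics start with
the first trial after the fourth hit — read as the cumulative fourth
hit, with a flag for the consecutive reading; both coincide on the
standard 8-trial high-γ engagement prefix. HR, FA and performance =
HR − FA are exact ratios; the criterion HR > 0.75 and FA < 0.25 is
strict on both sides (HR = 0.75 fails). Excluded-band trials never
enter the counts. First-lick times are referenced to odor onset.
Decoding from perceived intermittency uses the cumulative perceived γ
up to each time cutoff as a single feature in the same cross-validated
discriminant, with a shuffled-label control and Bonferroni correction
across cutoffs (the family is the cutoff count).

## The synthetic generator and what passing tests mean

The generator plants two glomerular phenotypes. A cluster-2 unit with
planted slope s responds during each whiff it samples — a whiff counts
as sampled when an inhalation interval overlaps it — for the first
s-fraction of the whiff's duration, after its latency; its expected GI
is s·γ. A cluster-1 unit does the same on blanks, giving
GI = |s|·(1 − γ). Durations, not amplitudes, carry the planted slope,
because GI is a time-above-threshold fraction and amplitude scaling
cannot move it once the response clears z = 2. Slope presets are
+0.89 and −0.59 with ±0.04 jitter across units, the reference
population split is 37/191, and response gain and latency follow a
posterior–lateral gradient (gain 0.09–0.18 ΔF/F, latency 40–140 ms) so
spatial-map statistics have planted signal. Activation edges are
smoothed with a ~60 ms Gaussian so the planted rate is band-limited to
the preprocessing passband; the smoothing is symmetric, preserving
epoch durations and hence planted slopes.

Fluorescence is F = F₀·(1 + ΔF/F) with the response convolved by the
same AR(1) kernel the preprocessing inverts, plus quadratic bleaching
(≈ −3% over 9 s) and white frame noise (SD 0.003 ΔF/F, i.e. z-scored
response amplitudes around 8–12, comparable to strong glomerular
responses; "moderate noise" in the recovery tests means this default).
Licking follows a logistic policy on the trial's true perceived γ
(threshold 0.175 — the midpoint of the CS gap — slope 50), with
first-lick latency decreasing linearly in perceived γ (5.4 − 2.2·γ s
plus 0.3 s noise), so hit rates, false alarms and latency slopes have
known ground truth.

What the generator does not emulate: real plume statistics beyond γ,
sniff-locked response phase within a breath, correlated (non-white)
imaging noise, movement or hemodynamic artifacts, ROI segmentation
errors, and any within-session learning or motivation drift. Passing
recovery tests therefore demonstrates that the estimators are correct
and unbiased under the stated forward model, not that real recordings
meet that model.

## Problem sizes and tolerances in the test suite

Recovery suites run at sizes where the checked property is
well-resolved: GI-slope recovery uses 50 units × 180 square-wave trials
(γ ∈ {0.2, 0.5, 0.8} × 60, the size of the encoding protocol) with
per-unit error bounded by ±0.10 and ≥95% sign recovery; cluster
recovery uses the full 228-unit (37/191) session over 56 trials;
decoding uses 25 units × 180 trials with 20×3-fold repeats, and its
label-shuffled null averages 20 permutations. Deterministic checks
(square-wave γ, round trips, behavioral bookkeeping) are exact to
quantization or to 10⁻⁶–10⁻¹⁰; Monte-Carlo checks state 3–4×SEM bands.
Generator determinism is asserted at byte level via a SHA-256 digest of
all session arrays.
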