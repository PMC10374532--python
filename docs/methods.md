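# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `respmem`. Units follow the field's conventions:
seconds for time, milliseconds for pulse phases, Hz for rates, cm and
pixels (with an explicit `px_per_cm` / `px_per_um` calibration) for space,
arbitrary units for plethysmographic pressure, and percent for ensemble
fractions.

## Stimulus trains and interval algebra

A pulse train is `n_pulses` repetitions of an on/off period. Flat
(continuous) stimulation is a single pulse with no off phase and duty
cycle 1. Durations that do not hold an integer number of periods are
rejected rather than truncated — the experimental sequences are exact (40
and 16 pulses) and silent truncation would misreport total light dose.

All behavioral and stimulation epochs are half-open `[start, end)`
intervals in seconds, so adjacency is unambiguous and union measure is
additive. `coverage_ratio` intersects against the union of light-**on**
phases by default (a literal reading of "stimulation during exploration");
callers who want envelope-based coverage can pass full train extents.
For flat trains the two notions coincide. The interval intersection is
exact sweep-line arithmetic; tests cross-check it against a 1-ms grid
sampler.

## Breathing simulation

Each breath cycle is rendered as an asymmetric raised-cosine pressure
pulse with an inspiratory (rising) limb occupying 35% of the cycle — a
generic shape chosen because real plethysmographic waveform morphology
varies with chamber, animal and anesthesia; the analyzers must not and do
not depend on it. Cycle durations are lognormal (strictly positive),
parameterized so the mean and coefficient of variation hit their targets
exactly in expectation; `cycle_cv = 0` degenerates to constant durations.
Default mean cycle 0.3 s (~3.3 Hz) is a resting-mouse rate; default
noise SD 0.05 at amplitude 1 gives SNR 20, and the recovery experiments
use noise SD 0.2 (SNR 5).

Apnea intervals silence the trace to the noise floor; no partial cycles
are emitted, so ground-truth onsets never fall inside an apnea window.
Stimulation windows (`stim_intervals`) can rescale amplitude
(`amplitude_scale_during_stim`), retarget the mean cycle, or inflate
jitter for cycles starting inside them — the knobs needed to express
stimulus-locked respiratory effects (suppressed amplitude, slowed or
irregular rhythm) with exact ground truth.

What the generator does *not* emulate: movement artifacts, sighs,
sniffing bouts, chamber drift, and ECG crosstalk. Passing recovery tests
therefore demonstrates correctness of the estimators under clean breathing
statistics, not robustness to every artifact class of real recordings; the
detector's gating parameters are exposed for that reason.

## Breath-cycle detection

The detector low-pass filters the trace (4th-order zero-phase Butterworth,
10-Hz cutoff — above any murine breathing rate of interest), subtracts a
1-s rolling median to remove baseline drift, and finds inspiratory peaks
with prominence at least `prominence_frac` (default 0.5) times the
interquartile range of the detrended signal, no closer than `min_cycle_s`
(default 0.1 s). Each onset is the **inter-peak trough** — the minimum of
the filtered signal between consecutive accepted peaks — which marks the
foot of the inspiratory limb without assuming waveform shape. On generator
traces at SNR 5 this lands within ~10 ms of the true cycle start; simpler
alternatives (crossing of the rolling median, or a fixed-fraction
threshold) lag the true onset by 20–55 ms, which matters because
recovered onset times feed 30-ms-tolerance matching and cycle-duration
CVs.

After a silent gap (apnea), the inter-peak trough can land on an arbitrary
noise dip inside the gap; onsets whose foot-to-peak rise exceeds 2.5x the
median rise are therefore re-anchored to the last 25%-height crossing
before the peak. Residual boundary fuzz is the detector's temporal
resolution (~30 ms): the first breath after an apnea may be timestamped
marginally inside the apnea bound. The prominence gate is scale-free, so a
recording of pure stationary noise can still yield pseudo-cycles; an
absolute `min_prominence` floor is available when the sensor noise level
is known.

Windowed statistics: frequency is event counting (onsets in window /
window length), not `1/mean duration`, so apnea windows report 0 Hz
rather than being undefined. CV uses the sample SD (n−1 denominator;
per-window cycle counts are small) over complete cycles inside the window
and requires at least three. Window amplitude is the mean peak-to-trough
excursion of detected cycles; in cycle-free (apnea) windows it falls back
to the 95th percentile absolute deviation from the rolling median, which
keeps amplitude-change percentages defined through apnea.

## Arena simulation and activity scoring

The synthetic animal is a soft-edged disk on a uniform background taking
fixed-length steps in random directions on "active" frames (reflected at
walls) and holding position on "frozen" frames; a scripted trajectory can
replace the walk. Rendering contrast and noise are configurable because
the downstream threshold must be tested across contrasts. Not emulated:
body-shape deformation, grooming/rearing (movement without translation),
lighting gradients, shadows and occlusion by cables — so activity
recovery results certify the pipeline arithmetic, not pose-level realism.

The activity pipeline decimates 60-Hz video to 20 Hz by keeping every
third frame (averaging would blur motion and change XOR counts),
binarizes at a configurable gray threshold, and counts nonmatching pixels
between each frame and its one-back frame. "Active time" per block is a
per-frame-pair binarization: pairs whose count exceeds the background
baseline contribute one 50-ms frame period. The continuous alternative
(integrating baseline-subtracted counts) is exposed as a `mean_excess`
column but thresholding is the default, since it yields seconds
commensurable with block durations. The baseline is the 95th percentile
of activity counts from an animal-free or frozen reference segment — a
high quantile of background noise, reproducible and conservative. Frame
pairs are assigned the time of their earlier frame, consistent with
half-open block bounds.

Object-zone masks dilate the object footprint by the 2-cm proximity
criterion (converted through `px_per_cm`). The animal reference point is
the centroid of the largest foreground component; nose direction is not
recoverable from a binary blob, so zone entry is a centroid approximation.
`d2 = (novel − familiar)/(novel + familiar)` is undefined when both
exploration times are zero and raises rather than returning a sentinel.

## catFISH simulation and quantification

The generator places neuronal (~10 µm, diffusely textured DAPI) and
non-neuronal (~5 µm, intensely bright, uniform DAPI) nuclei by dart
throwing with centers at least the sum of radii plus 2 px apart, so each
perinuclear shell is attributable to a single cell. The two per-cell
positivity indicators are drawn from a Gaussian-copula threshold model:
correlation 0 gives independence, 1 forces the positive sets to coincide
when marginals are equal, and intermediate values interpolate smoothly.
Nuclear-positive cells carry signal inside the nucleus; cytoplasmic-
positive cells carry a perinuclear ring. Two assay styles are supported:
cytoplasmic-vs-nuclear signal of one gene in Cy5, or nuclear signal of two
genes in Cy3/Cy5. Single-plane 2-D fields only, matching 10-µm
cryosections imaged at 0.83 µm/px; 3-D stacks and hybridization chemistry
are out of scope.

Segmentation is deliberately standard and replaceable: Gaussian smoothing
(σ = 1 px), Otsu threshold, hole filling, a 3-µm minimum equivalent
diameter, and a distance-transform watershed whose marker separation
scales with the field's 90th-percentile nucleus radius (splitting tangent
nuclei without oversplitting textured ones). All intensity features
(mean DAPI, uniformity = SD/mean) and nuclear compartment measurements
are taken on a 2-px-eroded core of each mask, because the threshold-
dependent boundary band otherwise inflates within-nucleus variation and
lets perinuclear ring signal leak into nuclear calls.

Non-neuron-like nuclei are excluded only when **all three** hold: small
(equivalent diameter < 7 µm), bright (mean DAPI ≥ 2 robust z-scores above
the field median, MAD-scaled), and uniform (core SD/mean ≤ 0.15). The
conjunction errs toward retention: a merely small or merely bright nucleus
stays in.

Shell zones are each retained nucleus's dilation (default 3 px ≈ 2.5 µm,
a perinuclear cytoplasm ring at section scale) minus all nucleus pixels;
competing pixels go to the nucleus with the nearest boundary
(`expand_labels`), so shells are mutually disjoint and never overlap any
nucleus. Nearest-boundary assignment coincides with nearest-centroid for
round nuclei of equal size and behaves better for unequal ones.

A cell is positive in a compartment when the fraction of compartment
pixels above the signal threshold reaches `min_positive_fraction`
(default 0.10). The threshold derives from channel background — pixels
outside all nuclei and shells — as mean + 4 SD after trimming the top 2%
(plain MAD collapses when detector offsets clip background noise at
zero). These defaults were calibrated on generator fixtures, where signal
pixel fractions (≥ 0.85) and noise fractions (≤ 0.10) separate cleanly; on
real data both knobs should be re-examined per batch, and both are
plain parameters.

Chance coexpression is the independence product **on proportions**
(`p_a × p_b / 100`, percent scale). A raw product of counts would carry
cells² units and could not be compared with an observed coexpression
percentage. Section aggregation pools cells across sections by default
(variance-minimal for region estimates from ≥ 3 nonadjacent sections);
per-section averaging is available.

## Cohort simulation and derived endpoints

Per-animal endpoints (CS+ minus CS− summed onset-block active time;
nuclear-minus-cytoplasmic positive-cell percentage) are drawn from a
bivariate normal with a configurable latent correlation (default −0.75,
n = 12 per cohort, active-time change −10 ± 8 s against a 40 ± 6 s CS−
baseline, ensemble change 10 ± 6 points). With n = 12 the sample Pearson r
is slightly biased toward zero (|E[r]| ≈ 0.735 at ρ = −0.75); the
recovery test's ±0.05 band covers this known small-sample bias, which the
package reports as-is rather than correcting.

Onset-block active time per condition is **summed** over a session's four
onset blocks (per-block mean available via `how="mean"`). Group-level
hypothesis testing beyond Pearson r is out of scope by design: the module
emits tidy per-animal tables for any statistics environment.

## Determinism and problem sizes

Every generator consumes a `numpy.random.default_rng(seed)`; the pipeline
derives per-stage seeds from one base seed, logs all parameters to a run
manifest, and produces byte-identical outputs on rerun. The validation
suite and the reproduction script size their experiments to run in a few
minutes on one core — 150-s traces × 50 seeds per jitter level, 20
ten-second videos, 20 fields of 300 neurons, 200 cohorts — sizes at which
the measured tolerances (onset F1 ≥ 0.99, CV error ≤ 0.03, regression
slope within 5%, ensemble percentages within 2 points) are stable across
seeds.
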