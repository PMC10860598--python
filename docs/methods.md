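# Methods

`dsriem` implements, end to end, the analysis of a dual-serial-retrocue
(DSR) visual working-memory fMRI experiment in which two sample items are
defined by a polar-angle **location** (the to-be-reported *content*,
360° space) and a bar **orientation** (the cue-relevant *context*, 180°
space).  Because every stage is exercised on a synthetic generator with
known ground truth, this note states exactly what is modeled, what is
deliberately not, and the numerical choices that matter.

## Trial design

The schedule fully crosses signed inter-item distance in location
(−160°…160° in 40° steps, 9 levels), signed distance in orientation
(−60°, −30°, 0°, 30°, 60°, 90°, 6 levels) and the second cue's status
(stay/switch) — 108 unique trial types; `reps = 3` copies of each give
324 trials shuffled into 27 runs of 12.  Consequences that the tests pin
down exactly: the two samples share an orientation on 1/6 of trials and a
location on 1/9 of trials.

Epoch durations (s): sample 2, delay 1.1 8, cue 1 2, delay 1.2 8,
probe 1 2.5, delay 2.1 1, cue 2 2, delay 2.2 2, probe 2 2.5.  Probe 2's
duration is not independently specified by the task description; it is
set equal to probe 1 (2.5 s), which, with ITIs balanced within each run
(four each of 6/8/10 s) and four discarded 2-s dummy volumes, makes every
run exactly 464 s.  ITI balancing *within* run (rather than free
jittering) is a design choice that buys identical run lengths.

Sample-1 features are drawn uniformly with replacement from the 9/6 base
values; sample 2 adds the cell's signed distance (convention:
sample 2 − sample 1, wrapped to the printed sets).  A shared 0–10°
jitter is added to both locations (not orientations), preserving the
pair's distance while covering the circle.  The first cue's target is
balanced as evenly as a 3-repetition cell allows (2/1 within each cell,
exactly 50/50 over the session); whether the original experiment balanced
this within cells is not stated, so the generator makes the most
constrained choice.

## Channel basis

k idealized channels tile each circular feature axis (9 for location at
20°…340°, 6 for orientation at 15°…165°).  A channel's tuning curve is a
half-wave-rectified sinusoid raised to a power (8 for location, 6 for
orientation).  The argument scaling is chosen so one half-cycle spans the
full feature period — activation `max(0, cos(pi*d/period))^p` for signed
circular offset `d` — the standard convention for inverted encoding
models; the bare "sin^p(x)" notation leaves this scaling open, and no
other scaling makes the tuning curve vanish exactly at half a period.
Rectification precedes exponentiation (irrelevant for even exponents, but
stated).  Channel centers are fixed at the stimulus base values; no
iteration over basis phases.

## Synthetic BOLD generator

Each voxel receives a preferred location and orientation (uniform over
the feature spaces); its weight row over a basis is the basis activation
of that preference plus Gaussian weight noise (sd 0.05).  The per-TR
signal is the linear encoding

    s(tr) = a_PMI(tr)·W·c(PMI) + a_UMI(tr)·W·c(UMI)      (per dimension)
          + baseline + load terms + N(0, noise_sd),

with 12 trial-locked 2-s TRs and additive location/orientation signals
within a voxel (no claim about within-voxel feature interaction is
modeled).  The amplitude profiles play the role of HRF-convolved epoch
gains: both items ramp with the sample response and sustain through the
delays; the unprioritized item is attenuated to 0.4 from TR 8 (cue onset
at TR 6 plus hemodynamic lag).  These default time courses are
illustrative — the true generative amplitudes of real data are unknown —
and every regime-dependent test sets them explicitly.  "Remapping"
replaces the unprioritized item's channel vector by its reflection about
the channel mean (`2·mean − c`), an involution that preserves the mean
response and exactly flips the collapse-and-slope statistic's sign.

Defaults: 500 voxels (matching the GLM-selected ROI size), noise_sd 2,
baseline 100 signal units (so percent signal change has a meaningful
run-mean denominator).  Noise is white over voxels and TRs; no spatial or
temporal autocorrelation, no voxel geometry, no smoothing, no motion.
Passing tests therefore demonstrate estimator correctness under the
linear encoding model, not robustness to realistic fMRI noise structure.

Univariate load: when the two samples differ in a dimension (load-of-2),
that dimension's per-TR load profile is added uniformly over voxels.
The cohort generator draws per-subject load gains g_s ~ N(1, 0.3) and a
behavioral RT load effect ρ·z(g_s) + √(1−ρ²)·ε mapped to milliseconds
(base RT 1000 ms, effect 100 ± 50 ms); ρ defaults to 0.44, the magnitude
implied by a shared-variance r² ≈ 0.19 between neural and behavioral
context-load sensitivity.  Every subject receives an independently
randomized schedule, as in the scanner; a shared schedule would convert
its idiosyncratic label imbalance into a fixed cohort-level bias that the
subject-resampling bootstrap then flags in truly silent conditions.

## Encoding model estimation and inversion

Training solves `What = B1 C1'(C1 C1')^-1`; inversion computes
`C2hat = (What'What)^-1 What' B2` — the closed forms, verified against a
generic least-squares solver to 1e-8 on random instances.  The
raised-power basis is smooth, so these Gram matrices are legitimately
ill-conditioned (~1e10 with few voxels); only condition numbers beyond
1e13 are treated as rank deficiency (e.g., all training trials sharing
one feature), and the error names the offending fold and TR.

Cross-validation leaves one run out, training and testing at the same TR
with prioritized-item labels; each test trial's reconstruction is
recentered by an integer channel shift so the channel nearest the tested
item's feature lands at the 0°-offset position (index 4 of 9 for
location, index 2 of 6 for orientation, so offsets span −160…160 and
−60…90).  Sub-channel jitter is not interpolated.  Reconstructions are
recentered before averaging; for the slope of the mean the two orders are
equivalent.

Per-run z-scoring (and optional polynomial detrending, orders 1–3, for
real data) is an explicit preparation step, not welded into the
cross-validation loop: z-scoring subtracts a per-voxel mean that the
linear identity `B = W C` does not carry through, so exact noise-free
parameter-recovery checks run on raw signal while the analysis default
applies it.

## Slope statistic and inference

Channels are paired by absolute offset, pairs averaged (the unpaired
+90° orientation channel enters singly), and the collapsed values are
regressed on rank ordered *toward* the 0° center — a center-peaked curve
gives a positive slope, a center-inverted one a negative slope.  The
whole statistic is a fixed linear functional of the curve; resampling
loops use that operator form, and a test pins operator and explicit
regression together.

Group inference resamples subjects with replacement (default 10,000
iterations), averages curves, recomputes the slope, and reports
p = 2·min(fraction positive, fraction negative).  An all-zero resampled
distribution reports p = 1 (no evidence); when one sign is entirely
absent the true p is unresolvable at that iteration count and the bound
2/B is reported with a flag.  No continuity correction is applied.  The
paired PMI−UMI contrast bootstraps the per-subject slope differences.
The percentile bootstrap is known to be mildly liberal at small n
(effective two-sided size ≈ 0.067 at n = 24 for normal data, against
nominal 0.05); calibration is asserted in its working regime (n = 100,
size ≈ 0.054).  The sign-flip permutation test (load contrasts) is exact
under a symmetric null and is calibrated at n = 24.  BH-FDR corrects
families of p values; for time courses the default family is the TRs
within one ROI × dimension × item trace, with a config option to pool
across ROIs (the family the original figure legends imply without
enumerating).

The power routine searches the smallest n whose one-sample t test
reaches target power using the exact noncentral-t distribution; the
normal approximation flips the boundary at d = 0.62, α = 0.05 one-tailed,
90% power, where the exact answer is n = 24.

## Model adjudication

The three competing accounts are transcribed as sign tables over
{early visual, IPS} × {content, context} × {PMI, UMI}: *domain-dependent*
(regions follow the feature domain), *functional* (early visual cortex
carries content, IPS carries context) and *hybrid* (domain-dependent plus
IPS encoding context regardless of domain).  Each observed cell is
classified +/0/− at the TR of interest (TR 10, 18–20 s, late first
delay — before the second cue, so stay and switch trials are pooled)
after BH-FDR across the 8 cells, and match counts are reported per model.

## Univariate load analyses

Percent signal change baseline-corrects each trial to its first TR and
divides by the run-mean intensity — recorded in output metadata because
z-scored runs make "percent" ill-defined and real-data users may prefer a
raw-intensity baseline.  GLM voxel selection builds the seven epoch
regressors (impulses and boxcars), convolves them with a canonical
double-gamma HRF (peak 5 s, undershoot 15 s, ratio 1/6) sampled at the
2-s TR, fits per-run OLS with intercept and linear drift, and ranks
voxels by the target regressor's averaged coefficient.  Load contrasts
reduce the 5/4 distance levels to the binary load-of-1 vs load-of-2
comparison (the primary exploratory inference); multi-level
repeated-measures ANOVAs are out of scope.  Delay-period load sensitivity
is the TR 8–10 mean of the load-2 − load-1 PSC difference, correlated
across subjects with the behavioral RT load effect.

## Known estimator properties worth knowing

Two deliberate findings from the integration tests, documented rather
than suppressed:

1. **Load activation is decodable.**  The univariate load term is gated
   by inter-item distance, so it is itself weak location (or orientation)
   information; with it enabled, a multivariately "silent" condition is
   not strictly silent.
2. **Cross-decoding leakage.**  Decoding a silenced item with a model
   trained on the other item's labels carries a small noise-induced bias
   (about 4% of the prioritized slope at noise_sd 1 with 64 voxels;
   absent in noise-free data; unrelated to stimulus jitter).  It arises
   from overfitting to the training labels interacting with recentering
   by the other item's (mostly different) labels.  At any cohort size a
   predicted-null cell can therefore reach bootstrap significance, which
   is why regime-recovery tests assert that the generating model *wins*
   the adjudication rather than matching all 8 cells.

Exact antisymmetry of the two items' slopes under remapping holds when
the training labels are exactly uniform and the inter-item distance
exactly counterbalanced (the contamination is then rank-one along the
constant channel vector, which the slope annihilates); randomized
schedules perturb it at the ~1/√n sampling scale.

## Problem sizes in the test suite

Tests run the full study geometry where it is cheap (design checks, one
27-run subject) and scaled-down cohorts elsewhere, chosen as the smallest
sizes at which the asserted properties are stable: 9-run single-repetition
schedules, 25–100 voxels, cohorts of 3–24 subjects, 200–1000 resampling
iterations, with Monte-Carlo assertions stated in units of their own
standard errors.  The detection-power check calibrates noise_sd through
the full pipeline (grid bracket plus local power-law fit of d(σ)) so the
per-subject slope distribution has d ≈ 0.62 — the smallest predicted
effect the study was powered for — then measures the 24-subject bootstrap
rejection rate over 100 replicate cohorts.

## Limitations

No HRF convolution inside the trial beyond the amplitude profiles; no
anatomical ROIs (ROI labels are generative regimes); no eye movements,
behavioral accuracy models, or probe-response simulation beyond RT load
effects; no ridge or Bayesian IEM variants; real-data ingestion is
limited to the events-TSV + numeric-array path exercised by the staged
CLI.
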