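# Methods

This note documents the models behind `cardiomea`, the parameters that
matter, what the synthetic data do and do not emulate, and the numerical
choices in the analysis chain.

## Recording protocol and geometry

The simulated experiment follows the in-vitro ischemia–reperfusion
protocol: a 20 h normoxic baseline recorded 1 min every hour, then 24 h of
hypoxia and 24 h of reoxygenation recorded 1 min every 30 min. Time is
measured in hours with t = 0 at hypoxia onset; segment start times are
negative during baseline. Analysis periods are half-open intervals on
segment start times: baseline [−20, 0), 7–15 h and 15–24 h hypoxia, 0–6 h
and 6–24 h reoxygenation.

The electrode grid is the commercial 60MEA200 layout: 8×8 positions at
200 µm pitch with the four corners absent (60 electrodes). Beat-rate
scenarios reduce this to 41 analyzed electrodes (the study-scale electrode
count) by dropping trailing row-major positions; layout is irrelevant there
because rate analysis is per-electrode.

**Desk profile.** The default profile samples at 5 kHz with 20 s segments.
At 5 kHz one sample is 0.2 ms, an order of magnitude below every landmark
interval in play, and a full two-day protocol (116 segments × 41
electrodes) simulates and analyzes in under a minute per stage on one
core. The native 25 kHz / 60 s settings are plain configuration
(`SimConfig.sampling_rate_hz`, `segment_length_s`).

## Oxygen model

Culture pO₂ relaxes toward the active gas set-point (19 kPa normoxic,
0 kPa hypoxic) with first-order kinetics, `oxygen_trajectory` being the
piecewise-exponential solution continuous across switches. The time
constant defaults to τ = 4/3 h so the trajectory is within 5 % of the step
span 3τ = 4 h after a switch — the culture "stabilizes within four hours"
in both directions. The simulator emits pO₂ directly; sensor physics and
calibration are out of scope.

## Phase programs

The physiological state is driven by four deterministic multiplier
programs over time — beat rate, depolarization time, FPD and conduction
velocity — each relative to the per-electrode baseline. Programs are built
from per-period targets joined by monotone cubic (smoothstep) transitions
(default window 1 h). Because smoothing a step function perturbs the time
average of short periods, plateau levels are solved from a small
tridiagonal linear system so that the exact time average over every period
equals its target; a trapezoid-integration test holds this to well below
0.1 %.

Rate period targets follow the observed phase response (normalized units):
baseline 1.0, decline to 0.65 over 0–7 h hypoxia (a transition window
excluded from statistics; its level is read from the gradual slowing after
onset), 0.358 at 7–15 h, 0.656 at 15–24 h, overshoot to 1.274 at 0–6 h
reoxygenation, 0.981 at 6–24 h. Landmark folds per timepoint:
depolarization 1.26 / 1.65 / 1.49 at 6.5 / 8 / 24 h hypoxia and
1.15 / 1.52 at 6 / 24 h reoxygenation; FPD 0.75 / 0.87 / 0.96 and
0.92 / 0.97. Conduction-velocity multipliers are the reciprocal of the
per-timepoint lag targets (0.45 / 0.72 / 0.86 / 0.71 / 0.56 ms), since for
a planar wave lag ∝ 1/velocity.

## Waveform and beat trains

One field potential is three Gaussian components on a flat baseline: P1
(+200 µV, σ 1.5 ms), P2 (−150 µV, same width) at the depolarization-time
offset (baseline 8 ms), and a +30 µV, σ 40 ms repolarization bump at the
FPD offset (baseline 350 ms). Component widths are small relative to the
landmark intervals, so rendered extrema sit at the programmed offsets and
serve as exact ground truth. Amplitudes and intervals are free parameters;
the defaults are plausible extracellular values and nothing downstream
depends on their absolute scale.

Per-electrode baseline rates are log-normal around 42 BPM with 20 %
relative SD (electrodes over a sheet report different local rates). Within
a segment the instantaneous rate is constant (programs vary on the hour
scale, segments last seconds), so beats are periodic with a shared random
phase per segment; a 250 ms refractory floor (≈240 BPM) raises an error if
a configured rate would violate it. Gaussian draws feeding rates are
clipped at ~3σ to keep extreme tails physiological.

**Baseline rate variability.** Spontaneous baseline beating is irregular
and right-skewed: per segment, each electrode's rate is multiplied by a
log-normal fluctuation with median 1 and log-SD σ_b = √(2 ln 1.081) ≈ 0.395
during the baseline window. Median-normalization is exactly invariant to
the location of this fluctuation, but its skew makes the *mean* normalized
baseline ≈ e^(σ_b²/2) = 1.081 — reproducing the hallmark that the mean of
median-normalized baseline rates sits above 1. After hypoxia onset the
per-segment fluctuation is mild and mean-one (log-SD 0.08), so recovered
period means track the programmed targets directly. This phase split is a
modelling choice: a single phase-independent skewed noise would inflate
every period mean by the same factor and is incompatible with the observed
pattern (baseline mean ≈ 1.08 together with post-onset means at their
period values).

**Propagation.** Activation spreads as a planar wave from a pacemaker
corner (default (0,0); the wavefront normal points into the array, i.e.
along the grid diagonal), delaying each electrode by its projected distance
divided by velocity, plus per-beat Gaussian timing jitter (0.1 ms SD). With
the diagonal direction every 4-neighbour pair has the same ground-truth lag
pitch/(√2 v); `cv_for_mean_lag` calibrates v so that lag equals a target
(0.45 ms baseline → v ≈ 0.314 m/s, within the range reported for hiPSC-CM
sheets). Conduction scenarios set the rate spread and rate noise to zero so
the sheet beats coherently — a rate-heterogeneous sheet would not carry a
single wave; the beat-rate scenario conversely uses per-electrode
variability and does not analyze conduction.

Determinism: all randomness descends from `SimConfig.seed` through a
`SeedSequence` tree (one child per segment); equal configs give
bit-identical traces, and HDF5 datasets are written with
`track_times=False` so files are byte-identical too.

## Detection and landmarks

Detection band-passes at 10–2000 Hz (2nd-order Butterworth, zero-phase),
estimates the noise SD robustly as MAD/0.6745 of the filtered trace and
thresholds |signal| at 6 noise SDs, with a floor of 0.2× the largest
deflection so that near-noiseless traces do not trigger on filter ripple;
peaks closer than the refractory bound are suppressed (largest wins). A
silent trace yields zero beats; an all-NaN trace is an error.

Landmarks are read from the raw trace. P1/P2 timing uses slight Gaussian
pre-smoothing at the spike-width scale (σ 1 ms) — symmetric, so peak
positions are preserved — followed by 3-point parabolic refinement; this
brings P1 timing noise to ~0.03 ms at 10 µV noise, an order of magnitude
below the sample period requirement of conduction mapping. P2 is the
largest opposite-signed extremum within 80 ms of P1. The flat peak is
located on a 20 ms moving-average trace within [80, 600] ms after P1 and
refined with a least-squares parabola over ±45 ms: the repolarization bump
is wide and low-curvature, and a 3-point vertex there is noise-limited
(~5 ms SD) where the wide fit achieves ~1.5 ms. A flat peak below 5 µV, or
a window leaving the trace, marks FPD missing for that beat (excluded from
summaries, never imputed).

Beat frequency is interval-based when ≥2 beats are present
(60 × n_intervals / span), which is robust to edge truncation of short
segments; otherwise 60 × count / segment length. Electrodes enter the
normalized analysis when ≥50 % of their baseline segments carry ≥10
detected beats and ≥3 baseline segments have nonzero rate; exclusions are
reported so included + excluded = total.

## Conduction analysis

Beats are matched across electrodes by nearest-neighbour association
within a 50 ms coincidence window around the beats of the
most-active reference electrode; beats matched on fewer than 30 electrodes
are skipped. Lags are absolute activation-time differences over present
4-neighbour pairs, pooled over pairs and beats per timepoint (a single
positive mean per timepoint; the large SD relative to the mean in
such pooled statistics is why direction is not retained). Timepoint
segments are placed on program plateaus, clear of the 1 h smoothing
windows around period boundaries. Rectified noise biases a pooled |lag|
mean upward once per-measurement noise approaches the true lag; with the
0.1 ms jitter plus ~0.03 ms P1 noise against a 0.45 ms baseline lag the
bias is below 1 %.

## Imaging

The nucleus generator renders elliptical nuclei with log-normal areas
(control mean 35.7 µm², SD 16.4) at random orientation and aspect 0.7–1.0,
slightly blurred (σ 2 px) with additive noise; exact areas πab are carried
as ground truth. Each nucleus keeps its drawn size while retrying random
positions, and centers are drawn inside the admissible non-border region —
both choices prevent crowding and border margins from selecting against
large nuclei, which would bias the population mean. A configurable clump
fraction places partners in contact to exercise declumping.

Segmentation follows the stated recipe: global two-class Otsu on a 256-bin
min–max-normalized histogram, hole filling, distance-transform watershed
seeded by smoothed-distance peaks (shape-based declumping), equivalent-
diameter gates 50–250 px, border-object removal, and accounting such that
detected = kept + size-filtered + border-filtered.

**Pixel calibration.** The size gates are specified in pixels but areas
are reported in µm², so the pixel size fixes which physical areas survive.
The default is 0.05 µm/px: for populations with 22–36 µm² mean area to
pass the 50 px minimum diameter essentially intact, the gate must sit below the
populations' lower percentiles, which requires a scale near this value. At
0.16 µm/px the minimum gate would discard the entire control population;
at 0.08 µm/px it would still clip ~23 % of a 22.3 µm² hypoxic population
and bias its measured mean upward by ~15 %. Both the gate values and the
calibration are configurable.

Coverage images carry a blobby cell mask and a positive sub-region grown
to an exact target fraction, textured with oriented sinusoidal striations.
Coverage is 100 × |positive ∩ cell| / |cell| (enforced intersection; an
empty cell mask yields 0, flagged). Tests and recovery studies use
ground-truth masks; for real images a texture-energy threshold
(difference-of-Gaussians band-pass at the striation frequency, local
energy, Otsu) is offered as a documented substitute for the original
manual wand-tool masks — a methodological substitution, flagged as such.

## Statistics and qPCR

Rank tests are two-sided and exact at small n by full enumeration — all
C(n_x+n_y, n_x) labelings for Mann–Whitney (combined n ≤ 12, no ties), all
2^n sign assignments for Wilcoxon (n ≤ 15, no tied |d|), with two-sided
p = min(1, 2·min(P(T ≤ t), P(T ≥ t))). The thresholds keep enumeration
sub-second. Beyond them, or with ties, a tie-corrected normal
approximation with continuity correction applies (midranks throughout;
zero differences dropped for Wilcoxon; an all-zero difference set is
degenerate with p = 1). No multiple-testing correction is applied — raw p
values are reported.

ΔΔCt: technical replicates averaged per (sample, gene); reference Ct is
the arithmetic mean of the per-gene means over the housekeeping panel
(equivalent to a geometric mean at expression level); ΔCt is calibrated
against the mean ΔCt of the control group; fold = 2^−ΔΔCt with assay
efficiency fixed at 2.0. Samples lacking the target or all references are
excluded and reported. Folds are invariant to any constant shift of all
Cts (RNA input), which the generator exploits by giving each sample a
common offset.

The Ct generator programs true group folds on the ΔCt scale
(ΔCt = 8 − log₂ fold for the target against an 18/26/20-cycle housekeeping
panel), with 0.2-cycle inter-sample and 0.1-cycle replicate noise. These
spreads emulate technical variability only; the much larger group SDs of
real batches (differentiation-batch effects) are deliberately not
emulated, so recovered group means are tight around the programmed folds.

## What the synthetic data do not show

The simulator is phenomenological: no ionic or monodomain model, no
arrhythmia, reentry or spiral waves, no drift, electrode dropout or
movement artefacts; waveform shape is stylized and noise is white. Planar
propagation with a fixed pacemaker is the only activation pattern.
Baseline irregularity is a per-segment multiplier, not beat-to-beat heart
rate variability. Imaging omits uneven illumination, out-of-focus nuclei
and dense tissue-like clumping; the coverage generator's between-image SD
(10 abs %) is deliberately smaller than real morphology spread. Passing
parameter recovery therefore demonstrates that the analysis chain is
unbiased and correctly calibrated under its stated assumptions — not that
it is robust to every failure mode of real recordings.

## Problem sizes

Recovery studies run at: 41 electrodes × 116 segments (beat rate), 3
samples × 19/4/13/17/14 beats per timepoint (landmarks), 60 electrodes ×
10 segments (conduction, ~2800 pooled lags per timepoint), 124 coverage
images and ~530 segmented nuclei over 18 images (morphometry), 6 + 5
samples × 4 genes × 3 replicates (qPCR). The full suite plus the
acceptance script completes in a few minutes on one core.
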