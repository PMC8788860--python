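# Methods

## Scientific setting

`wdi` analyzes layer 2/3 calcium signals recorded in primary whisker
somatosensory cortex (wS1) while a head-fixed mouse performs a
whisker/auditory go/no-go detection task. Neurons are labeled by their
projection target — S2p (projecting to secondary somatosensory cortex,
wS2) or M1p (projecting to whisker motor cortex, wM1) — and the analyses
compare these two populations: stimulus-evoked response amplitudes in
defined post-stimulus epochs, activity around spontaneous (false-alarm)
licks, day-to-day response stability, and pairwise correlations of
spontaneous activity.

## Behavioral model

A trial is a stimulus (whisker deflection, auditory tone, or nothing on
catch trials) at a known time, preceded by a 3 s quiet window and
followed by a 1 s reward window. Classification is rule-exact:

- any lick in `[t_stim − 3 s, t_stim)` → trial aborted;
- otherwise a lick in `(t_stim, t_stim + 1 s]` makes a stimulus trial a
  hit (WHIT/AHIT) and a catch trial a false alarm (FA);
- otherwise the trial is a miss (WMISS/AMISS) or a correct rejection (CR).

The reward window is half-open on the left because a lick exactly at
stimulus onset cannot be stimulus-driven. Catch trials carry a virtual
stimulus time against which FA licks and FA reaction times are scored.
Aborted trials are excluded from every rate denominator and from all
neural analyses. Hit rate = 100·hits/(hits+misses) per modality; FA rate
= 100·FA/(FA+CR); an empty denominator yields "undefined", never 0.

## Imaging preprocessing

Pixel coordinates are 0-based `(row, col)`, origin top-left; shifts are
`(Δrow, Δcol)` displacements of a frame relative to its reference.

- **Background subtraction**: the scalar minimum over all pixels and
  frames of each trial's video segment is subtracted per segment
  (idempotent; each segment's minimum becomes exactly 0).
- **Motion correction**: per-frame rigid translation estimated by
  subpixel Fourier cross-correlation (default 1/10 px, 1/20 px in the
  recovery checks) against a reference image (default: mean of the
  first 300 frames), then undone by interpolation (linear by default,
  order configurable). Border pixels exposed by the shift are filled
  with 0, the post-subtraction background. Flat frames yield zero shift
  with a warning.
- **Session-to-master registration**: a full affine transform
  (translation, rotation, isotropic scale, shear) is estimated by
  maximizing normalized cross-correlation with Powell's method, seeded
  by a phase-correlation translation estimate and refined over a
  2-level multi-resolution pyramid. Registration failing a minimum
  correlation (default 0.5) raises with diagnostics rather than
  returning a bad transform. ROI masks move across sessions by
  nearest-neighbour resampling through the stored transform; masks that
  leave the frame are flagged `lost`, never dropped.

Interpolation order and the optimizer are configurable because the
subpixel resampling scheme is a numerical choice, not part of the
analysis definition.

## Trace extraction and ΔF/F

Somatic fluorescence is the per-frame mean over the ROI pixels. The
neuropil signal is measured in a 40 µm-radius disk around the ROI
centroid, excluding the pixels of **all** detected ROIs (an optional
inner exclusion margin is available; default 0). Correction:

    F_corrected = F_soma − a·(F_neuropil − median(F_neuropil)),  a = 0.7

with the median over the whole gap-free session — a deliberate choice
over per-trial medians, since the acquisition is continuous and the
contamination coefficient is a single session constant. ΔF/F =
(F − F0)/F0 with F0 the mean corrected fluorescence over the 60 frames
(2 s at 30 Hz) before each trial's (virtual) stimulus frame; the
stimulus frame is `floor(t_stim·30)` under the convention that frame k
covers `[k/30, (k+1)/30)` s. Trials with F0 ≤ 0 are flagged invalid and
excluded (no clipping — a sign-flipped ΔF/F is worse than a dropped
trial).

## Event analysis

Stimulus-aligned responses are averaged across trials of a type first;
epoch values are means of that averaged trace over half-open ms windows
mapped to frames by frame start time: early [33, 233) ms = frames 1–6,
late [233, 1000) ms = frames 7–29, very late [1000, 3600) ms = frames
30–107 at 30 Hz. The stimulus frame itself (frame 0) belongs to no
epoch. The peak is the maximum of the trial-averaged trace over
(0, 1000] ms (frames 1–30); a per-trial-peak-then-average alternative
sits behind a flag. Epochs without full post-event coverage are
undefined (`None`), never 0.

Lick-triggered analysis aligns ΔF/F to the first in-window lick of each
false-alarm trial and averages; `pre` (100–33 ms before the lick) and
`post` (33–167 ms after) are reported relative to a 1200–466 ms
pre-lick baseline window. Re-baselining uses this explicit window (not
the trial F0) by default.

## Population analysis

Pairwise coupling is computed on correct-rejection trials only (no
stimulus, no lick): per ROI the CR segments are concatenated, the ROI's
mean over the concatenation subtracted, and the cross-correlogram
computed per pair over ±30 frames. The default normalization ("coeff")
makes each trace's zero-lag autocorrelation 1, so zero-lag values are
correlation coefficients; the raw sliding dot product ("none") is
available for strict comparison with MATLAB `xcorr`'s default. Sign
convention: for `y[t] = x[t−d]` the correlogram of (x, y) peaks at lag
+d. Pair classes are unordered (S2p–S2p, S2p–M1p, M1p–M1p); group
summaries pool either all pairs or per-mouse means.

Cross-day stability is the OLS fit of day-j whisker-hit peak responses
on day-i, summarized by slope, intercept and R² = 1 − SS_res/SS_tot.

Group tests: Wilcoxon rank-sum for unpaired per-neuron comparisons,
Wilcoxon signed-rank for paired per-mouse comparisons (exact null at
n ≤ 25 without ties, so n = 6 all-positive differences gives exactly
p = 0.03125 two-sided). No multiple-testing correction is applied;
p-values are reported raw, and the test metadata records whether the
exact or asymptotic regime was used.

## Synthetic sessions

The generator produces the statistical structure each stage is designed
to recover, with one global integer seed driving a single `numpy`
Generator so sessions are bit-reproducible.

**Behavior.** Stimulus times at uniform 11–14 s inter-stimulus
intervals; 35% catch trials, remaining trials split evenly between
whisker and auditory. Hit probabilities default to expert-level
performance (whisker 0.81, auditory 0.77, FA 0.046), reaction times are
Gaussian per modality (whisker 240 ± 74 ms, auditory 195 ± 56 ms, FA
537 ± 75 ms) truncated to the reward window, and a low-rate Poisson
process of spontaneous licks (0.01 Hz) produces occasional quiet-window
aborts.

**Fluorescence.** Events drive a causal difference-of-exponentials
GCaMP6f-like kernel (rise 50 ms, decay 400 ms — typical literature
values, configurable), peak-normalized so amplitudes are peak ΔF/F.
Class structure: evoked amplitude 0.15 (S2p) vs 0.05 (M1p) on whisker
hits, scaled per outcome (miss 0.5×, auditory 0.6×, auditory miss
0.3×), with per-neuron lognormal gain variability (CV 0.25). The
amplitudes are free parameters of the simulation, not calibrated to any
dataset. S2p cells ramp linearly over the 500 ms before the first lick
of hit/FA trials (0.2 ΔF/F·s⁻¹), then decay with the kernel constant.

**Correlation structure.** A slow shared input (AR(1), τ = 0.3 s, unit
variance) is added with weight 0.033 to S2p cells and 0.01 to M1p
cells, plus independent white noise (sd 0.05). The expected zero-lag
correlation is w²/(w² + σ²) within a class (≈0.30 for S2p, ≈0.04 for
M1p) and the geometric mean of the two across classes — so the strict
ordering S2p–S2p > S2p–M1p > M1p–M1p holds in expectation. The M1p
weight is deliberately small-but-nonzero: with exactly zero, the
cross-class and within-M1p means are both zero in expectation and their
ordering would be a coin flip, contrary to the weak-but-real M1p–M1p
coupling the analysis is meant to resolve. Tests that need fully
independent M1p noise set the weight to zero explicitly.

**Movies.** ROIs are disjoint disks (radius 3 px) on a grid in a
128 × 128 field of view (a desk-scale stand-in for 512 × 512
acquisition, which is supported but not default). Each frame is a
static textured baseline plus soma brightness modulated by each cell's
trace, plus a spatially uniform slow neuropil signal scaled by
`neuropil_gain` (default 0.7) added everywhere — including over somata,
which is what makes neuropil correction recoverable. Frames are rigidly
shifted by i.i.d. Gaussian displacements (sd `motion_sd_px`) with
linear interpolation and optional Poisson shot noise; the stochastic
part of the neuropil signal scales with `noise_sd` so a noise-free
render is exactly time-invariant.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: optics (PSF, depth-dependent blur),
non-rigid tissue deformation, z-drift, slow photobleaching, correlated
shot noise, overlapping somata, spike-history-dependent indicator
nonlinearity, and any calibration of amplitudes or correlations to the
real dataset. Recovery results demonstrate the correctness of the
pipeline's arithmetic and inference under its stated assumptions, not
the biological effect sizes.

## Problem sizes and numerical choices

Default synthetic scale is 6 mice × 3 days × 600 s sessions with 30+30
neurons per mouse (≈45 trials/session); the class-effect recovery
checks use single 2 300 s sessions so that ≥50 whisker-hit trials are
available, and movie-level round trips use 300 frames at 128 × 128.
These sizes keep a full run on one CPU in the tens of seconds while
leaving every statistical check well-powered.

Degenerate inputs are contracts, not silent fallbacks: empty trial
segments, empty neuropil rings, rings smaller than the soma,
zero-variance reference days, non-contiguous particle blocks and
mismatched trace lengths all raise; zero-variance traces in the
correlation analysis flag the affected pairs as invalid NaN entries.

## Known limitations

- The deposit loader expects the documented per-session
  `trials.csv` + `traces.h5` layout and will need adapter code on first
  contact with an arbitrarily structured external deposit.
- Affine registration assumes a dominant overlap between fields of view
  and an intensity relationship well captured by normalized
  cross-correlation; it is not a landmark or feature-based method.
- Motion correction is strictly rigid 2-D translation; rotational or
  non-rigid motion leaks into the residual.
- Stability R² on synthetic data is noise-limited by the small number
  of hit trials per session and is not tuned to reproduce any specific
  empirical value.
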