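# Methods

## Analysis model

The pipeline treats a study as n subjects, each with a continuous
multichannel recording (four region-level neural traces M1/S1 × left/right
hemisphere, one lead-II-style ECG, two EMG channels) and a cue table
(onset, cued side, task).  All event times are seconds from recording
start; trial time is seconds relative to the cue; every interval is
half-open.

**Cardiac delineation.**  The ECG is band-passed 0.2–40 Hz with a
symmetric (Type-I) FIR filter applied centred, which is exactly zero-phase;
the filter length is 8 s of taps (capped at a third of the signal), and the
signal is reflect-padded so the edges carry no DC transient.  R-peaks are
local maxima above half the 99.8th-percentile excursion with a 250 ms
refractory period; polarity is resolved automatically by comparing the
largest positive and negative excursions.  T-wave offsets use the tangent
rule: within (R + 150 ms, R + 0.6·IBI), the tangent at the steepest point
of the descending T limb is extrapolated to the local baseline.  Beats
without a detectable T wave are flagged NaN and their cues excluded —
flag-and-exclude, never interpolate.  On noise-free synthetic ECG the
detector recovers R times within ±1 sample and T offsets within ~2 ms
(tolerance asserted: 15 ms).

**Phase and angle.**  Systole is [R, T_off), diastole [T_off, next R); the
half-open convention makes boundary cues deterministic (a cue exactly at
the T offset is diastole, exactly at R is systole).  The cycle angle is
θ = 2π(C − R)/IBI wrapped to [0, 2π), with IBI the mean of up to four
preceding R-R intervals; with fewer preceding intervals the available ones
are averaged (the four-beat averaging is a robustness device, not a hard
requirement), and angles exceeding 2π (a cue late in an unusually long
beat) are wrapped because the Rayleigh test needs angles on the circle.
Wrapping means the angle/phase correspondence (θ inside the systolic arc ⇔
systole label) holds only for latencies below the averaged IBI; tests
exclude wrapped cues from that consistency check.

**Artifact regression.**  The cardiac-field artifact is removed per neural
channel by OLS of the channel on the concurrent ECG plus intercept, pooled
over all samples (per-epoch mode available).  Pooling gives a stabler slope
when the artifact gain is constant across the session, which is how the
leakage is modelled.  The operation is idempotent and a no-op at zero gain.

**Time–frequency.**  Epochs span −1 to 4 s; 5-cycle complex Morlet wavelets
at integer frequencies 8–30 Hz (via MNE's `tfr_array_morlet`); power is
z-scored to the −0.5..0 s pre-cue baseline and averaged into alpha
(8–13 Hz, 6 bins) and beta (14–30 Hz, 17 bins).  Baseline statistics are
per-trial by default, with a trial-pooled mode behind a flag.  Per-trial
z-scoring of chi-square-distributed power carries a small positive offset
on stationary data (the baseline SD estimate correlates with the baseline
mean when the baseline holds only a handful of independent wavelet
samples); the offset is common to both hemispheres and cancels exactly in
the paired ipsi-vs-contra contrasts that all inference uses, so the
default is kept.  The first and last 0.3 s of each epoch are excluded from
statistics to avoid wavelet edge effects; the analysis window is
0.5–2.0 s post-cue (primary) or 0.5–4.0 s (exploratory), both inside the
guard band.

**EMG.**  The 10 Hz filter is a zero-phase 4th-order Butterworth
*high*-pass — at 10 Hz a low-pass would delete the surface-EMG band, while
a high-pass removes motion artifact and drift, which is what a 10 Hz
cutoff is for in EMG practice.  Envelopes are |x| smoothed by a 100 ms
moving RMS (hop 1 sample; window configurable).

**Group statistics.**  Paired condition differences (one trace per
subject) are tested per time point with a sign-flip permutation null:
each permutation flips each subject's whole difference trace with
probability ½, so the null preserves the temporal autocorrelation and the
pairing.  The statistic is the group mean difference (a t-statistic is
available; the mean is the default because the permutation already
studentizes implicitly).  Two-tailed p-values use the add-one convention,
bounding p at 1/(n_perm+1).  Across time points the FDR is controlled at
q = 0.05 by the two-stage adaptive linear step-up (first pass at
q/(1+q) estimates the true-null count m0 = m − r1; second pass at
q/(1+q)·m/m0); the implementation is ~20 lines and is cross-checked in the
tests against both a brute-force re-derivation and statsmodels'
`fdr_tsbh`.  Δ_dep, the probability of superiority for dependent samples,
is (#{x>y} + ½#{x=y})/n computed on subject values averaged over the
significant window.  Control runs resample systole and diastole trials
with replacement to equal per-subject counts (10 runs) and repeat every
test.

**Circular analysis.**  The suppression index is the per-trial mean over a
significant window of (z_ipsi − z_contra); the window is the longest
significant run of the all-trials laterality contrast (chosen independent
of cardiac phase to avoid circularity), falling back to the full analysis
window, with the fallback logged.  Per subject, trials above the 50/75/90th
percentile of the index enter a Rayleigh test; subjects with fewer than 3
usable angles are dropped with a log entry.  The group test applies the
Rayleigh test to the subject mean directions as unit vectors (a weighted
mode scaling by each subject's R̄ exists); this second-order test discards
subject-level concentration by construction — documented, not "fixed".
P-values use P = exp(√(1+4n+4(n²−R²)) − (1+2n)) with R = nR̄; results
always report R̄, Z = nR̄² and p side by side, because the literature
sometimes prints R̄ under the name "Z".  The Monte-Carlo null redraws
uniform angles per trial and subject (1000 permutations) and recomputes the
group Z, giving an empirical add-one p.  The overlap summary intersects the
diastole-cued significant laterality window with each diastole cue's next
systolic interval, cue-relative, and averages per subject.

## Synthetic data: what it emulates and what it does not

Each beat is a sum of Gaussian bumps (P, Q, R, S, T; R dominant) placed at
R times with truncated-normal IBIs (mean 0.9 s, SD 0.05 s, ±3 SD — the
source experiment reports no numeric IBI summary, so these are realistic
resting values, exposed in the config).  The T-wave offset of beat k is
*defined* as R_k + systole_fraction·IBI_k (default fraction 0.35, giving a
315 ms mean systole, inside the 243–546 ms range seen across
participants); the T bump's peak sits two T-widths earlier so that the
tangent rule recovers the programmed offset exactly on clean data.  Cue
onsets are jittered ±0.25 s around an 8 s trial grid so cue phase is
effectively uniform on the cardiac cycle and cannot lock to the heartbeat.
Neural channels are alpha+beta oscillators whose amplitude drops by a
programmed depth inside the 0.4–2.5 s post-cue window (contralateral depth
0.5 for diastole-cued trials, 0.2 for systole-cued; ipsilateral 0.2 —
i.e. laterality only for diastole cues), plus 1/f pink noise and a
cardiac-field artifact equal to artifact_gain × ECG.  EMG channels are
noise carriers amplitude-modulated by a post-cue burst with ipsilateral
gain 3 vs contralateral 1, multiplied by 1.5 when the cue is in diastole.
Every channel has its own generator substream derived from the master
seed; identical seeds give bit-identical sessions.

Not emulated: scalp topographies and volume conduction (the generator
emits region-level traces directly), respiratory or movement artifacts,
non-stationary heart rate, inter-trial variability of desynchronization
depth beyond the phase dependence, and realistic EMG spectra.  Passing
tests therefore demonstrate that the *pipeline* recovers known structure
through the full detection → labelling → spectral → inference chain; they
do not certify performance on recordings with artifacts the generator
lacks.

## Problem sizes and numerical choices

Test and verification studies are scaled down from a full experiment
(29 subjects, 100+100 imagery trials, 1024 Hz) to 6–7 subjects, 15–30
trials per side, 250 Hz — sizes at which the programmed effects are still
unambiguous.  250 Hz comfortably carries the 40 Hz ECG edge and the EMG
band, and matches common post-decimation rates for band-power analysis
below 30 Hz.  A floor of 7 subjects applies to recovery runs: with n
subjects the sign-flip null has only 2ⁿ distinct patterns, and below 7 the
smallest attainable p-value is too coarse to clear the FDR threshold
reliably — a property of paired permutation tests at tiny n, not of this
implementation.  "Sustained" significance in recovery checks means a
contiguous significant run of at least 0.5 s.

Degenerate inputs are contracts, not crashes: flat ECG, zero-variance
baselines, empty suppression windows, cues outside beat coverage, and
missing T waves all either raise with a diagnostic or flag-and-exclude
with a log entry, as documented per function.

## Known limitations

- The T-offset tangent rule assumes a single-lobed T wave; biphasic T
  waves would be flagged missing rather than delineated.
- The second-order group Rayleigh test ignores per-subject concentration;
  the Monte-Carlo null compensates for its anticonservative tendencies at
  small subject counts but cannot restore the discarded information.
- Regression-based artifact removal assumes a session-constant leakage
  gain; pulse-amplitude drift would leave a residual.
- Sessions are persisted as an NPZ + TSV + JSON container rather than EDF;
  readers for EDF can be slotted in where a deployment needs them.
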