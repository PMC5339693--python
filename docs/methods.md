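# Methods

`drowsikit` analyzes synchronized EEG/EOG/ECG + continuous-wave NIRS
recordings from simulated driving sessions in which a subject drifts from
wakefulness into drowsiness. This note documents the models, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical choices a maintainer would want to know about.

## Signal model and pipeline

**Preprocessing.** All electrophysiological streams pass a zero-phase
quality-factor-30 IIR notch at 60 Hz; EEG is band-passed 1–50 Hz and NIRS
low-passed at 0.2 Hz with zero-phase 4th-order Butterworth filters. EOG and
ECG are linearly detrended. Zero-phase filtering is used because every
feature window is aligned to behavioral events (eye closures), so group
delay would bias lead-time estimates.

The notch is applied with autoregressive-continuation padding (2 s per
side, AR order 40 fitted on the adjacent samples) rather than reflection
padding. Reflection puts a derivative kink exactly at the signal boundary;
a high-Q notch rings at its own pole frequency (≈ the notch frequency)
right where the data start, leaving a percent-level 60 Hz residual at the
edges. AR continuation extends a sinusoid exactly, so the transient dies
inside the pad; an unstable AR fit falls back to odd reflection.

Artifact handling replaces manual ICA component inspection with an
automated criterion: FastICA (seeded, hence reproducible) decomposes the
EEG, and components whose absolute Pearson correlation with either EOG
channel exceeds 0.6 are zeroed before re-mixing. The threshold is exposed;
0.6 separates clear ocular components from neural ones on the synthetic
fixtures with a wide margin. ICA is optional in the end-to-end driver
because it dominates runtime on long 64-channel recordings and the
downstream features (frontal beta RPL, channel-averaged HbO) are only
marginally affected by the ocular bleed; it is validated on dedicated
fixtures with a known mixing vector.

**Spectral features.** Band power is a Welch estimate — 2 s Hann segments,
50 % overlap — summed over the band's bins with the half-open convention
`lo ≤ f < hi`, so delta (1–4), theta (4–8), alpha (8–13), beta (13–30) and
gamma (30–50 Hz) exactly tile 1–50 Hz. 2 s segments give 0.5 Hz
resolution, which keeps the Hann leakage of a component at least 1 Hz
inside a band within that band (at 1 Hz resolution a 3 Hz tone loses a
sixth of its power across the 4 Hz edge, breaking Parseval agreement at
the 5 % level). On the 2 s sliding window the estimator degrades to a
single Hann periodogram; the resulting per-sample noise on the frontal
beta RPL (17 channels averaged) is ≈ 4–7 % relative, which is the scale
against which the detection rule's "continuous decrease" runs must be
read. The relative power level (RPL) of a band is its group-averaged power
divided by the five-band total: rows sum to one and are invariant to
amplitude rescaling.

**Hemodynamics.** Each NIRS channel is expressed relative to its own mean
over the first 10 s of the recording, then averaged over the (non-excluded)
channels and block-averaged to 1 Hz (non-overlapping 10-sample means,
stamped at the block's left edge). The sliding beta RPL (2 s window, 1 s
step, stamped at window centers) lands on the same integer-second grid, so
the two 1 Hz series align exactly.

**State identification.** Five per-minute parameters are computed: EOG
blink count, ≥ 2 s eye-closure count (from annotations — mirroring
video-based scoring, never inferred from EOG), ECG R-peak count, occipital
alpha power (10 channels) and frontal beta power (17 channels). Peak
counting smooths the trace with a moving average (0.1 s for blinks, 30 ms
for R-peaks) before prominence-thresholded picking (3 robust SDs of the
raw trace, refractory 200/300 ms); without smoothing, wideband noise
produces spurious high-prominence maxima. A minute is *drowsy* iff it
contains an eye closure and its beta power is below the awake reference
(median of the first five minutes); *awake* iff it has no closure and beta
is within 20 % of the reference; otherwise *undetermined*. The 20 %
tolerance absorbs normal minute-to-minute beta fluctuation, which would
otherwise break awake runs roughly one minute in five. Blink rate, heart
rate and alpha are recorded as corroborating flags only. The analysis
segments are the earliest runs of five consecutive awake and five
consecutive drowsy minutes; a missing run excludes the subject.

**Classification.** Each 5-minute window yields 60 disjoint 5 s trials; a
trial's feature vector is its five consecutive 1 Hz samples (frontal beta
RPL or channel-averaged HbO), keeping within-trial dynamics. FLDA is the
two-class closed form w ∝ S_w⁻¹(μ₁ − μ₂) with the pooled within-class
scatter ridge-regularized by 1e-6 · trace(S_w)/d; the bias is the midpoint
of the projected class means, the sign is fixed so drowsy projects
negative, and a score of exactly zero classifies as awake.
Cross-validation shuffles the 120 trials into 10 class-stratified groups
of 12 (6 + 6 — unstratified groups can produce single-class training
folds), trains on 7 and tests on 3, and repeats 120 times with fresh
shuffles. Fusion is score stacking: a second FLDA on the 2-D vector of
per-modality continuous discriminant scores, under the identical group
partitions. Continuous scores (not hard labels) feed stage 2 because hard
labels make the stage-2 scatter degenerate; when both modalities carry
identical features, the stage-1 scores are symmetric about zero and
stacking reproduces the single-modality decisions exactly.

**Detection.** On the aligned 1 Hz series, the drowsiness detection index
is `DDI = 1` iff `ΔHbO_v > 0.05 mM/DPF` **and** `%Δbeta > 20 %`, where
`ΔHbO_v` is the rise of HbO above its running reference (tracks the
current value while HbO is non-increasing, freezes at the preceding local
minimum during a continuous strict increase) and `%Δbeta` is the drop of
beta RPL below the mirror-image running maximum. A zero first difference
counts as "not increasing", so flat segments never hold a stale reference.
Both thresholds are configuration, not constants. The index is not
latched; repeated detections are possible. Evaluation against the first
≥ 2 s eye closure: the detection is the first rising edge after the awake
reference window and at or before the closure; edges strictly inside the
awake window are recorded as awake false triggers (the field sometimes
calls these "false negatives" — misreading awake as drowsy — and that
alias is kept); no qualifying edge is a miss. Lead time is closure minus
detection. Raising either threshold can only remove detections.

## The synthetic cohort

The generator emulates a 30-minute session per subject. Defaults are the
study conditions: drowsy onset on an integer minute drawn uniformly from
12–25, a transition window of 10–50 s ending at the first eye closure,
awake/drowsy HbO state means +0.019/−0.017 mM/DPF (Hb −0.003/+0.005), an
HbO transition surge of 0.10 mM/DPF, a frontal beta-RPL drop of 38 %, and
awake/drowsy band-weight profiles (0.22, 0.18, 0.20, 0.30, 0.10) →
(0.29, 0.23, 0.225, 0.18, 0.075). Blink rates (18/8 per minute) and heart
rates (72/62 bpm) are plausible placeholders — the source material reports
no magnitudes — and are consumed only as event counts.

EEG is a per-channel sum of band-limited Gaussian noise (4th-order
Butterworth bands) mixed by state-dependent power weights, scaled to
30 µV RMS, plus an 8 µV 60 Hz mains sinusoid, 2 µV sensor noise, and a
frontally-weighted copy of the EOG (so notch filtering and artifact
rejection have real work). Because the synthesis filters have finite
skirts, target weights are pre-distorted by the inverse of the 5 × 5
spectral cross-talk matrix (computed from the filter frequency responses),
so the *measured* band mixture matches the configured weights; the frontal
drowsy beta fraction is additionally pinned to awake-beta × (1 − drop), so
the injected frontal drop equals the configured fraction by construction
(residual measurement bias ≈ 0.02, from Hann smearing and the ocular
bleed).

Within-state nonstationarity — the feature that makes classification
nontrivial — is a slow shared log-AR(1) "wander" per band (SD 0.2, time
constant 45 s) and an Ornstein–Uhlenbeck HbO wander (SD 0.015 mM/DPF,
60 s), chosen so that single-modality accuracies land in a realistic
80–95 % range, awake HbO excursions occasionally approach the 0.05
threshold and awake beta dips occasionally exceed 20 % of the running
maximum (reproducing the single-rule false-trigger structure of real
sessions) while *joint* excursions stay rare. The single `noise_sd` knob
scales every nuisance term; at zero the ramps are clean and downstream
detection and classification are exact.

The transition is a slow drift covering the first quarter of the effect
amplitude followed by a fast 1 s collapse completing 3 s before the
closure, for both the HbO surge and the beta drop (coincident by
construction — their joint occurrence is what distinguishes a real
transition from awake fluctuations). The collapse makes consecutive 1 Hz
beta steps large compared with spectral-estimation noise, so the
"continuous decrease" reference anchors at the pre-collapse level; a
slowly-spread drop of the same total size is invisible to the running
reference, which re-anchors on every noisy uptick. With this morphology
the deterministic joint threshold crossing sits ≈ 3–4 s before the
closure, matching the seconds-scale early detection the method is designed
to deliver.

Eye closures recur through the drowsy state with 20–40 s gaps (every
drowsy minute contains one); the EOG flat-lines during closures. What the
generator does **not** emulate: volume conduction and source topography,
1/f background spectra, ECG/EOG morphology beyond impulse trains,
motion/optode artifacts in NIRS, and between-region differences in the
drowsy band-weight shift (all non-frontal channels share one profile).
Passing tests therefore demonstrate the pipeline's correctness and the
method's behavior under the modeled statistical structure, not performance
on real recordings.

## Statistics

The band × region comparison is an unpaired two-tailed t-test per cell
(5 bands × 5 regions) at a Bonferroni-style significance level of
0.05/25 = 0.002 that follows the matrix shape. The hemodynamic state
summary uses a paired two-tailed t-test across subjects by default — the
same subjects contribute both state means, and on the published
per-subject values the paired variant reproduces the reported p-value
(≈ 0.002) while the unpaired variant gives ≈ 0.005 — with the unpaired
variant also exposed. Report rounding: 3 decimals for mM/DPF, 1 decimal
for percentages, matching field conventions.

## Problem sizes and determinism

The test suite exercises the full chain on a session-scoped 9-subject
cohort at the default 30-minute, 64-channel conditions (≈ 25 s per subject
without ICA) plus many small targeted fixtures; `scripts/acceptance.py`
regenerates a fresh 9-subject cohort from its `--seed` and recomputes the
published-table arithmetic at runtime. Every stochastic component — the
generator, ICA initialization, and the cross-validation shuffles — draws
from explicit seeds, so identical configurations reproduce bit-identical
recordings and identical accuracy vectors.

## Known limitations

* The DDI evaluates against annotation-based ground truth; with real
  recordings the eye-closure annotations must come from external scoring.
* The awake beta reference assumes the subject starts awake; sessions
  beginning drowsy (excluded in the emulated study) would need a manual
  reference.
* FLDA assumes shared within-class covariance; the stacking stage inherits
  that assumption in score space.
* The 0.05 mM/DPF and 20 % thresholds are system- and subject-dependent;
  they are defaults, not calibrated constants.
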