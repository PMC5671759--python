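# Methods

`adneuro` turns per-subject-per-ad physiological recordings into a
fixed set of ad-effectiveness metrics, tests those metrics against
behavioural labels, and predicts online view counts from them.  This
note records the models, the parameter choices that matter, and what
the synthetic cohort generator does and does not emulate.

## EEG metrics

A recording is a channels x samples matrix (µV) at 256 Hz with 10-20
montage labels and event markers delimiting a neutral baseline period,
the ad period, and brand-on-screen windows.

**Preprocessing.** The pipeline assumes ocular/muscular components have
already been removed (any externally cleaned recording can be passed
in); its native artifact stage is epoch rejection: the signal is cut
into non-overlapping 1-s epochs aligned to window onset (partial
trailing epochs dropped) and an epoch is discarded when any channel's
epoch kurtosis

K(x) = E[(x − µ)⁴] / E[(x − µ)²]²

is an outlier among that channel's epochs.  *Numerical choice:* the
outlier score is a robust z on **log** kurtosis (median and scaled MAD
across epochs), threshold |z| > 5.  A plain mean/SD z-score is masked
by the very epoch it should flag — with n epochs the largest attainable
|z| is (n−1)/√n, below 5 whenever n < 30 — and raw kurtosis is
right-skewed, which the log corrects.  Measured on white-noise epochs
the false-rejection rate is ≈0.2% per channel-epoch; a planted spike
train is flagged with probability ≈1.

Bad channels can be replaced by an inverse-distance-weighted mean of
the k = 4 nearest good electrodes in the projected 10-20 layout.

**Band power.** Each band (delta 1–3, theta 4–7, alpha 8–12, beta
13–24, beta-extended 13–40, gamma 25–60 Hz; configurable) is isolated
with a 4th-order Butterworth band-pass applied forward and backward
(zero phase, effectively a twice-applied filter).  Global field power
(GFP) is the spatial standard deviation across the frontal electrode
set at each sample.  The per-band z-score is

z = (mean GFP_ad − mean GFP_baseline) / SD(GFP_baseline),

with per-ad-mean normalization (per-sample normalization is the noted
alternative, not implemented as default).  Rejected epochs are excluded
from both means; when nothing is rejected the result is bit-identical
to running without the rejection stage.

**Pleasantness Index (PI).** Frontal asymmetry in theta and alpha:
GFP is computed separately over the left and right electrodes of the
homologous pairs (Fp1/Fp2, AF3/AF4, F3/F4, F7/F8 when present), each
side z-scored against its own baseline, and PI is the ad-period mean
of (left − right).  Positive PI = left-dominant, conventionally the
approach/pleasant direction.  PI is antisymmetric under swapping the
pair labels.

**Interest Index (II).** Peaks of the band GFP exceeding
mean + 2·SD with ≥250 ms spacing are counted over the whole ad
(PN_total) and inside brand windows (PN_brand); II = PN_brand/PN_total,
defined 0 when there is no peak.  Emitted for theta and beta.

## HRV metrics

Input is an RR-interval series (ms) with cumulative beat times; an
energy-based R-peak detector (derivative → square → 150-ms moving
integration, adaptive threshold requiring peaks ≥4x the series median,
200 ms refractory period) is provided for raw single-lead ECG but the
screened RR series is the canonical input.  Ectopic screening flags
intervals deviating >20% from a window-5 running median, replaces them
with the local median, and rejects series with >20% flagged.

Seventeen metrics:

* time domain — t_meanHR and t_sdHR from the instantaneous rate
  60000/RR (bpm, sample SD), t_RMSSD = √mean(ΔRR²) (ms), t_NN50 =
  #{|ΔRR| > 50 ms};
* frequency domain — Lomb-Scargle periodogram of the mean-centred
  intervals at their beat times (no resampling), on a grid
  [0.003, 0.5] Hz with resolution 1/(4·span); band powers by
  trapezoidal integration over LF 0.04–0.15 Hz and HF 0.15–0.40 Hz,
  aTotal = aLF + aHF (VLF excluded so nLF + nHF = 1 exactly), ratio
  LF/HF, and within-band peak frequencies.  The absolute-power scale
  (2/n x scipy's periodogram) is arbitrary but fixed; only identities
  and peak locations are treated as meaningful;
* non-linear — Poincaré SD1/SD2 and sample entropy.  SD1 is the RMS
  perpendicular distance of (RRᵢ, RRᵢ₊₁) points to the identity line,
  |ΔRR|/√2 without mean subtraction, which makes SD1 = RMSSD/√2 an
  exact identity; SD2 is the sample SD of projections along the line.
  Sample entropy is −ln(A/B) with Chebyshev tolerance r = 0.2·SD,
  template lengths m and m+1 over the n−m templates that admit an
  extension, self-matches excluded; m = 1 and m = 2 are reported.
  Constant series return 0 by the regular-series convention; B = 0
  returns NaN, A = 0 returns +inf.

## Eye-tracking metrics

Input is a 300 Hz gaze stream (timestamp, x, y, validity; pixels,
origin top-left) plus a dynamic brand AOI: non-overlapping timed
rectangles.  Fixations are detected by velocity threshold (I-VT):
consecutive valid samples with point-to-point velocity below 30 px per
nominal frame (9000 px/s at 300 Hz) form a fixation; invalid gaps up to
75 ms are bridged; fixations shorter than 60 ms are dropped.  The
detector parameters are stated defaults — the vendor tooling the field
typically uses does not publish its settings.

Nine metrics per ad: fixation count and mean duration over the ad;
fixation count/mean duration on the brand (a fixation belongs to the
AOI when its centroid lies in the half-open rectangle active at its
start time); mean latency from brand appearance to first brand
fixation (over appearances with a hit); visit count and mean visit
duration, a visit being a maximal run of consecutive valid samples
inside the active rectangle (invalid samples neither open nor close a
visit); and two scan-level summaries:

* **Quad_sec** = N_q / t_s, where N_q counts quadrant *entry events*
  on a 4x4 full-screen grid — a visit starts at the first valid sample
  and at every quadrant change, re-entries counting again.  Entry
  counting (rather than distinct-quadrant counting, which saturates at
  16) is what distinguishes ambient scanning from focal viewing over a
  30-s ad; a distinct-quadrant variant would be a one-line change.
* **Brand_ratio** = t_bf / t_b ∈ [0, 1]: summed fixation time inside
  the active AOI during visibility over total brand-visible time.
  Fixation time (not raw sample time) implements "looked directly at".

All gaze metrics are invariant under a common time translation of
stream and AOI track.

## Statistics

One row per subject x ad (pooled across subjects; no mixed-effects
structure — a known limitation, kept for fidelity to the validated
design).  For each metric and each two-group labelling (recalled RMB
vs forgotten FRG; liked LIKE vs disliked DISLIKE, the split being a
10-point rating ≥ 5), a Shapiro-Wilk gate at α = 0.05 on each group
routes to one-way ANOVA (both normal) or Mann-Whitney U.  Significance
uses a fixed corrected threshold p < 0.005 — a per-test constant, not
a stepwise FDR procedure.  Metric-outcome association: Pearson r
against view counts (linear scale), Spearman ρ against the ACE survey
score (rank scale), flagged at p < 0.01.  Undefined metric values are
dropped pairwise.

## View-count prediction

Both networks share one architecture: a single hidden layer of
⌈(n_inputs + n_outputs)/2⌉ tanh units on typified covariates, softmax
output for the four view-rank bins (<1M, 1M–5M, 5M–10M, >10M;
lower-closed edges at 1e6, 5e6, 1e7) or identity output for the view
count (target typified, predictions mapped back).  Training uses adam
(learning rate 0.02 — the small single-hidden-layer nets here converge
far too slowly at the library default), early stopping on a 20%
validation split with patience 50, and an L2 penalty α = 1.0.  The
penalty is load-bearing: with ~37 covariates of which most carry no
signal and ~200 training rows, an unregularized network memorizes the
training split (100% train, ~78% test on the synthetic cohort) while
α = 1 restores generalization without touching the architecture.

Validation is k = 10 repeated stratified 70/30 hold-out; per-repeat
test confusion matrices (or relative errors) are element-wise
averaged.  Relative error is RSS/TSS on the test set, so predicting
the mean scores 1 and perfection 0.  Variable relevance is permutation
importance — mean loss increase over 10 permutations per column, each
column with its own name-keyed random stream so results do not depend
on column order — normalized to max = 100%.

## Synthetic cohorts

No recording of the original study is publicly deposited, so the
generator emulates the full data structure at the study's scale
(35 subjects x 8 ads of 30 s, 2-min baseline, 256 Hz EEG / 300 Hz
gaze) with planted, analytically recoverable effects:

* **EEG** — per-band Gaussian noise filtered into the band, scaled to
  per-period RMS amplitudes (defaults: delta 8, theta 6, alpha 10,
  beta 4, gamma 2 µV over a 1 µV broadband floor), with a signed
  left/right frontal power offset a applied as √(1±a) amplitude
  scaling in theta and alpha during the ad.
* **RR** — direct sinusoidal modulation of the interval series,
  RR(t) = 850 + 30·sin(2π·0.10·t) + 20·sin(2π·0.25·t) + N(0, 5) ms,
  sampled at the beat times it itself induces.  This is deliberately
  not an integral-pulse-frequency-modulation model: the spectral peaks
  are known in closed form, which is what the recovery tests need.
* **Gaze** — fixation centres with 4 px within-fixation jitter and
  2-sample saccade transits; ambient mode scatters centres over the
  whole screen with 120–280 ms dwells, focus mode clusters them
  (σ = 60 px) with 350–650 ms dwells.  Brand attendance is planted as
  a per-appearance fixation-time budget (attendance x appearance
  duration), with the closing fixation truncated to the budget and
  off-brand dwells truncated at pending appearance onsets, so the
  downstream Brand_ratio recovers the planted fraction within ±0.05.
  Two generator realism rules matter: fixation centres are nudged at
  least 4σ of jitter away from quadrant gridlines (otherwise sensor
  jitter aliases into spurious quadrant visits at 300 Hz), and transit
  samples that would cross the visible brand rectangle are dropped
  (otherwise attendance 0 is violated by flyovers).
* **Labels** — each ad gets a rank bin (cycling over all four), a
  view count log-uniform within its bin, and an ACE-like score; each
  subject x ad draws a latent score effect_size·(rank − 1.5) + noise
  that thresholds into recall (RMB/FRG) and a 1–10 liking rating
  (LIKE at ≥5).  The same rank effect modulates the planted theta
  gain, frontal asymmetry, mean RR and brand attendance, and — in the
  fast metric-level generator — shifts six feature columns (PI_theta,
  II_theta, t_meanHR, p_SD1, Fix_Count_Advert, Fix_Count_Br) by
  effect_size SD per rank step while all other columns stay pure
  noise.

What the generator does **not** emulate: EEG morphology (no ERPs, no
1/f background, no ocular artifacts beyond optional spikes), realistic
baroreflex dynamics, smooth pursuit, blinks, or calibration drift.
Passing tests therefore demonstrate that the measurement chain
recovers known ground truth under the stated signal models — not that
the metrics are valid on human recordings.

Determinism: an identical spec (including seed) reproduces
byte-identical cohorts; per-stream generators draw from seed-sequence
children keyed by (subject, ad), and the pipeline derives per-stage
seeds by hashing, so toggling one stage does not shift another's
randomness.

## Problem sizes used in the checked examples

The shipped tests and the acceptance script run the statistics
calibration at 1000 null and 200 shifted datasets (n = 50 per group),
the spectral recovery at 100 two-minute RR series, the asymmetry
recovery at 20 seeded recordings on a six-channel frontal montage
(8-s ad, 12-s baseline), and the network recovery on the 280-row
(35x8) metric-level cohort with effect size 2.0; the raw-signal path
runs end-to-end at reduced cohort sizes.  These sizes give stable
pass/fail behaviour across seeds while keeping a full run inside a
few minutes on one CPU.

## Known limitations

* ICA-based ocular/muscle cleanup is out of scope; only kurtosis epoch
  rejection is native.
* The PI/II formulas follow the operational definitions above; sign
  conventions are documented and isolated in single functions so
  alternative published variants can be swapped in.
* Absolute Lomb powers are unit-calibrated only up to a fixed scale.
* Observations are treated as exchangeable across subjects; repeated
  measures within subject are not modelled.
* The 4x4 quadrant grid covers the full screen; a video-area rectangle
  can be configured when stimuli are letterboxed.
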