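# Methods

This note documents the models, conventions and design choices behind
`valphys`, in the spirit of a methods appendix: what is computed, under
what assumptions, and where the open choices were resolved.

## Study structure emulated by the generator

The synthetic cohort mirrors a video-stimulation valence experiment:
24 subjects (16 men, 8 women), 14 clips per subject (7 positive,
7 negative, durations uniform on 43–78 s) alternating with 30 s baselines
that also provide the initial rest period. ECG is rendered at 256 Hz,
wrist temperature at 1 Hz; EEG enters as band-power features per analysis
window (one 28 s window per trial, or 4 s sliding windows with 50% overlap
— the default — which multiplies the samples available to
subject-dependent models). Subjective ratings are drawn from truncated
normals on the 1–9 scale whose **post-truncation** means match the target
class summaries (valence 7.51 ± 1.6 positive, 2.91 ± 0.98 negative;
arousal 3.76 ± 1.62 / 5.47 ± 1.35): the location parameter is solved
numerically, because clipping at the scale ends shifts the realized mean
(a naive location of 7.51 yields ≈ 6.9). The realized s.d. is slightly
below the nominal parameter for the same reason.

## Interval-series model

Beat-to-beat intervals are AR(1) (coefficient 0.8, innovation s.d. 8 ms)
around a base RR of 857 ms (≈ 70 bpm), plus sinusoids with random phase in
the HF (0.25 Hz, 20 ms), LF (0.08 Hz, 15 ms) and VLF (0.02 Hz, 10 ms)
bands so all frequency measures are nondegenerate. The ECG renders a
Gaussian-derivative QRS-like wavelet (80 ms support) at each beat time
snapped to the sample grid — the simplest shape an amplitude-threshold
detector must handle; detection recovers intervals to within one sample.

### Planted autonomic effects

* **NN50 (men, positive trials).** Alternating ±30 ms runs of 8 intervals
  are injected at Poisson-distributed counts. An alternating run of any
  length contributes only `amp²/n` to SD2² (its energy lives in the
  successive differences), so the short-term plant barely leaks into the
  long-term measure; the Poisson rate is calibrated from the closed-form
  successive-difference s.d. so the expected NN50 surplus equals the
  configured shift (default 10 counts/trial).
* **SD2 (women, negative trials).** A slow 0.015 Hz sinusoid whose
  amplitude is solved from the closed-form base SD2 so that SD2 rises by
  the configured shift (default 20 ms). The low carrier frequency keeps
  its successive-difference energy (and hence NN50 leakage) negligible.
* **Temperature.** A mean-reverting 1 Hz walk (AR 0.995, step 0.02 °C)
  around a subject baseline uniform on 27–29 °C, with rare ±4–8 °C
  single-sample spikes to exercise the MAD rule. Stimulation adds 1.7 °C
  (the stimulus–baseline gap); negative trials add a further 0.4 °C for
  women only. The 0.4 °C figure is chosen for detectability with
  per-trial means as observations (56 vs 56 trials in the women split) —
  pooled-sample testing of raw 1 Hz values would detect far smaller gaps,
  but per-trial means avoid pseudo-replication of autocorrelated samples.

### Planted EEG effects and heterogeneity

Log band powers are normal per feature (band-specific baselines, subject
intercept s.d. 0.6, window noise s.d. 0.3); powers are their exponentials.
Positive valence shifts the prefrontal left/right log-power difference by
+`eeg_asym_shift` (left up, right down) and the occipital difference the
opposite way; negative valence reverses both. Central and parietal pairs
carry no planted effect. Every subject's effects are scaled by a
multiplier ~ Normal(1, `subject_heterogeneity`), and — by default — the
EEG effect direction receives an independent random sign per subject.
This is the mechanism that makes subject-dependent models succeed while
leave-one-subject-out transfer fails: the within-subject effect is strong
and consistent, the population-level direction is not. The subject
intercept spread (0.6) deliberately dominates the half-shift (0.3) so
nearest-neighbor classifiers cannot exploit cross-subject sign cliques.

## HRV measures

Population variances (divide by *n*) are used for SDNN, SD1 and SD2 so the
identity `SD1² + SD2² = 2·SDNN²` holds exactly. The identity is
definitional whenever SD2 is real; adversarial series with near-perfectly
anticorrelated successive beats (past the alternating-series boundary,
where `2·var < SD1²`) would give a negative SD2², which is clamped to
zero. NN50 counts successive differences strictly greater than 50 ms and
pNN50 divides by *n − 1* pairs.

Spectral band powers come from a Lomb–Scargle periodogram of the
mean-centred tachogram evaluated on a linear grid over 0.003–0.4 Hz and
integrated per band; integrals are rescaled to sum to the tachogram
variance, so absolute powers are in ms² and the three percent fields sum
to exactly 100. This avoids choosing a resampling scheme for the unevenly
sampled series. The VLF lower bound defaults to 0.003 Hz (configurable).
Trials shorter than 30 s still yield frequency measures but are logged as
low-confidence; sub-minute trials are already below conventional
standards, which is also why geometric HRV methods (needing ≥ 20 min) are
out of scope. The 19-measure table includes total spectral power, the
natural companion of the band decomposition.

R-peak detection (method open in the source literature) uses the squared
10 Hz-high-passed signal against an adaptive threshold (sliding 2 s mean
+ 2 s.d.) with a 200 ms refractory period. Interval artifacts are flagged
when deviating more than 25% from the median of the 5 preceding clean
intervals (global median as the early reference) and replaced by a
shape-preserving cubic (PCHIP) through the clean beats: an unconstrained
cubic overshoots beyond the neighboring beats around ectopic-like drops
(e.g. to ~811 ms for the fixture 800, 810, 400, 805, 795, against
neighbors at 805–810), whereas the monotone cubic stays inside. Trials
with more than 20% flagged intervals are rejected with a quality error
(threshold configurable). Correction is idempotent on corrected series.

## EEG conventions

Band edges Alpha 8–12, Beta1 12–20, Beta2 20–30, Gamma 30–45 Hz
(consistent with the 45 Hz low-pass; fully configurable). Region →
electrode defaults are standard 10/10 neighborhoods (PF-left =
{Fp1, AF3, AF7}, etc.) and configurable because no canonical mapping
exists. Preprocessing is a 0.5–45 Hz zero-phase band-pass followed by
common average reference; a pluggable artifact hook is provided (empty by
default — ICA-style visual rejection is out of scope, and synthetic data
are clean). Powers enter statistics untransformed by default; a log
option exists. Midline features never enter asymmetry pairs; 9 lateral
pairs are evaluated.

## Temperature conventions

"Three scaled MADs" is read as 3 × 1.4826 × MAD, the consistency scaling
under normality. When MAD = 0 (more than half the samples equal the
median) the threshold degenerates to zero and any sample different from
the median is flagged — so a constant segment is untouched while a lone
spike on an otherwise constant segment is still caught. Replacement uses
the mean of the retained samples only (the all-sample mean would reinject
the spike). Cleaning is applied once per segment; the `cleaned` flag makes
the operation idempotent (recomputing the threshold on cleaned data could
otherwise flag borderline samples as the MAD shrinks). The analyzed 28 s
is the first 28 s after clip onset (configurable offset); baselines use
the same window length.

## Statistics

All group comparisons are two-sided Mann–Whitney U: exact when both
groups have ≤ 8 observations and the pooled sample is tie-free, otherwise
the tie-corrected normal approximation with continuity correction (the
two agree to |Δp| ≤ 0.02 at n = 8/8). Normality screening uses the
one-sample KS test on the standardized sample (conservative, since
parameters are estimated). Feature–rating association is Spearman rank
correlation (consistent with the nonparametric stance; Pearson behind a
flag). p-values are reported raw — multiple-testing correction is
deliberately off by default, with a Benjamini–Hochberg helper available —
because the downstream use is qualitative pattern description, not
confirmatory inference. z-scoring uses the population convention and
fails loudly on zero-variance columns.

## Selection and classification

The annealer searches bit masks over candidate features with single-bit
flips, Metropolis acceptance `exp(−Δ/T)` and a geometric schedule
(T₀ = 0.1 f1 units, cooling 0.95, 500 steps by default, random
half-size initial subset). One set of stratified CV folds is frozen per
run and reused for every subset so comparisons are not confounded by fold
noise; the best-ever state is returned with ties broken toward the
smaller subset. At T → 0 the search is greedy (never accepts a worse
state), and runs are bit-reproducible under the seed.

Classification uses KNN with 5 neighbors (Euclidean on z-scored features)
and QDA with covariance shrinkage `reg_param = 1e-3` (small folds are
otherwise singular; regularization replaces failure). SD evaluation is
stratified k-fold per subject with folds grouped by trial, so analysis
windows of one trial never straddle folds — splitting them would leak
within-trial autocorrelation and inflate SD scores. SI evaluation is
leave-one-subject-out. Scalers live inside the CV pipeline (training
folds only); f1 is computed on the positive class per held-out unit and
averaged, with macro-f1 reported alongside. Modality fusion is a key join
on (subject, trial): the per-trial NN50 and mean cleaned temperature
broadcast to each EEG window — feature-level alignment in place of
signal-level resampling, which is equivalent for per-trial scalars.
Subjects missing a modality are dropped from fusion with a logged list.

## Pipeline and reproducibility

`run_full_analysis` derives per-stage seeds from one top-level seed via a
seed sequence, writes every stage table as TSV (fixed float format), the
manifest as JSON, and a plain-text summary; re-running a config writes
byte-identical bundles. The dataset writer stores floats at full
precision and the reader parses with round-trip float handling, so a
written cohort reloads losslessly. A full default run (24 subjects,
14 trials, both classifiers) completes in roughly a minute on one CPU;
the test suite uses reduced cohorts (6–12 subjects) and shortened
annealing schedules (120–150 steps) where the property under test does
not need the full design.

## What the generator does and does not show

Passing tests demonstrate that the pipeline recovers planted effects with
the right direction, calibration and subject-level phenomenology — not
that real recordings behave this way. The generator omits, among other
things: real QRS morphology variability and detection-hostile noise, EEG
artifacts (ocular, muscular), circadian and ambient temperature drift,
arousal-driven autonomic modulation (ratings are generated but drive no
physiological effect), and any correlation structure between modalities
beyond the shared valence labels. Raw multichannel EEG synthesis is
limited to tiny fixtures for testing the filtering/CAR/band-power path;
cohort-scale EEG is generated directly at the band-power level.

## Known limitations

* The small female subgroup (8 subjects) makes gender-split SI
  classification noisy; the code warns below 15 subjects per group.
* Frequency-domain measures on sub-minute trials are low-confidence by
  construction; VLF in particular is barely resolved on 43–78 s windows.
* QDA on 22 features with small per-subject samples relies on the
  shrinkage regularizer; scores under SD with few windows per trial are
  sensitive to fold layout.
* The exact Mann–Whitney path requires tie-free pooled samples; count
  features (NN50) with small groups route to the tie-corrected
  approximation.
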