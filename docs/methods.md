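# Methods

This note records the models, algorithmic choices and numerical
conventions behind `voicepd`, and what the synthetic test bed does and
does not establish about real speech data.

## Synthetic voice model

Each voice is a source–filter simulation. The source is a Rosenberg
glottal flow pulse (smooth cosine rise over 40% of the cycle, faster
cosine fall over 16%, closed otherwise), which gives a realistic
spectral tilt so that MFCCs are not degenerate, as an impulse train
would make them. Successive cycle periods are

    T_i = (1 / f0_i) * (1 + jitter_frac * eps_i),   eps_i ~ N(0,1) clipped at ±3,

and pulse amplitudes `A_i = 1 + shimmer_frac * eta_i` analogously, so
`jitter_frac` and `shimmer_frac` are by construction the relative SDs of
periods and amplitudes — the ground truth that recovery tests compare
against. The pitch contour `f0_i` is `f0_base` plus a per-cycle AR(1)
wander with stationary SD `f0_drift_sd` and coefficient ρ = 0.9
(correlation time ≈ 10 cycles ≈ 60–70 ms). ρ trades smoothness against
one-step predictability: a near-random-walk contour (ρ → 1) is removed
almost perfectly by the low-order whitening inside PPE, leaving the
measure blind to the dial it is meant to sense; ρ = 0.9 keeps the wander
slow on the cycle scale while leaving a detectable whitening residual.

The pulse train is rendered phase-exactly (each cycle's waveform is the
continuous pulse evaluated at sample instants), so a zero-jitter voice
is periodic to machine precision rather than to ±1 sample. The train is
colored by cascaded second-order resonators (unit peak gain) at the
formant frequencies; "running speech" is approximated by 3–6 vowel
segments with distinct formant presets separated by 50–150 ms gaps.
Aspiration noise is Gaussian, band-limited to 0–4 kHz, and scaled so
that the harmonic-to-noise power ratio *in that band over the voiced
samples* equals `hnr_db`; band-limiting the noise to the band in which
it is calibrated means an autocorrelation HNR estimator sees exactly the
requested ratio instead of a full-band ratio ~3 dB off. Ambient
(recording-chain) noise is added over the whole file, including the
non-speech pads, at an SNR of 45 dB for "lab" and 32 dB for "home"
recordings.

Cohort defaults mirror the emulated study population: 262 PD / 464
control; 38.5% / 64.6% female; ages 65.92 ± 9.2 vs 57.98 ± 14.2
(truncated normal); 7.4% lab-recorded; mean F0 assigned from smooth
demographic curves (female `210 − 0.55(age−18)` Hz, male
`118 + 0.012(age−45)²` Hz — female monotonically declining and always
above male, male minimal at 45) plus 12 Hz of individual scatter.
No quantitative PD-vs-control effect sizes exist for these acoustic
parameters in the emulated setting, so the group contrasts are fixed at
clinically plausible magnitudes — control jitter 0.008 ± 0.003 vs PD
0.020 ± 0.006, shimmer 0.040 ± 0.012 vs 0.090 ± 0.025, HNR 22 ± 3 vs
14 ± 3 dB, drift 3 ± 1 vs 8 ± 2.5 Hz — fixed once at these values.
With several near-independent features each separated by about two
within-group SDs, the resulting classification task is considerably
easier than real-world screening: synthetic AUCs land far above what
heterogeneous clinical cohorts yield, and should be read as a check
that the pipeline preserves the planted contrast, not as a performance
claim.
Default voiced duration is 2 s per subject, which keeps a 726-subject
end-to-end run tractable while leaving ≥ 250 glottal cycles per
recording for the perturbation statistics.

What the generator does *not* model: articulation (no consonants, no
true pangram), dysarthric timing deficits, room acoustics and
reverberation, device compression, and any coupling between dysphonia
parameters and spectral envelope. Passing tests therefore demonstrate
that the *pipeline* measures what it claims on signals with known
ground truth — not that the classifier's synthetic AUC transfers to
real cohorts.

## Endpoint trimming

Forced alignment is used in web-speech studies only to locate the first
and last word; an energy endpointer approximates that on clean and
synthetic audio without trained acoustic models. Frames of 25 ms / 10 ms
hop are loud when within 35 dB of the loudest frame (relative, because
device gains vary wildly; plus an absolute floor of −90 dB so numerical
residue never counts); the span runs from the first to the last run of
≥ 5 consecutive loud frames, keeping interior pauses, as alignment
would.

## Pitch, cycles, and perturbation features

F0 is tracked Praat-style: normalized short-term autocorrelation (40 ms
frames, 10 ms hop), lag-bias corrected by dividing out the rectangular
window's autocorrelation — without that correction a perfect tone's
peak is deflated by (n−lag)/n and HNR saturates near 7 dB. The peak is
refined by parabolic interpolation; a small octave cost
(0.05 · log2(lag/lag_min)) breaks the tie toward the shorter lag when a
subharmonic matches equally well. Frames are voiced when peak
correlation ≥ 0.45 and energy is above the silence threshold; estimates
more than an octave from the utterance median are re-marked unvoiced.
Search range 75–500 Hz, all thresholds configurable.

Cycle marks are placed within voiced runs by stepping one local period
at a time and snapping to the maximum-amplitude sample within ±T/4 of
the prediction, with parabolic sub-sample refinement. Marks are picked
on the *fundamental band* (zero-phase Butterworth bandpass,
0.6–1.6 × median F0): on the raw waveform, noise makes the argmax flip
between formant-ringing peaks ≈ 1/F1 apart, an error of ~20% of a
period that would bury genuine jitter. The first and last cycle of each
run are discarded (onset transients). The band is wide enough to pass
the jitter modulation sidebands, but some attenuation of extracted
vs. true perturbation remains; the feature contracts are therefore
monotonicity in the generator dials and group separability, not
unbiased recovery of the dial value.

Jitter/shimmer definitions (on periods T and amplitudes A):
`Local = mean|ΔT|/mean T`, `LocalAbsolute = mean|ΔT|` (s),
`Rap/Ppq5 = mean|T − centered 3/5-point mean|/mean T`,
`Ddp = mean|Δ²T|/mean T = 3·Rap` (identity, tested to 1e−12), and
analogously for shimmer with `LocaldB = mean|20·log10(A_i/A_{i−1})|`,
`ApqN`, `Dda = 3·Apq3`. The `Mean*/Median*` variants are
under-specified in the source feature inventory ("mean/median
variation"); they are defined here as the mean/median absolute
successive difference normalized by the *median* (robust) rather than
mean, which also keeps them from duplicating `Local*` exactly. Fewer
than 11 cycles marks the family missing (NaN) with a logged warning.

HNR per voiced frame is `10·log10(r/(1−r))` with r the lag-bias-
corrected autocorrelation at the F0 lag (searched ±1 sample), averaged
over voiced frames and clipped to [−20, 60] dB.

## Spectral and nonlinear measures

MFCCs: Hamming window, power FFT, 26 triangular mel filters spanning
0–Nyquist, log energies, orthonormal DCT-II, coefficients 0–12.
"Variation" is the per-coefficient SD across frames (a mean-absolute-
delta alternative sits behind `variation="mad"`). Relative band power
uses Welch PSD integrated over 0–500, 500–1000, 1000–2000 and
2000–8000 Hz (F0/low harmonics, F1, F2, frication), renormalized to sum
to one.

RPDE embeds the voiced signal (m = 4, delay = first autocorrelation
zero crossing, capped at 5 ms) and records, for a strided set of anchor
points, the first return time into an ε-ball (ε = 0.12 × embedded SD)
*after leaving it*, up to T_max = 20 ms; the normalized entropy of the
return-time histogram is H/ln T_max. DFA integrates the mean-removed
signal, removes a linear trend per non-overlapping window at 12
log-spaced scales from 50 samples to N/4, and fits the slope of
log F(n) vs log n; the estimator is validated against signals of known
exponent (white 0.5, 1/f 1.0, Brownian 1.5, each within ±0.1).

PPE maps voiced F0 to semitones relative to the speaker median
(transposition-invariant), whitens with an order-2 autocorrelation-
method LPC filter, and takes the entropy of the residual histogram over
±2 octaves in 30 bins, normalized by ln 30. The bin edges are offset by
half a bin so that zero is a bin *center*: with an even bin count, a
perfectly steady pitch would straddle the central edge and register
ln 2 of spurious entropy. RPDE, DFA and PPE are computed on running
speech here even though they were designed for sustained phonation;
extraction metadata flags that the measures are taken over concatenated
voiced segments.

## Cohort assembly and pruning

Per-file failures exclude the subject (logged), never the run; subjects
with any missing feature are dropped so kept columns are NaN-free.
Correlation pruning visits pairs in the fixed documented feature order
and drops the later-ordered member of any still-kept pair with
|Pearson r| > 0.9. The reference procedure iterated pairs in an
unspecified order, which makes the kept set nondeterministic; fixing
the order makes it reproducible and biases survival toward
earlier-listed features. |r| (not signed r) is thresholded; constant
columns correlate with nothing and are kept with a warning.

## Classification protocol

LOOCV with n folds: per fold, features are standardized on the n−1
training subjects and the oversampler runs on the training portion
only — oversampling before the split would place synthetic
near-copies of the held-out subject in training, and a leakage test in
the suite documents the resulting optimistic bias on a null cohort.
SMOTE interpolates x + u(x_nn − x), u ~ U(0,1), between a minority seed
and one of its k = 5 nearest minority neighbors (Euclidean on
standardized features, k capped at minority−1); SVM-SMOTE restricts
seeds to minority points inside the margin band (|decision| ≤ 1) of a
linear-kernel SVC, falling back to all minority points if the band is
empty. Held-out scores are pooled into one ROC (per-fold AUC is
undefined with a single held-out sample); AUC is the Mann–Whitney
statistic with ties counted half; accuracy thresholds the score at 0.5.
Four algorithms are exposed — SVM (RBF, score = logistic of the
decision function), random forest, gradient boosting (LightGBM) and
extreme gradient boosting (XGBoost) — at library-default
hyperparameters with a fixed seed, overridable per `ModelSpec`; the two
boosting entries are deliberately separate named configurations.

## Shapley attribution

The coalition value v(S) is the path-dependent conditional expectation:
per tree, follow the instance's branch at nodes splitting on features
in S, otherwise average the subtrees weighted by training cover; the
background distribution is thus the cover statistics embedded in the
trees (no interventional variant). Two independent routes compute the
Shapley values of this game: exact enumeration over all 2^d coalitions
(d ≤ 15), and the polynomial-time per-tree path algorithm that tracks
permutation weights along each root-to-leaf traversal and unwinds each
path feature to obtain its marginal contribution. The fast route is
tested against the exact one to 1e−6 on random depth-3 ensembles and
satisfies efficiency (base + Σφ = raw margin), dummy and symmetry
axioms. Trees are extracted with their covers from XGBoost (JSON dump;
margins offset by the logit of base_score), LightGBM (model dump;
attribution in log-odds space) and scikit-learn forests (probability
space, per-tree value divided by the ensemble size). SVMs expose no
trees and are rejected with a typed error. Global importance is the
mean |φ| per feature, ties broken stably by feature order; the
incremental curve re-runs LOOCV on the top-k features for k = 1..k_max
and reports the first k within 0.01 AUC of the k_max value.

## Experiment designs

Selectors: `all`, `male`, `female`, `age_trimmed` (age ≥ 50, i.e.
excluding subjects younger than 50), `drop_lab`, and
`drop_random_home` (drop `round(0.07 × n_home)` home subjects, redrawn
`repeats = 10` times, metrics averaged). Reported n is always the raw
subject count; when an oversampler is active the post-balancing
training-fold size is echoed separately, because "n" is otherwise
ambiguous between raw and post-oversampling counts. `ablation_delta`
is AUC(all) − AUC(ablated) per shared model spec: positive means the
ablation hurt. Note that 7% of 672 home subjects is 47, not the ~54
that a "same size as the lab subset" reading would give; the fraction
is the contract and the resulting count is reported explicitly.

## Problem sizes and determinism

The acceptance run (`scripts/acceptance.py`) uses the full default
cohort — 726 subjects at 2 s voiced duration — for generation,
extraction, the four-classifier LOOCV grid, the stratified models and
both ablations. The tree ensembles in that script run at 50 trees
(performance plateaus well before that on these features, and the
full-cohort LOOCV grid then completes in minutes); the repeated
ablation and the incremental curve use the SVM, and the incremental
curve evaluates a 250-subject subsample with the top-8 ranked features.
Everything — cohort sampling, per-voice synthesis seeds, SMOTE,
classifiers, SHAP subsampling — derives from the single `--seed`
argument; the test suite uses its own fixed seeds throughout.

## Known limitations

* Extracted jitter/shimmer are attenuated and noise-floored relative to
  the generator dials; contracts are monotonicity and group contrast.
* RPDE/DFA/PPE on running speech violate the sustained-phonation
  assumptions under which those measures were designed; they are
  computed on concatenated voiced segments and should be read as
  pipeline features, not validated clinical biomarkers.
* The SVM is scored through a logistic squash of its decision function;
  its 0.5 accuracy threshold corresponds to the decision boundary, not
  a calibrated probability.
* Synthetic cohorts share one recording chain per site class; real
  heterogeneous-device effects (codecs, clipping, room noise) are out
  of scope.
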