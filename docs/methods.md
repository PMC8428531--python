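# Methods

## The problem

The package implements a binary (positive vs negative) emotion classifier
for video-evoked EEG, together with everything needed to evaluate it without
access to recorded data: a generator of synthetic emotional EEG with a known
class effect, the preprocessing chain, a 59-feature per-channel descriptor
set centred on band differential entropy, gradient-boosting electrode
selection, and a four-classifier comparison under stratified 10-fold
cross-validation.

The unit of classification is the 1-s epoch. A recording session consists of
subjects watching 60-s positive or negative video clips while 32-channel EEG
is acquired; after each clip the subject reports valence/arousal/dominance/
liking on 9-point scales. Epochs inherit the clip's stimulus tag as their
label, but a clip whose reported valence contradicts its tag (valence not
strictly above 4.5 for a positive clip, not strictly below for a negative
one) is deleted wholesale — self-report must corroborate the stimulus before
its epochs are trusted. A rating of exactly 4.5 counts as mismatch, since
the classification rule is stated strictly in both directions.

## Synthetic data model

Each channel of a synthetic recording is the sum of

* 1/f-power-shaped broadband noise (default total variance 10 uV^2), and
* five independent band-limited Gaussian oscillations, one per canonical
  band (delta 0.5-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-45 Hz),
  with default variances 20/15/25/12/10 uV^2 — a low-frequency-dominated
  resting-like spectrum.

The class effect is a multiplicative variance scaling: positive clips
multiply the oscillation variance by `effect_size` (default 2) in the
profile's effect bands (default gamma) on its effect channels (default
Fp1/Fp2/T7/T8). This choice makes the differential-entropy separability
analytically predictable: since the band DE is half the log band energy, a
variance ratio r shifts the class-conditional mean DE by exactly
`0.5*log(r)` on affected channels. A per-band override
(`effect_size_by_band`) expresses conditions like "strong gamma, weak beta".

Ratings are drawn normally around valence 7 (positive clips) or 3
(negative) with configurable noise sd (default 1 point), arousal around 6
for both; all clipped to [1, 9]. Artifacts are optional and off by default:
ocular events are frontal-weighted raised-cosine pulses of 80-150 uV at a
configurable events/minute rate; muscle events are 20-45 Hz bursts on the
temporal electrodes at half that rate.

The desk-scale default (6 subjects, 4+4 clips of 8 s at 250 Hz) keeps every
analysis runnable in minutes on one CPU; the full-shape preset (26
subjects, 60-s clips, 1000 Hz) is expressible through the same config. The
number of subjects is deliberately a free parameter rather than a fixed
constant.

What the generator does *not* emulate: volume conduction and channel
covariance (channels are independent), non-stationarity across a session,
genuine ocular/muscle waveform morphology, subject-specific spectra.
Passing tests therefore demonstrate that the pipeline recovers structure it
is pointed at — not that the classifier accuracies transfer to human EEG.

## Preprocessing

Multi-channel path (in order): zero-phase 4th-order Butterworth band-pass
0.5-45 Hz plus 48-52 Hz band-stop notch (applied forward-backward, so the
effective order is 8 and the phase response zero) -> common average
reference -> ICA ocular removal -> segmentation into 1-s epochs ->
rejection of any epoch exceeding +/-80 uV on any channel. Epochs emitted by
the pipeline always satisfy the amplitude bound.

Ocular removal decomposes the recording with FastICA (as many components as
channels) and flags components that (a) correlate above |r| = 0.8 with an
ocular reference — the frontal-weighted channel average low-passed at 4 Hz
— and (b) are themselves low-frequency dominated (>50% of power below
4 Hz). Flagged components are not zeroed: only their sub-8-Hz content is
removed, which empirically cuts frontal delta power of blink-contaminated
recordings by >90% while leaving beta/gamma within a few percent (zeroing
the whole component redistributes its broadband estimation residue and can
visibly distort the weak beta band).

Dual-frontal path (Fp1/Fp2 only): two channels cannot support ICA directly,
so each channel is first decomposed by ensemble empirical mode
decomposition (EEMD) and ICA runs on the pooled set of intrinsic mode
functions; flagged sources are cleaned the same way and each channel is
rebuilt from its retained IMF parts plus residue. Average re-referencing is
skipped in this path (with two channels it would subtract the pair mean and
destroy half the signal). EEMD defaults follow standard practice: noise sd
0.2 x signal sd, 100 ensembles (the desk suite uses 24, which keeps the
reconstruction error well inside the noise floor at a quarter of the cost).
The EMD sifting uses cubic-spline envelopes with mirrored boundary extrema
and the classic relative-change stop criterion (threshold 0.2, at most 50
sifts); IMF count is capped at log2(N)-1.

The 2-s window mentioned alongside artifact screening is not used for
classification: the classification unit is fixed at 1 s, and the amplitude
screen operates on the same 1-s epochs.

## Features

Per channel, 59 features in a fixed order:

1-14: mean, mean squared first difference, sd, max, min, median, skewness,
excess kurtosis, zero crossings, peak-to-peak amplitude, mean |first
difference| (raw and sd-normalised), mean |second difference| x[n+2]-x[n]
(raw and sd-normalised).
15-16: Hjorth mobility and complexity (first-difference variance ratios).
17: Higuchi fractal dimension, k_max = 10.
18: instability index — variance of per-segment variances (4 segments)
over the squared overall variance, an amplitude-invariant nonstationarity
score. No canonical formula exists for this quantity; this definition is
the package's own and is near 0 for stationary signals.
19-32: spectral energies: total (0.5-45 Hz), and the five main bands plus
low/high splits of delta (at 2 Hz), alpha (10), beta (20), gamma (38).
33-37: main-band energy ratios (they sum to 1 by construction).
38-42: band differential entropies.
43-54: centroid frequency and frequency variability (power-weighted mean
and sd of frequency) for the total band and each main band.
55-59: sample entropy, approximate entropy, fuzzy entropy (m = 2,
r = 0.2 x sd, fuzzy exponent 2), permutation entropy (order 3, delay 1,
normalised), spectral entropy (normalised, over the analysis band).

Binding the embedding-entropy tolerance to 0.2 x sd makes all five
entropies amplitude-scale invariant, which is asserted by tests.

Spectral energies use the plain unwindowed DFT periodogram of the 1-s
epoch. This is deliberate: without a taper, summing |X_k|^2 / N over all
bins reproduces the time-domain sum of squares exactly (Parseval), and the
band differential entropy

    h_i = 0.5 * log(P_i)

then equals the band-limited-Gaussian closed form
0.5*log(2*pi*e*sigma_i^2) minus the constant 0.5*log(2*pi*e/N), which is
fixed for fixed epoch length and therefore classification-neutral. The 1/2
factor is likewise neutral but retained so the closed form tests exactly.
Windowing would buy less leakage at the price of breaking the identity.

Band edges are the conventional clinical choices above; none are dictated
by the problem and all are configurable. Natural logarithms throughout.

Focused sets reuse the same primitives: `ratio_de` (5 ratios + 5 DEs per
channel), `de`, `ratio`, `de_<band>` (one column per channel), and `dual20`
(ratio_de on Fp1+Fp2, 20 columns).

## Electrode selection

A gradient-boosted tree ensemble (200 trees, depth 3, learning rate 0.1,
fixed seed) is fit on one gamma-DE feature per electrode; the normalised
split-gain importance of each column is that electrode's contribution rate.
Importance by gain rather than split count matches the "contribution rate"
reading of the statistic. On synthetic data with a gamma effect on four
electrodes, the four reliably absorb the large majority of the total
contribution.

Five electrode-combination schemes are provided as fixed lists: the
forehead pair (Fp1, Fp2), a ">0.05" group of six, a ">0.03" group of nine,
the head-loop ring (Fp1, Fp2, T7, T8, O1, O2) and its half (Fp1, T7, O1).
The reference contribution table these groups descend from is shipped for
reproducibility, and strict thresholding rules (`thr_0.05`, `thr_0.03`) are
offered alongside. The two deliberately disagree: strictly thresholding the
reference table at 0.05 keeps seven electrodes (O1 at 0.0589 qualifies)
and at 0.03 keeps twelve, while the published groups list six and nine.
Both behaviours are shipped as-is; neither is silently "corrected" into the
other.

## Classification

Four classifiers, all evaluated with stratified 10-fold cross-validation
(folds disjoint, exhaustive, sizes within one, class-balanced,
seed-deterministic):

* **svm_linear** — linear-kernel SVM, cost C selected from
  {0.01, 0.1, 1, 10, 100} by an inner 3-fold grid search.
* **dt_c45** — a C4.5-style tree grown in-package: numeric threshold
  splits chosen by information gain *ratio*, with the classic guard that
  only splits of at least average gain compete (plain gain ratio prefers
  near-degenerate cuts). No pruning; the overfitting gap between train and
  test accuracy is itself one of the study's observations. Library trees
  split on Gini/plain gain, hence the in-package grower.
* **bpnn** — single-hidden-layer perceptron; input width n = feature
  count, output l = 2, hidden width m = round(sqrt(n*l)) (overridable).
  The hidden-width rule in the source material is typeset corruptly
  ("m=n1"); the geometric-mean rule is the standard reading and is
  documented here as a choice. Trained with lbfgs, which converges
  reliably at these widths where first-order methods stall.
* **knn_brute** — brute-force neighbour search, k selected exhaustively
  over odd 1-31 by inner 3-fold CV.

All hyperparameter searches and any feature normalisation are fit strictly
inside the training folds; a label-permutation null stays at 0.50 for every
classifier, which is the leak test. Inner-fold search is mandated even
though a laxer protocol (tuning on the test fold) could report higher
numbers.

Two evaluation schemes: **whole** pools every subject's epochs into one CV;
**single** cross-validates each subject separately (k capped at the
smaller class count when a subject has few epochs) and reports the
unweighted mean across subjects. With one subject the two coincide, which
is asserted.

Accuracy is the headline metric throughout; per-fold values are retained in
`CVResult`.

## Determinism and numerical choices

Every stochastic step takes a seed: generation derives per-clip seeds from
(seed, subject, class, clip) tuples, so datasets are reproducible
element-wise; FastICA, the GBDT, the MLP and the fold shuffles all receive
fixed seeds. Degenerate inputs fail loudly: constant signals (Hjorth,
entropies, fractal dimension), empty or zero-energy bands (energies, DE),
single-class fits, sub-minimum channel counts. SampEn with no template
matches returns the standard capped value with a warning rather than
infinity. Zero-variance columns under z-scoring are left at zero with a
warning.

## Problem sizes

The shipped analyses run at desk scale by choice: 6 subjects x 8 clips x
8 s at 250 Hz (~380 epochs) for the experiment suites, 2000 epochs for
electrode-recovery checks, 24 EEMD ensembles in the suite. These sizes give
stable qualitative results (orderings, recoveries, nulls) in minutes on a
single CPU; all of them scale up through configuration alone.

## Known limitations

* Synthetic channels are spatially independent; no forward model. ICA on
  such data separates sources more easily than on real EEG.
* Classifier accuracies on synthetic data say nothing quantitative about
  human-EEG accuracy; only structure (orderings, dimensionalities,
  leak-freeness, recovery) is asserted.
* EDF import requires the optional mne dependency; EDF export is not
  implemented (the portable epoch container is the interchange format).
* The C4.5 grower handles numeric features and binary thresholds only — no
  categorical multi-way splits, no error-based pruning.
* EEMD is O(n_ensembles x sift cost) and dominates dual-channel runtime;
  the suite default of 24 ensembles is a speed/fidelity compromise.
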