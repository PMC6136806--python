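# Methods

`songdkl` quantifies how much of a reference vocal repertoire's spectral
content is absent from a comparison repertoire, as an estimated
Kullback-Leibler divergence (in bits) between probabilistic models of the
two repertoires. This note documents the model, the numerical choices,
the synthetic-data generator, and the known limitations.

## Pipeline overview

1. **Pre-filtering.** Every recording is high-pass filtered with an
   elliptic IIR filter (default cutoff 500 Hz, 4th order, 0.1 dB passband
   ripple, 40 dB stopband attenuation), applied forward-only so sample
   indices keep their causal meaning. Only the family and cutoff matter
   downstream; order and ripple are exposed in `FilterSpec` but the
   divergence estimate is insensitive to them.

2. **Segmentation.** The rectified waveform is smoothed by convolution
   with a unit-area 8 ms square window (same-length, centered, so envelope
   indices align with waveform samples). A per-recording threshold is
   chosen by Otsu's method over a 256-bin histogram of envelope values;
   supra-threshold runs are merged across gaps ≤ 5 ms, runs shorter than
   10 ms (avian; 50 ms for speech) are dropped, and survivors are padded
   by 3 ms per side. Rule order is fixed: merge, minimum-duration, pad.
   When padding would make neighbors overlap, both are clipped at the gap
   midpoint so no sample belongs to two syllables.

3. **Spectral features.** Each syllable is reduced to a Welch power
   spectrum: 4096-point FFT windows advanced so that consecutive windows
   share 256 samples, the final window zero-padded, periodograms averaged,
   one-sided spectrum truncated to 2048 bins and band-restricted to
   600 Hz–Nyquist (1971 bins at 32 kHz). Rectangular window, no
   detrending. PSDs are normalized to unit sum by default so similarity
   reflects spectral shape, not recording gain; the flag is exposed
   because gain can itself be of interest. An optional multi-block mode
   splits the syllable into equal-duration pieces and concatenates their
   PSDs, restoring coarse spectro-temporal structure (useful for
   classification; largely irrelevant for the divergence).

4. **Similarity-space.** N basis syllables (default 50) are drawn from
   the reference repertoire; each syllable becomes the vector of its
   similarities to the basis, `A_ij = 1 - D_ij / max(D)` with `D_ij` the
   squared Euclidean distance between unit-sum PSDs. The bounded form is
   the default because it maps data into [0, 1] as the method's published
   figures show; the literal reciprocal form `max(D)/D_ij` is retained as
   an option (`form="reciprocal"`), with zero distances mapped to the
   largest finite similarity. When two repertoires are compared,
   `max(D)` is taken over the union of both distance matrices so both
   songs live on one scale.

5. **Song models.** Each repertoire's distribution in similarity-space is
   fit with a full-covariance Gaussian mixture by EM (scikit-learn's
   implementation), initialized from a 10-restart K-means solution,
   restarted 5 times from independent seeds, best converged fit kept.
   Convergence is a relative log-likelihood change below 1e-4, with an
   iteration cap of 500 — EM on these data converges in tens of
   iterations, so the cap only guards pathological inputs. Covariances
   carry a 1e-6 diagonal regularization.

6. **Model selection.** The number of components K (interpretable as the
   number of syllable types) minimizes a three-fold cross-validated BIC:
   for each fold, fit on the other folds and score the held-out fold with
   `-2·loglik + n_params·ln(n_heldout)`; fold scores are summed. The
   aggregation is isolated in one function (`cv_bic`) because
   "cross-validated BIC" admits variants (mean over folds, plain BIC);
   the chosen form is documented here rather than asserted as canonical.
   Grids: 2–20 (avian default), 2–35 (speech). Candidates infeasible for
   the row count are dropped with a warning; a chosen K on the grid
   boundary sets a flag.

7. **Divergence.** With reference model P̂ (fit on one subset of the
   reference rows) and comparison model Q̂,

   D_KL(P̂‖Q̂) ≈ (1/N) Σₙ [log₂ p̂(xₙ) − log₂ q̂(xₙ)]

   over N held-out reference rows never used to fit P̂. This is the
   standard cross-entropy difference estimator; it needs no closed form
   for mixture KL and is unbiased in the sample limit. Base-2 logs
   throughout, so results are in bits. Densities are floored at 1e-300
   before the log and floored points counted. The per-point log-ratio
   standard deviation divided by √N is reported as a Monte-Carlo standard
   error; the identity comparison (Q̂ = P̂) is exactly 0 by construction.
   Split rule: with ≥ `n_fit + n_eval` reference rows (defaults
   3000/3000) the requested sizes are used; otherwise 50/50.

8. **Innovation.** The same estimator with roles reversed (reference =
   tutee) measures comparison content missing from the reference — e.g.
   syllables a learner invented. `split_half_baseline` halves one
   repertoire at random and compares the halves: the measurement noise
   floor for that repertoire.

9. **Classification.** Syllables are labeled with the maximum-posterior
   mixture component; ties break to the lowest index; winners with
   posterior < 0.5 are flagged for review. Against known labels,
   agreement is scored after an optimal one-to-one Hungarian matching of
   predicted to true labels, the standard unsupervised-clustering score.

## Operating regime

Full-covariance mixtures in an N-dimensional similarity-space need
sample counts well above K·N per fit: a component fit on fewer rows than
dimensions has a singular covariance and meaningless held-out
likelihoods. The method's standard operating point (M = 3000 sample
syllables, N = 50 basis syllables, K ≤ 20) respects this. At smaller
sample sizes the basis should shrink with the data; the test suite
mostly runs at N = 15–20 basis syllables with a few hundred to a few
thousand syllables per song, which keeps every fit inside the regime
while exercising exactly the same code paths. The cross-validated BIC is
doubly conservative (held-out likelihood *and* a parameter penalty), so
its chosen K drifts low when n/(K·N) is marginal; with the scaled basis
it recovers the planted type count reliably (see the acceptance tests).

## Synthetic songs

The generator (`synth`) renders songs as sequences of 5–10 categorically
distinct syllable types — harmonic stacks, band-limited noise bursts,
frequency sweeps — of 30–200 ms, separated by silent gaps of 20–40 ms,
with per-rendition jitter. Choices worth recording:

- **Harmonic stacks** are equal-phase sinusoid sums with 1/n roll-off
  under 5 ms raised-cosine ramps, with a gentle downward glide (6% of f0
  by default). The glide spreads each harmonic over a band a few tens of
  Hz wide, as natural vibrato does; without it, pure stationary stacks
  have bin-width spectral peaks, and ordinary f0 jitter moves those peaks
  by more than their own width, which makes renditions of one type as
  distant from each other as from other types — unlike any real syllable.
- **Loudness equalization.** Syllables are normalized by RMS (the
  `amplitude` field is the RMS-equivalent sine level, default 0.25), not
  by peak: noise bursts have a much higher crest factor than tones, and
  peak normalization makes them too quiet for a single per-recording
  amplitude threshold, again unlike real song.
- **Jitter** is multiplicative log-normal on f0 (default CV 0.5%,
  typical of crystallized adult song) and duration (5%), a 10% relative
  amplitude jitter, and an additive white noise floor (0.002 full scale).
  The f0-jitter axis doubles as the degradation dial for tutor/tutee
  experiments (`TuteeSpec.spectral_jitter_extra`).
- **Tutees** re-render the tutor's repertoire with extra spectral jitter,
  omitted types, and/or innovated (novel) types; ground truth marks each
  rendition's type and provenance (copied/innovated) with exact sample
  boundaries.
- **PSD-level repertoires** (`render_psd_repertoire`) synthesize Welch-
  spectrum statistics directly — Gaussian harmonic bumps with f0 jitter
  and per-bin gamma noise mimicking short-window periodogram variability
  — skipping audio entirely. They exist for estimator-scale studies
  (thousands of evaluation samples, 160-basis spaces) where rendering
  audio would dominate runtime; they share no code with the audio path
  beyond the PSD container.

What the generator does **not** emulate: syllable sequencing syntax,
amplitude/frequency modulation patterns within types beyond the fixed
glide, reverberation, cage noise with spectral structure, or multiple
singers. Tests passing on these songs show the pipeline's statistical
machinery is correct, not that segmentation is robust to field-recording
artifacts.

## Numerical notes and degenerate inputs

- Otsu's threshold is computed over histogram bin edges; among tied edges
  (exact ties arise from empty bins between modes) the lowest edge wins.
  A constant envelope has no threshold and raises an error.
- An all-zero syllable yields an all-zero PSD with a warning (unit-sum
  normalization skipped).
- If every PSD is identical, max(D) = 0 and the similarity transform
  raises rather than dividing by zero.
- K-means initialization falls back to the global covariance for clusters
  with fewer rows than dimensions, keeping every initial precision matrix
  finite.
- If no EM restart converges, the best non-converged fit is returned with
  `converged=False` and a warning rather than an exception.
- The causal high-pass filter has an onset transient (~20 ms at 32 kHz);
  DC rejection figures apply to the post-transient steady state.

## Limitations

- Song D_KL compares distributions of *individual syllable spectra*;
  temporal ordering of syllables is invisible to it (by design), and
  within-syllable temporal structure is only visible via multi-block
  PSDs.
- The measure is relative, not absolute: values depend on the basis draw
  and the shared max(D) scale, so comparisons are meaningful within one
  projection (one reference song and basis), and a split-half baseline
  should accompany cohort analyses.
- At marginal sample sizes the estimator can go slightly negative for
  near-identical repertoires (both models overfit, the comparison model
  sometimes slightly less); the reported standard error makes this
  visible.
- Model selection inherits the conservatism described under "Operating
  regime": chosen K is an estimate of the number of *spectrally
  distinguishable* types at the available sample size, not a census.
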