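# Methods

This note documents the models implemented in `neuroscore`, the
assumptions behind them, the parameters that matter, and the design
choices made where the procedure was genuinely open. Nothing here states
an empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Encoding model and brain score

The core statistic is the cross-validated linear predictivity of an
embedding for brain responses. Per cross-validation fold:

1. **Feature scaling.** The word × dim embedding X is z-scored across
   words using training-split statistics only. Zero-variance columns are
   set to 0 and flagged rather than dropped, so design shapes stay fixed.
2. **Response scaling.** Y is scaled with a robust scaler: values are
   clipped at the training split's 0.01st and 99.99th percentiles, then
   standardized. The clipping/standardization details (mean/std after
   clipping vs median/IQR) are ambiguous in common usage; mean/std is
   the default and median/IQR is available via `RobustScaler(center=
   "median")`. With a few hundred training samples the extreme
   percentiles interpolate near the training minimum/maximum, so
   clipping mainly guards against isolated spikes.
3. **FIR expansion (fMRI).** Word features are summed into the TR bin
   containing their onset and five delayed copies (2, 4, 6, 8, 10 s) are
   stacked horizontally, so the hemodynamic lag is estimated, not
   assumed. Delays must be TR multiples; anything else is a
   configuration error.
4. **Ridge with exact LOO λ selection.** For every λ on a 20-point grid
   log-spaced in [10⁻³, 10⁸], the leave-one-out residuals on the
   training split are computed in closed form from one SVD of X via the
   hat-matrix identity e_i = (y_i − ŷ_i)/(1 − h_ii); the λ minimizing
   LOO MSE is selected independently per target dimension. This is
   mathematically identical to an explicit refit-without-each-sample
   loop (asserted to 10⁻⁸ in the tests) and costs one SVD rather than n
   refits. No intercept is fitted — both sides are centered by their
   scalers.
5. **Scoring.** Pearson r between held-out truth and prediction, per
   voxel (fMRI) or per channel × time sample (MEG; the model is fitted
   independently at each sample). Zero-variance targets score 0 with a
   degenerate flag. Fold scores are averaged.

**Leakage control.** Folds partition 5-sentence blocks (words of a block
never straddle the split), scalers are fitted on training data only, and
— specific to fMRI — a scan enters a fold only if all its delayed word
contributions come from that fold's blocks; scans at block seams that
mix folds, and scans receiving no contribution, are excluded from both
training and testing. Train/test disjointness is asserted inside the
scoring functions (hard failure).

## Noise ceiling (shared response model)

The ceiling replaces the embedding with the average response of all
other subjects who read the same sentences, robust-scaled, through the
identical ridge + scoring pipeline. In fMRI mode no FIR expansion is
applied: template and target live on the same scan grid and carry the
same hemodynamic lag; the seam-exclusion window uses delays 0–10 s so
lagged responses near block boundaries stay out of both splits. In MEG
mode the template is fitted per time sample. An optional linear source
projection K is applied to both measured and predicted responses before
correlation, yielding per-source scores. Subjects may have seen
different sentence subsets; the ceiling restricts to sentences the
target shares with at least one other subject and errors if none exist.

## Synthetic generator

The generator is the package's substitute for restricted-access
recordings; its defaults encode the emulated study conditions.

* **Stimuli.** Sentences of 9–15 words in blocks of five; word durations
  drawn from a shifted gamma (shape 2) with mean 351 ms, floor 300 ms,
  clipped at 1400 ms; 300 ms inter-word gaps, 5 s between sentences.
  Tokens are pseudo-words sampled with Zipf-like frequencies from a
  250-type vocabulary so word types repeat (needed for lookup layers).
  The gamma is a modelling choice: only the mean and range of the
  emulated protocol are known, and a floored, right-skewed distribution
  is the natural shape for per-word presentation times.
* **Embedding families.** Three nested signal levels per word: word-form
  features (character-level descriptors), a lexical lookup (one Gaussian
  vector per word type, blended with a projection of the word-form
  features so "word embeddings" implicitly carry visual information),
  and a compositional level — the causal exponentially decaying average
  (decay 0.7) of the lexical vectors within the sentence so far. A
  family indexed by (checkpoint t, layer l) has values
  (1 − α_t)·noise + α_t·S_l, where S_l ramps linearly from lexical
  (l = 0) to compositional (deepest l) and α_t follows a configurable,
  by default linear and required-monotone, mixing curve. The planted
  "top-1 accuracy" of checkpoint t is accuracy_max·α_t with
  accuracy_max = 0.45, in the range reported for small masked/causal
  transformers. This accuracy is a *label*, not a measured prediction
  accuracy; convergence analyses are validated against it.
* **Brain responses.** A shared forward map G (o × channels, Gaussian,
  zeroed on non-responsive columns; half the channels responsive by
  default) drives all subjects. fMRI: binned word features pass through
  a FIR kernel — by default a **one-hot delay** (6 s unless specified)
  rather than a double-gamma HRF, so delay-recovery tests have an exact
  target; a smooth multi-delay option exists for realism. MEG: the
  projected features appear at the epoch sample nearest a configurable
  latency (default 400 ms), zero before onset, on a −0.5…2.0 s axis at
  10 ms × 10 steps (26 samples). Per-subject white noise is rescaled so
  the responsive-channel variance ratio equals the requested SNR
  *exactly* (the sampled noise is renormalized per channel), and a
  configurable fraction of the noise variance is shared across subjects,
  inducing inter-subject correlation beyond the common signal. Noise is
  white by default; the generator does not model AR(1) spectra, spatial
  autocorrelation, or sensor physics.

What passing tests therefore show: the *pipeline* recovers planted
linear structure, controls leakage, and calibrates its statistics. What
they do not show: robustness to temporally autocorrelated noise,
non-linear hemodynamics, or realistic channel covariance — real-data
effect sizes cannot be inferred from the synthetic ones.

## Extraction protocol

Activations are extracted causally: the vector for word i of sentence s
is computed from the words of at most the three preceding sentences plus
words 1…i of s. Contexts never include future words, never cross run
boundaries, and deliberately do cross block boundaries (blocks exist for
cross-validation, not presentation). Layer 0 of a provider is a
non-contextual lookup; the toy contextual provider implements deeper
layers as normalized causal exponential mixtures with a decay that
flattens with depth, so context integration grows with depth. "Middle
layers" of an n-layer model are the integer depths in [n/2, 3n/4],
inclusive on both ends (a 12-layer model: {6, 7, 8, 9}).

## Downstream analyses

* **Gain.** ΔR = R_M1 − R_M2 elementwise on a common target grid;
  degenerate flags are unioned. Comparisons are raw differences; an
  optional residualization mode (regress M2 out of M1 on the training
  words) exists but is not the default.
* **Convergence.** Per subject, the Pearson correlation between each
  checkpoint's spatially averaged brain score and its planted accuracy
  (or training step). Constant inputs yield r = 0 with a degenerate
  flag, never NaN; the constancy check uses a 10⁻¹² relative tolerance
  to absorb floating-point summation noise.
* **Permutation importance.** Per subject, a random forest (500 trees by
  default; forest size is a stability choice, not tuned) maps seven
  model properties — task (binary-encoded), heads, layers, dim, training
  step, accuracy, layer position — to average brain scores under 5-fold
  CV across models; importance of a feature is the mean decrease in
  held-out Pearson R over 50 within-fold shuffles, averaged across
  folds. Shuffling within the held-out fold is the standard permutation
  contract; shared information between features (e.g. accuracy and
  training step) splits importance between them, which is documented
  behaviour, not asserted beyond sign.
* **Group statistics.** Two-sided Wilcoxon signed-rank across subjects
  (zeros dropped — Wilcoxon's original rule; exact null for n ≤ 25
  without ties, tie-corrected normal approximation otherwise) with
  Benjamini–Hochberg FDR across all locations of a map jointly — for
  MEG, space and time are pooled in one correction. Locations degenerate
  in any subject are excluded from testing but keep their mean/SEM.

## Numerical and degenerate-input choices

* Word indexing 0-based; onsets in seconds; time axes half-open.
* LOO denominators 1 − h_ii are floored at 10⁻³⁰⁰ (h_ii → 1 only when a
  sample is self-determining; the exploding LOO error correctly
  penalizes that λ).
* λ ties in selection resolve to the smaller grid value (argmin of the
  LOO curve).
* Pearson scores are clipped to [−1, 1] to absorb rounding.
* Scalers require ≥ 2 samples; ridge requires ≥ 2 training samples;
  cross-validation requires at least one block per fold.

## Study sizes in the validation suite

The recovery studies run on compact problems — 25 sentences (5 blocks),
4–6-word sentences where only timing structure matters and 9–15-word
sentences where word statistics matter, 10–20 channels, 6–8 embedding
dims, 20 subjects for group tests, 200 voxels × 200 replicates for the
FDR calibration. These sizes were chosen once as the smallest problems
on which the planted effects are unambiguous; the planted conditions
(SNR levels, responsive fraction, mixing curves) follow the emulated
protocol and were not adjusted against test outcomes.

## Known limitations

* The fMRI scan-grid construction (rather than per-word samples) is the
  only construction consistent with the FIR design; per-word fMRI
  responses are not supported.
* The MEG ceiling fits an n×n channel map per time sample, which is
  quadratic in channels and meant for desk-scale channel counts.
* The per-subject sentence-assignment scheme of the emulated protocol is
  unspecified; the generator supports arbitrary assignments and defaults
  to all subjects seeing all sentences.
* Supplementary-style orthogonalization variants beyond the single
  residualization mode, atlas parcellation, and preprocessing of real
  recordings are out of scope.
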