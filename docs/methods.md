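# Methods

This note records the model, the synthetic data-generating process, the
numerical conventions and the deliberately open design choices behind
`blendspec`. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Problem and model

The task is targeted screening of blends of plant varieties of a *single
species* from IR spectra: for each variety of interest, decide presence
(binary PLS-DA) and, when present, estimate its percentage (PLS1
regression). Binary one-variety-at-a-time models are preferred over a
global multi-response model because the model set stays modular (a new
variety adds one model pair without invalidating the rest) and each model
is cheap enough for portable instruments.

PLS1 is implemented with the NIPALS recursion (weights from the covariance
`X'y`, scores, x/y-loadings, rank-one deflation of both X and y). X and y
are always mean-centred inside the model, *after* any pre-treatment; this
makes autoscaling's centring idempotent and costs nothing for the other
recipes. The coefficient form `b = W (P'W)^-1 q` and the score recursion
agree to 1e-10 (tested), and a full-rank fit reproduces the ordinary
least-squares oracle to 1e-8. If y is fully deflated before the requested
number of components, extraction stops early and the model carries a
warning flag instead of propagating NaNs.

PLS-DA encodes membership as 0/1 and calls a sample positive iff its
predicted response exceeds 0.5 strictly. The 0/1-with-0.5 convention is a
documented choice (it is symmetric under class swap), not inferred from
any reference output; no probability calibration is applied.

## Pre-treatments

Six recipes: `autoscale`, `snv`, `d1`, `d2`, `snv_d1`, `snv_d2`.

* SNV normalises each spectrum to mean 0 / SD 1 (SD with n−1 denominator
  everywhere in this package, for consistency with the RPD definition).
  Constant spectra are rejected by name.
* Savitzky–Golay derivatives use a second-order polynomial and a 17-channel
  window (defaults; both configurable). Edge channels without a full window
  are truncated rather than extrapolated — a window of 17 drops 16
  channels. Derivatives are scaled per cm⁻¹, making them invariant to grid
  resolution. In the combined recipes SNV precedes differentiation.
* Autoscaling is the only statistics-bearing step: channel means/SDs come
  from the training set only and are reapplied unchanged to validation and
  screening spectra (leakage is tested by mutating test data and asserting
  the training output unchanged). Channels with numerically zero training
  SD (< 1e-12) carry no information and map to 0 instead of raising, so
  derivative-flattened regions are not fatal.

## Splitting and validation

The duplex algorithm assigns maximally distant sample pairs (Euclidean
distance in the raw, region-cut but un-pre-treated spectral space)
alternately to training and test, starting with training, until the test
set is full; the remainder joins training. Distances are computed once per
dataset and shared by all six recipe runs. Two tie-breaks are fixed for
determinism: equally distant pairs resolve to the lexicographically
smallest index pair, and an odd final test slot takes the pair member with
the larger minimum distance to the already chosen test samples (lower index
on ties). The test size defaults to `round(0.2 n)`.

Complexity is selected by 10-fold cross-validation on the training set.
Folds are a seeded shuffle followed by contiguous blocks of size ⌊n/k⌋ or
⌈n/k⌉; for classification the assignment is stratified (positive counts per
fold within one of proportionality) to avoid single-class training parts on
near-balanced sets; if one still occurs the assignment is re-seeded once.
Every fold re-fits the pre-treatment statistics and the PLS model on its
own training part; held-out predictions are pooled before computing
RMSECV (and pooled CCR for classification). The selected complexity is the
RMSECV argmin with ties (within 1e-12) going to the simpler model. The
ceiling is 15 latent variables, capped at `n_train − ⌈n_train/k⌉ − 1`.

The best pre-treatment is chosen primarily on the external test criterion
(minimum RMSEP, or maximum test CCR), with ties — equality after rounding
to 4 decimals — broken by the CV criterion, then by fewer latent variables,
then by recipe order. Selecting on the test set re-uses it; the winning
recipe's test criterion is therefore an optimistic estimate. This is the
emulated study's own design and is kept deliberately.

RPD = SD(test references, n−1)/RMSEP and RER = range(test references)/
RMSEP. Bands: RPD < 1.5 poor, 1.5–2.0 rough screening, 2.0–2.5 approximate,
2.5–3.0 good, > 3.0 excellent; RER < 5 poor, 5–10 acceptable, > 10
excellent (boundaries left-closed at the lower edge; a perfect fit yields
infinite ratios and the "excellent" band). Undefined classification ratios
(zero denominator) are NaN with a warning, never 0.

## Limit of detection

The chosen classifier is applied to the variety's trituration series
(1/2/5/8 % spikes in an equal quinary background, pre-treated with the
*training* statistics). The LOD is the smallest level from which all higher
levels are also positive (monotone-tail rule); an isolated positive below
it is reported in the flags but does not lower the LOD, and "no level
positive" is reported as ">8%". The monotone-tail rule resolves the
ambiguity of "lowest level classified positive" under non-monotone flags.

## Synthetic data generator

The generator defines the study conditions; it is not tuned per run.

* **Grids**: NIR 4000–10000 cm⁻¹ at 8 cm⁻¹ (751 channels); mid-IR
  fingerprint 650–1998 cm⁻¹ at 4 cm⁻¹ (338 channels). In mid-IR mode the
  workflow cuts to 650–2000 cm⁻¹ (inclusive) before anything else.
* **Endmembers**: each of the six variety spectra is one shared sum of 30
  Gaussian bands plus `similarity_delta` (default 0.15) times a
  variety-specific sum of 8 bands; centres uniform on the grid, widths
  uniform in 20–150 cm⁻¹, amplitudes uniform in 0.1–1.0. The shared
  backbone dominates, so pairwise endmember correlations exceed 0.9
  (tested), emulating varieties of one species.
* **Mixing**: clean blend spectra are Beer–Lambert linear,
  `x = Σ_v (p_v/100) e_v`, so noise-free parameter recovery is an exact
  testable limit (a 50/50 blend equals the mean of the pures to 1e-12).
* **Instrument effects per sample**: multiplicative scatter `exp(g)` with
  `g ~ N(0, 0.05²)` (log-normal, always positive — what SNV removes), an
  affine baseline `b0 + b1·ν_scaled` with `b0, b1 ~ N(0, 0.01²)` on the
  grid mapped to [−1, 1] (what derivatives remove), and white noise
  `N(0, 0.001²)` per channel. One measurement per sample by default;
  replicates are a config option.
* **Designs**: complete enumeration gives 63 equal-proportion subset rows
  (6 pures + 15 binary + 20 ternary + 15 quaternary + 6 quinary + 1 senary)
  plus 24 triturations = 87 samples. "Commercial-like" screening unknowns
  blend 2–4 varieties with lognormal weights normalised to 100 %, giving
  the uneven composition ranges of real products.
* **Determinism**: every random draw derives from one integer seed through
  named `SeedSequence` streams (endmembers, calibration synthesis,
  screening synthesis, designs), so identical configs reproduce all outputs
  byte-identically.

The per-variety sample sets follow from the composition table: the
qualitative models train on the 63 equal-proportion rows (positives are
the 32 rows containing the variety at ≥ 16.7 %); the quantitative models
train on *all* rows containing the variety — 32 subset rows plus all 24
triturations (each trituration contains all six varieties), i.e. 56
samples spanning 1–100 %, with `round(0.2·56) = 11` duplex test samples.

## What the synthetic world does and does not show

Passing tests demonstrate that the pipeline machinery is correct and that,
under low-noise linear mixing, the workflow attains perfect external
classification and sub-percent proportion errors. They do not demonstrate
performance on real spectra: real varieties differ by correlated,
nonlinear, batch-dependent features, real products contain additives and
moisture, and real proportions are uneven. Two visible consequences of the
linear synthetic world:

* regression is *easier* than in reality (the response is an exact linear
  functional of the clean spectrum), hence RMSEP values far below what
  measured spectra would give;
* the classifier LOD is *conservative*: with nearly linear score-versus-
  proportion behaviour, spikes at 1–8 % score well below the 0.5 threshold
  trained on the ≥ 16.7 % design, so the default run reports LODs of
  ">8%" rather than the few-percent LODs achievable on measured spectra
  where class separation is not proportional.

## Problem sizes and defaults

The shipped defaults are the full emulated design: 87 calibration samples,
751 NIR channels, 6 varieties × 2 tasks × 6 recipes × 10-fold CV with up to
15 latent variables — a few seconds end to end on one CPU, so no stage is
scaled down anywhere in the tests or the acceptance script.

## Known limitations

* The decision threshold is fixed at 0.5; no ROC-based or Bayesian
  threshold tuning.
* No replicate-aware validation (replicates, when enabled, are treated as
  independent samples).
* No feature/wavelength selection, MSC, OSC or orthogonal PLS variants —
  the whole (region-cut) spectrum is modelled by design.
* The generator makes no attempt at band-assignment realism (Gaussian
  shapes only); it targets the statistical structure the pipeline must
  handle, not spectroscopic fidelity.
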