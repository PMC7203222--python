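# Methods

This note documents the models and procedures implemented in `eemlearn`, the
assumptions behind them, the defaults and why they were chosen, and what the
synthetic-data tests do and do not demonstrate.

## Data model

An EEM is stored as an `[emission rows × excitation columns]` matrix on
uniform wavelength grids (the default acquisition geometry is excitation
250–790 nm and emission 260–800 nm in 5 nm steps, i.e. 109 × 109 points).
Missing cells are tracked by an explicit boolean mask — never by a sentinel
value — because a zero intensity is a legitimate datum after sub-diagonal
zeroing. A dataset is the three-way stack `X (I × J × K)` over samples with a
*global* missing mask, the union of the per-sample masks: a cell enters the
model only if every sample measured it. After pre-processing the excised
first-order Rayleigh band is identical across samples, so the union adds
nothing beyond that band.

Absorbance spectra are assumed measured at 1 cm path length and are linearly
interpolated onto the EEM grids; wavelengths outside the measured range
return absorbance 0 with a warning, on the reasoning that long-wavelength
absorbance of dilute cultures is negligible. Negative absorbance readings
(baseline noise) are clipped to 0 by default; a `reject` policy is available.

## Pre-processing

Stages, their defaults, and the reasoning:

| stage | rule | default |
|---|---|---|
| inner-filter correction | multiply each cell by `10^((A(ex)+A(em))/2)` | applied whenever `max A > 0` |
| first-order Rayleigh | `\|em − ex\| ≤ w₁` → missing | `w₁ = 15 nm` |
| second-order Rayleigh | `\|em − 2·ex\| ≤ w₂` → linear interpolation along emission | `w₂ = 15 nm` |
| sub-diagonal zeroing | `em < ex` (strict) → 0, marked present | always |

The ±15 nm halfwidths are conventional for 5 nm-step EEMs, not physical
constants; both are configurable. Second-order interpolation is 1-D per
excitation column between the nearest non-missing flanking cells; if the band
touches the grid edge the affected cells become missing instead. Where the
zeroed lower triangle overlaps the first-order band, zeroing wins, so final
spectra carry an explicit zeroed triangle rather than a missing wedge.

**Stage order.** The default order is IFE → first-order excision →
second-order interpolation → zeroing. The inner-filter correction is
multiplicative on *measured* intensities, and the scatter interpolation
should operate on corrected values, so IFE runs first; the order is exposed
in `PreprocessConfig.order` for users who disagree. With threshold 0 the IFE
stage is skipped only for identically zero absorbance, where it is the
identity anyway, so the order question is moot in that case.

## N-PLS (tri-PLS1)

For a single response `y` (modelled on the log10 scale when the raw values
span decades), each latent variable f is extracted as:

1. `Z_jk = Σ_i y_i X_ijk` over included cells (`y` is the current residual,
   `X` the current deflated tensor);
2. `(w_f^J, w_f^K)` = dominant left/right singular pair of `Z` — the rank-1
   structure maximising score–response covariance;
3. scores `t_if = Σ_jk X_ijk w_fj^J w_fk^K`;
4. inner regression: `y` regressed (least squares) on *all* scores so far —
   re-estimated at every LV, as in the original sequential algorithm;
5. deflation: `X ← X − t (w^J ⊗ w^K)`, `y_res ← y_c − T b`.

`X` is centered over samples but not scaled (standard for spectral data,
where cell variances are physically comparable); `y` is centered.

Numerical choices:

* **Sign indeterminacy** of the singular pair is fixed by making the
  largest-magnitude element of the emission weight positive (flipping both
  weights together), so repeated fits are bit-identical.
* **Rank deficiency**: if the deflated covariance `Z` collapses below
  10⁻¹² of its first-LV magnitude (or a score norm vanishes), the model
  truncates at the last usable LV with a `RankDeficiencyWarning` instead of
  fabricating noise components.
* **SVD driver**: the divide-and-conquer LAPACK driver occasionally fails to
  converge on perfectly finite matrices; the model falls back to the slower
  QR-based driver when that happens.
* **Missing cells** in the training mask are excluded from centering and all
  inner products (no imputation machinery). Cells missing sporadically in
  *new* data but included in the model are set to the training mean (0 after
  centering) with a warning.

Prediction on new samples replays the same sequential scoring and deflation
with the stored weights, so predicting the training tensor reproduces the
fitted values exactly. Because every step is linear in the centered tensor,
the model folds into a single coefficient map `B` with intercept
`b₀ = ȳ − ⟨B, X̄⟩`: score f is `r_f' x` with
`r_f = (I − w₁w₁')⋯(I − w_{f−1}w_{f−1}') w_f` and `B = Σ_f b_f r_f`. The map
is verified two ways in the tests — against `predict()` on random tensors and
against finite-difference probing of single cells.

A useful identity checked in the tests: on a tensor with a single excitation
column (K = 1) the model's fitted values and predictions coincide with
single-block PLS1 to machine precision. The *score vectors* of the two
algorithms differ (weight-deflation versus loading-deflation bases — a known
property of PLS1 variants); the predictions are invariant.

## Validation

* **Fold plan**: a seeded permutation split into near-equal folds (first
  `n mod k` folds take the extra sample). For n = 92, 76, 72 and k = 4 this
  gives validation folds of exactly 23, 19, 18.
* **Inner LOOCV**: for each left-out training sample one model is fitted at
  the maximum complexity and its nested truncations provide predictions at
  every F — identical, bit for bit, to refitting at each F separately, but
  ~`max_lvs`-fold cheaper. RMSECV(F) is the root mean square of the n LOOCV
  errors; the chosen F minimises it, ties broken toward fewer LVs
  (parsimony). `max_lvs` defaults to 12 and is clipped to training size − 2
  with a warning.
* **Metrics**: `RMSEP = √mean((obs − pred)²)`; R² and slope from the OLS
  regression of predicted on observed (for simple OLS this R² equals squared
  Pearson correlation; the predicted-on-observed orientation is a documented
  choice — the reverse regression gives a different slope);
  `relative error % = 100·RMSEP / mean(obs)`. All metrics are on the
  modelling (log10) scale. Constant observations yield NaN for R²/slope
  rather than an arbitrary number.
* **Final model**: refit on all samples at the validated complexity; when
  folds disagree, the mode of their choices is used, ties to the smaller F.

The double CV is fully deterministic given its seed; reports serialize to
JSON plus a per-sample CSV of out-of-fold predictions.

## Synthetic data generator

The generator emulates the statistical structure the pipeline assumes, at
ground truth known exactly:

* **Fluorophores** (defaults): a chlorophyll-like pigment (ex 440/40 nm,
  em 683/12 nm, brightness 1000), a protein-like fluorophore (ex 280/12,
  em 340/25, brightness 600), and an accessory pigment (ex 490/30, em 660/20,
  brightness 400). Each is a rank-1 outer product of peak-normalised
  Gaussians — an analytic simplification; real pigment spectra are
  multi-peaked and excitation/emission shapes are not exactly separable.
* **Concentrations**: log-uniform per component, default range 1–3
  (≈3-fold), the within-run variation scale typical of a batch cultivation;
  responses are `intercept + Σ coef·log10(conc) + noise` with default
  intercept 6, loading 1.0 on the pigment only, and noise sd 0.02 log units.
* **Scatter**: additive Gaussian ridges along `em = ex` and `em = 2·ex`
  (sd 8 nm), peak amplitude 10 000 — an order of magnitude above the signal,
  so unhandled scatter visibly destroys the regression — with a per-sample
  ×U(0.5, 1.5) amplitude jitter, reflecting that scatter intensity is not
  proportional to analyte content.
* **Inner-filter attenuation**: each sample's absorbance is the
  concentration-weighted sum of Gaussian component absorption bands
  (default peak absorptivities 0.05/0.04/0.03 per concentration unit, total
  A ≈ 0.15–0.3 — the regime where the correction matters but intensities stay
  measurable); the whole noisy tensor is multiplied by
  `10^(−(A(ex)+A(em))/2)`, the exact inverse of the downstream correction, so
  the round trip is testable to 10⁻¹⁰.
* **Noise**: iid Gaussian with sd = (median per-sample peak clean
  intensity)/SNR, default SNR 50.

All randomness flows from one mandatory seed.

**What passing tests show — and don't.** The headline recovery property
(default configuration, n = 60: pooled double-CV validation R² ≥ 0.9 for the
pigment-loaded response) demonstrates that the pipeline is internally
consistent: pre-processing removes exactly the artefacts the generator
injects, and the regression recovers a response that is genuinely (log-)
linear in a tri-linear signal. It does not demonstrate performance on real
cultures, where spectra are non-Gaussian and non-separable, absorbance is
measured with error, scatter has structure (Raman, particulates) the
generator omits, and the response–fluorophore link is indirect. One inherent
limitation is visible even in simulation: the model is linear in intensities
while responses are linear in log-concentration, so recovery degrades as the
concentration range widens beyond about a decade.

## Problem sizes

The test suite runs on small grids (≈10 × 12 to 50 × 31) for unit and
property tests, and one full-scale end-to-end check (109 × 109 grid, 60
samples, 4-fold double CV with LOOCV inner loops, ≈ 7 s); the whole suite
completes in well under a minute. These sizes were chosen as the smallest
that exercise every code path at full fidelity.

## Other design notes

* Model files are a single JSON document (arrays as nested lists): models are
  small (≤ a few hundred KB) and a text format keeps bundles portable and
  diffable.
* Coefficient maps export in the same CSV grid dialect as EEMs, so any EEM
  heat-map tooling can plot them; excluded cells are blank.
* The Arnaud chlorophyll equation returns negative values (bad extracts)
  as-is with a warning — clamping would hide assay failure. Per-cell
  chlorophyll normalisation requires cell counts and is left to the user's
  response table.
* No Raman scatter handling, blank subtraction, Raman-unit normalisation,
  PARAFAC, or multi-response (PLS2) fitting; each response is modelled
  separately.
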