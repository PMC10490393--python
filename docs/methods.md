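# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of the package.

## Light-response model

The modified rectangular hyperbola

    A(I) = alpha * (1 - beta*I) / (1 + gamma*I) * (I - Ic)

is used because it yields all four summary indicators from one fit: the
light compensation point LCP = Ic µmol m⁻² s⁻¹ (A(Ic) = 0 identically), the
light saturation point LSP as the numerical argmax over [0, 2000]
µmol m⁻² s⁻¹ (bounded scalar minimization, xatol 1e-6; the 2000 cap sits
above the analyzer program's 1800 maximum, and fits pinned at the cap are
flagged), A_max = A(LSP), and the apparent quantum efficiency
AQE = A′(0) = alpha·(1 + (beta+gamma)·Ic). An alternative AQE — the OLS
slope over PAR ≤ 200 — is available behind a flag. The fit is bounded
nonlinear least squares (alpha ∈ [1e-6, 1], beta ∈ [0, 5e-3],
gamma ∈ [0, 5e-2], Ic ∈ [0, 500]; ftol/xtol/gtol 1e-10), initialized from
the initial secant slope (alpha), the first PAR level with positive
assimilation (Ic), and beta = 1e-4, gamma = 1e-3. The 18-step PAR program
retains its duplicate levels as replicate points; nothing is averaged before
fitting. A negative fitted maximum raises a degenerate-fit error carrying
the last iterate.

## PAM quenching parameters

The standard saturating-pulse ("lake model") definitions are adopted:
Fv/Fm, Fv′/Fm′, qP, qL = qP·F0′/Fs, qN = (Fm−Fm′)/(Fm−F0′),
Y(II) = (Fm′−Fs)/Fm′, Y(NPQ) = Fs/Fm′ − Fs/Fm, Y(NO) = Fs/Fm. These satisfy
Y(II)+Y(NPQ)+Y(NO) = 1 exactly, which has a practical consequence: the
three yields are linearly dependent, so the fluorescence family's
correlation matrix is singular by construction and the family PCA reports a
reduced component count (with a warning). Values that stray outside [0, 1]
by less than 1e-9 from floating-point rounding are clamped; larger
violations raise.

## 3FLD retrieval

Shoulder weights are the linear-interpolation weights
ω_left = (λ_right−λ_in)/(λ_right−λ_left), ω_right = 1−ω_left (they sum to 1
identically). Band values are taken at the nearest grid point — at 1.4 nm
instrument resolution sub-band interpolation adds nothing; a linear
interpolation mode and an auto-centering option (snap λ_in to the
minimum-irradiance grid point within ±2 nm) exist behind flags. Default line
positions are O₂-B (684, 687, 697 nm) and O₂-A (758, 760.5, 770 nm),
configurable. The retrieval is exact whenever the reflectance factor and
fluorescence are constant across a line's three bands, and rSIF normalizes
each line's F by the same line's incident irradiance.

## CSPC construction and grading

Standardization uses the population-SD convention (recorded in output
metadata), and PCA is computed on the correlation matrix (eigenvalue sum
equals the variable count). Component signs are arbitrary; each component is
flipped, if needed, so its loading on the first available reference feature
(rSIF_O2B, then WUE, then Y(II)) is positive. Per family the max-|loading|
variables on PC1 and PC2 are the characteristic indicators (with a
next-largest fallback if both picks coincide). The composite PCA retains the
minimal k components reaching 85 % cumulative variance. Component scores use
the loadings directly as weights, and the composite weights are
W_k = P_k/100, i.e. percent contribution over *total* variance — this
convention reproduces the published weight arithmetic (57.167 % → 0.572)
exactly. A loading/√eigenvalue score weighting is available as an option
(`pc_scores(..., weighting="eigen_scaled")`), but the default is fixed by
that arithmetic.
Grading uses half-open intervals of width SD/2 anchored at the cohort mean
of zero, lower bounds inclusive: level 0 for CSPC ≥ width, levels 1–4 on
successive descending intervals, level 5 below −3·width. A fixed width
(canonically 0.54) can override the SD/2 rule for scoring new samples under
a stored scheme. Boundary comparisons carry a 1e-9 tolerance so printed
3-decimal scores on exact boundaries grade deterministically.

Scoring new samples reuses the stored means/SDs, loadings, weights and
scheme; nothing is refitted.

## Spectral feature screening

Smoothing is Savitzky–Golay with window 13 and cubic polynomial; edges are
handled by fitting the polynomial on the truncated window. Continuum removal
divides by the linearly interpolated upper convex hull (monotone-chain), so
endpoints and hull-contact bands are exactly 1. First derivatives are
central differences per nm with one-sided edges. Wavelet "coefficient
spectra" are realized as per-band reconstructions of each level's detail
coefficients (CD1–CD6, bior1.3, symmetric extension): features are then
reported at native wavelengths, and approximation + ΣCD reconstructs the
input to machine precision. Six levels on 224 bands exceed the usual
dwt_max_level recommendation; the decomposition remains perfectly
reconstructable and the coarsest levels are simply smoother. For coarse
scales (CD2+) the extremal band is reported with its 2^(level−1)-band
support window, mirroring range-style reporting. Correlation screening uses
all cohort samples before the train/validation split; the selected features
therefore see the validation targets during screening, a leakage the
original screening-then-modeling order shares — the validation metrics
measure the inversion step, not a fully held-out pipeline. Zero-variance
bands are flagged and given r = 0; Ba/Bb ties break toward the shorter
wavelength; ratio and normalized indices are flagged missing where the
denominator is below 1e-12 and excluded pairwise from correlations. Scheme
count is fixed at 21 = 3 transforms × (origin + 6 detail levels).

## Inversion models

RF: 100 trees, raw features. SVR: RBF kernel, gamma 0.1, C 1.0, epsilon
0.1, standardized features. Ridge: alpha 1.0, standardized features. The
backprop network is an MLP with hidden layers (12, 12, 24, 24, 48, 48, 6, 6),
ReLU, Adam at learning rate 1e-3, trained for up to 1500 iterations on
standardized features, with L2 weight decay (alpha 1e-4) as the
regularizer. All fits are seeded. The split is a seeded uniform partition
(352/80 at the default cohort size, scaled proportionally otherwise). R² is
reported in two forms, the standard 1 − SSE/SST and the variance-ratio
Σ(ŷ−ȳ)²/Σ(y−ȳ)², because published R² values of this kind are often
ambiguous between the two; the standard form drives model comparison.

## Synthetic cohort generator

The generator emulates the 2-cultivar × 4-temperature (25/15, 20/10, 15/5,
10/0 °C) × 3-duration (3/6/9 d) design with 18 replicates per cell
(432 records). A scalar latent stress s ∈ [0, 1] per cell is a per-level
severity (CK 0, T1 0.30, T2 0.60, T3 0.85) times a duration ramp
(0.75/1.00/1.20), times a cultivar susceptibility (short-day 0.90, long-day
1.00), minus a fixed recovery term (0.20) for the short-day cultivar after
9 days at T1 — encoding the acclimation rebound of cold-tolerant short-day
plants under mild chilling. Controls sit at zero stress; stress is
non-decreasing in severity at fixed duration; the long-day worst case is
the 9-day severest treatment.

All measurement means are piecewise-linear (mostly linear) in s with
directions matching the observed physiology: A_max, LSP, AQE, gs, E, WUE,
Fv/Fm, Y(II), SIF and rSIF fall with stress; LCP, qN, ci/ca rise. PAM raw
levels are constructed from target derived values (Fm = 1000,
Fv/Fm = 0.83 − 0.08s, qN = 0.03 + 0.35s, Y(II) = 0.72 − 0.10s) so the
derived parameters shift monotonically. Reflectance (224 bands,
410.49–990.07 nm) is a smooth healthy-leaf template (green peak, red
trough, red edge, NIR plateau) with stress perturbations concentrated in
the chlorophyll region (576–615 nm, +0.07s) and the NIR (−0.055s broad,
plus a narrow −0.018s feature near 882 nm) — the planted signal the
screening stage is expected to find. SIF spectra (645–800 nm, 0.7 nm grid)
have two Gaussian absorption wells, a constant per-record reflectance
factor, and a two-peak emission spectrum scaled down by stress
(O₂-A > O₂-B always); the emission is flattened to its line-center value
inside each retrieval window so that noise-free 3FLD recovery is exact,
and the truth at both line centers is recorded per record.

Noise is independent Gaussian per measurement with base SDs at realistic
lab CVs (~3–5 % of healthy means: A ±0.25–0.3, gs ±0.006, E ±0.06, ci ±6,
PAM levels ±5 units, radiance ±0.1, reflectance ±0.004 per band), all
multiplied by a single `noise_scale`; a record-to-record illumination factor
(CV 8 % × noise_scale) multiplies irradiance and emission jointly, which is
what makes rSIF informative beyond SIF. Seeding uses one master seed with
per-record SeedSequence spawn keys from (cell, replicate), so cohorts are
bit-reproducible and extensible.

What passing tests do and do not show: the generator has linear
stress–response relationships, Gaussian noise, no replicate-to-replicate
biological variation beyond noise, no instrument drift, and a spectral
signal far cleaner than field leaves — so the near-perfect inversion metrics
demonstrate the pipeline's correctness, not the field accuracy of
hyperspectral chilling diagnosis.

## Problem sizes

The default cohort is the full 432-record design; the test suite mostly
uses a 96-record cohort (4 replicates per cell) and runs the full design
once in the end-to-end recovery test. These sizes keep the whole suite
around ten seconds on one CPU while exercising every stage at the design's
real shape.

## Known limitations

- No radiative-transfer leaf model; spectra are phenomenological templates.
- The light-response functional form of the original fits is not published;
  equivalence with the authors' fitted LCP/LSP/A_max values cannot be
  asserted, only the procedure.
- The published per-treatment score table is internally inconsistent with
  the published grading intervals in 3 of 24 cells; the implementation
  follows the interval definitions.
- Screening-stage leakage (see above) is inherited from the
  screen-then-model order.
- Grading of predictions assumes the training scheme transfers; no
  recalibration on new cohorts is attempted.
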