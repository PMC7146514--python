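# Methods

## Problem and workflow

`somvnir` estimates topsoil organic matter (SOM, g kg⁻¹) from laboratory
Vis-NIR reflectance spectra (350–2500 nm at 1 nm). The workflow is the
standard chemometric chain used in soil spectroscopy:

1. **Preprocessing** — trim to 400–2400 nm (instrument fringes are noisy),
   Gaussian-kernel resampling from 1 nm to 5 nm (2001 → 401 bands),
   Savitzky–Golay smoothing (order 2, window 11), and optionally continuum
   removal (division by the upper convex hull) to isolate absorption
   features.
2. **Partition** — a deterministic rank-ordered 2:1 split: sort by SOM,
   form consecutive triplets, send the middle member of each to
   validation. 168 samples → 112 calibration / 56 validation. A one-way
   ANOVA verifies the two sets are statistically comparable.
3. **Feature extraction** — (a) PCA scores ("1DV") of the
   continuum-removed calibration spectra, components retained by the
   cumulative-explained-variance > 95% rule with a floor of five;
   validation spectra are projected onto the calibration fit to avoid
   leakage. (b) The optimal band-combination search: for each of five
   two-band forms (SI = Rᵢ+Rⱼ, DI = Rᵢ−Rⱼ, PI = Rᵢ·Rⱼ, RI = Rᵢ/Rⱼ,
   NDI = (Rᵢ−Rⱼ)/(Rᵢ+Rⱼ)) and five three-band forms
   (TBI1 = Rᵢ/(Rⱼ+Rₖ), TBI2 = (Rᵢ+Rⱼ)/Rₖ, TBI3 = (Rᵢ−Rⱼ)/(Rⱼ−Rₖ),
   TBI4 = (Rᵢ−Rⱼ)/(Rᵢ+Rⱼ−2Rₖ), TBI5 = Rᵢ+Rⱼ−2Rₖ), Pearson r against
   calibration SOM is computed for every ordered combination of distinct
   wavelengths; the top 1% by |r| are retained; the final combination
   minimizes |r_cal − r_val| (stability between sets), with ties broken
   by larger |r_cal| then lexicographically smallest wavelengths.
4. **Models** — single-variable OLS per extracted feature, and random
   forests over six variable strategies: 1DV, 2DI, 3DI (five columns
   each) and their pairwise unions (ten columns). Forests use 1000 trees
   (200 in test-scale runs), node size 5, and m_try tuned by minimum
   out-of-bag RMSE on the calibration set (1–5 for single blocks, 1–10
   for unions; ties to the smaller value).
5. **Evaluation** — R² (squared Pearson correlation; the 1 − SSres/SStot
   variant is exported separately), RMSE, and RPIQ = IQR(observed
   validation SOM)/RMSE_val with quality categories A (> 4.05),
   B (3.37–4.05], C (2.70–3.37], D (≤ 2.70). Boundary values close
   downward. 95% confidence and prediction bands dress the 1:1 plots.

## Synthetic survey generator

No public dataset accompanies this kind of mining-area survey, so the
package ships a generator that reproduces the statistical structure such
an analysis assumes, with a planted ground truth so feature recovery is
testable.

**SOM marginal.** Truncated lognormal: (μ, σ) are moment-matched to mean
7.46 and SD 8.75 g kg⁻¹, then rejection-sampled into [0.26, 45.71]. This
reproduces positivity, strong right skew (≈ 2) and the heavy organic-rich
tail. Truncation lowers the realized mean to ≈ 7.0 g kg⁻¹; no
compensation is applied because the match is defined on the untruncated
distribution.

**Spectra.** For wavelength w and sample s:

    R_s(w) = B(w) · exp(−(k·SOM_s + γ₁ₛ)·v(w) − γ₂ₛ·h(w))
             · tilt_s(w) · Π_t (1 − d_t(SOM_s)·g_t(w)) · noise

- `B(w)`: smooth sigmoid baseline rising through the visible.
- `v(w)`: darkening weight, 1 over 400–700 nm, decaying to 0.01 outside
  (Gaussian shoulders, 150 nm scale on the long side). `k` =
  `darkening_strength` = 0.05 per g kg⁻¹: organic darkening is a
  visible-range chromophore effect.
- `γ₁, γ₂ ~ N(0, 0.25)`: two SOM-independent chromophore amplitudes with
  different spectral shapes (broad visible profile and a narrow
  blue-green band), emulating variable iron-oxide mineralogy. Two
  components are essential: with a single shared profile, a pair of
  visible bands can cancel the mineral factor and broad albedo
  differences become a spuriously clean SOM proxy, which real soils do
  not offer.
- `tilt_s(w) = 1 + t_s·(w − 1400)/1000`, `t_s ~ N(0, 0.05)`:
  SOM-independent spectral slope variability (particle size /
  scattering).
- Smooth continuum wiggles: five fixed broad Gaussian components
  (centers 1000–2400 nm, σ 250 nm) with independent per-sample
  amplitudes `~ N(0, 0.02)`, emulating moisture/texture-related baseline
  variation.
- A flat multiplicative albedo factor `~ N(0, 0.08)` and a flat additive
  baseline offset `~ N(0, 0.012)` — the classic nuisances SNV/MSC
  corrections target.
- Gaussian absorption troughs `g_t` at 1400 (σ 45), 1900 (σ 55) and
  2200 nm (σ 8, asymmetric: 0.75σ left / 1.2σ right — the 2.2 µm
  clay-lattice/organic feature is a sharp skewed doublet). The 1400/1900
  depths are fixed (0.25, 0.32); the 2200 nm depth is
  `0.05 + 0.006·SOM`, the planted SOM-linked signal.
- Noise: multiplicative N(0, 0.005), additive N(0, 0.001), then clipped
  to (0, 1]. Setting both noise SDs and
  `chromophore_sd`/`tilt_sd`/`albedo_sd`/`offset_sd`/`wiggle_sd` to zero
  gives the deterministic surface used by the monotonicity contracts.

The nuisance structure is what gives three-band indices their genuine
edge: no two-band form cancels both a flat multiplicative and a flat
additive factor (a difference kills offsets but not scatter; a ratio
kills scatter but not offsets), and the multi-component wiggles span more
nuisance dimensions than a handful of two-band features can jointly
absorb — while a local ratio-of-differences three-band index cancels
scatter, offset and smooth local baseline at once. This mirrors why
three-band indices outperform two-band ones on real soil spectra.

All randomness flows through one `numpy` Generator seeded from the
config; datasets are bit-reproducible per seed.

**What the generator does not emulate:** radiative transfer, specific
mineral spectra, moisture-dependent band shapes, instrument splice
artifacts, or any covariance between SOM and soil moisture/texture.
Passing recovery tests therefore show the *procedure* finds a planted
linear absorption signal under realistic interference — not that any
particular wavelength is diagnostic in real soils.

## Numerical choices

- Gaussian resampler: kernel σ = step/2.355 (FWHM = output spacing),
  truncated at ±3σ, edge-renormalized; outputs are convex combinations of
  inputs. Savitzky–Golay boundaries use one-sided polynomial fits, so
  grid length is preserved and degree-≤2 polynomials are fixed points.
- Continuum removal computes the upper convex hull by a monotone-chain
  scan keeping collinear points, interpolates it linearly, divides, and
  pins hull-touching bands to exactly 1. The operation is idempotent.
- Scan validity: a combination is invalid if wavelengths repeat, any
  sample's denominator magnitude is < 1e-12, any index value is
  non-finite, or the index variance is < 1e-12. Pearson r uses the
  two-pass centered formulation, so the chunked scan matches a naive
  per-cell loop to ≤ 1e-12 and chunking (over the first band axis, 64 MB
  working blocks by default) is bit-identical to an unchunked pass.
- Top-1% retention keeps ⌈0.01 · N_valid⌉ ordered combinations ranked by
  |r| descending, ties broken by lexicographic band order.
- The stability selection compares |r_cal − r_val| at a resolution of
  0.01 (the precision at which correlation coefficients are reported),
  breaking ties within a bin by larger |r_cal| and then lexicographically
  smallest wavelengths. The resolution matters: with ~10⁴ retained
  three-band candidates, some mediocre combination almost surely shows a
  freakishly small raw error, and an exact-minimum rule degrades into a
  lottery among stable-but-weak indices.
- m_try tuning uses *out-of-bag* RMSE, not resubstitution: for a random
  forest, resubstitution RMSE is nearly monotone in m_try and the tuning
  objective would be vacuous. Node size defaults to 5 (the common
  regression-forest default).
- Descriptive statistics: SD with n−1; IQR by linear-interpolation
  ("type 7") quantiles — the RPIQ definition depends on this choice;
  skewness/kurtosis are bias-corrected moment estimators, kurtosis on the
  non-excess scale.
- Degenerate conventions: two identical constant groups → ANOVA p = 1;
  constant predictions → R² = 0 with a warning; RPIQ undefined at
  RMSE = 0.

## Problem sizes used in tests and the acceptance run

Preprocessing always runs the full chain at 5 nm (2001 → 401 bands).
Exhaustive scans in tests and the acceptance script run on subsampled
band grids — 10 nm (201 bands) for two-band recovery checks, 20 nm
(101 bands) for three-band scans and the strategy comparison — and
test-scale forests use 200 trees. These sizes are the package's standard
quick-run configuration; the full 401-band, 1000-tree configuration is
the default of the library API itself.

## Known limitations

- The planted-feature recovery and strategy-ordering rates are properties
  of the simulated interference structure; different
  chromophore/tilt/noise settings change them.
- The stability selection (minimum |r_cal − r_val|) remains partly a
  lottery when many weak-but-consistent candidates enter the top 1%; the
  finite comparison resolution and the generator's interference design
  keep the planted feature dominant in that pool, which is the regime in
  which the procedure is meaningful.
- RPIQ category boundaries are conventions over strict inequalities;
  values exactly on a boundary are assigned to the lower category.
- R² reported as squared Pearson correlation can flatter models with
  scale bias; compare with the exported sum-of-squares variant when in
  doubt.
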