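# Methods

## Scope and model

`csidose` quantifies normal-tissue exposure along a pediatric craniospinal
radiotherapy pathway and its clinical consequence. Three stages are modelled:

1. **OSL dosimetry.** A carbon-doped alumina chip read by a stimulated-light
   reader returns a photon count proportional to absorbed dose. Per modality
   (planning CT, CBCT, megavoltage treatment beam) a calibration factor
   `k` (cGy/count) converts background-corrected counts to dose, further
   multiplied by beam-quality, linearity, angle and fading corrections:

   `D = (raw − background) · k · f_Q · f_lin · f_ang · f_fad`.

   `k` is the arithmetic mean of the per-point dose/count ratios over the
   calibration points, matching how single-factor OSL calibrations are
   usually quoted; a least-squares slope through the origin is available for
   comparison (it weights high-count points more, and the two coincide only
   for perfectly linear response). The relative SD of the per-point ratios is
   carried as the factor's uncertainty.

2. **Imaging-dose accounting.** For each organ the pathway deposits one
   planning-CT dose plus `n` CBCT doses (default `n = 15`, one positioning
   scan per ~2 fractions of a 30-fraction course):

   `D_img = D_CT + n · D_CBCT`, `u = sqrt(u_CT² + n · u_CBCT²)`.

   Repeated CBCTs are independent acquisitions, so their uncertainties add in
   quadrature (√n growth), not linearly. Totals are expressed as percent of
   the craniospinal prescription (36 Gy in 20 fractions) and of the total
   with the posterior-fossa boost (54 Gy); the 36 Gy column is the default
   reference because the published per-organ shares verify against it.

3. **Radiobiological comparison.** Per-organ treatment DVHs are reduced to
   Niemierko's equivalent uniform dose

   `EUD = (Σᵢ vᵢ Dᵢ^a)^(1/a)`

   with `vᵢ` the fractional volume in bin `Dᵢ` and `a` the tissue
   volume-effect exponent (`a = 1`: parallel organ, mean dose; `a ≫ 1`:
   serial organ, Dmax-driven; `a < 0`: target coverage, minimum-driven).
   The complication probability is the log-dose logistic

   `NTCP = 1 / (1 + (D50/EUD)^(4γ₅₀))`,

   exactly 0.5 at `EUD = D50`, with normalised slope `γ₅₀` at that point.

## Parameters

| parameter | unit | default | rationale |
|---|---|---|---|
| `n_cbct` | — | 15 | one positioning CBCT per ~2 fractions over the course |
| prescription | Gy | 36 + 18 boost | standard-risk craniospinal course, 20 + 10 fractions |
| `a`, `D50`, `γ₅₀` | —, Gy, — | per-organ file | see below |
| calibration factors | cGy/count | 2.937e-5 (CT), 4.7715e-5 (CBCT) | synthetic ground-truth defaults in the measured range |
| count CV | — | 0.05 | mid-range of observed replicate CVs (0.02–0.08) |
| organ imaging dose | mGy | uniform 3–8 | per-acquisition band measured on a pediatric phantom |
| dose table relative SD | — | 0.16 | ratio of quoted uncertainties to means in measured tables |

The bundled `data/ntcp_params.yaml` carries two kinds of entries, both
overridable by a user file: *literature* defaults (Gay–Niemierko/Emami-style
compilations, labelled by source) and *pair-derived* entries obtained by
inverting the sigmoid from published (mean dose, NTCP) pairs with
`fit_ntcp_params` — e.g. the heart pair (16 Gy, 30%; 6.6 Gy, 0.4%) implies
`D50 = 18.79 Gy`, `γ₅₀ = 1.318`. Pair-derived entries use `a = 1` because the
published figures quote mean organ doses; `a` is not identifiable from
(EUD, NTCP) pairs. The two-point inversion is closed-form on the logit scale
(`ln((1−N)/N) = 4γ₅₀ ln(D50/EUD)` is linear in log dose); more than two
pairs are fitted by ordinary least squares on that scale. A pair at
NTCP = 0.5 pins `D50` to its EUD exactly (special-cased to avoid an
exp/log round trip).

**EQD2.** A linear-quadratic fractionation correction
(`D → D·(D/n + α/β)/(2 + α/β)`) is available but **off by default**: the
accounting intentionally mirrors plain physical-dose comparisons, and the
correction only matters when plans with different fractionation are mixed.

## Synthetic data

The generator provides controllable ground truth for every stage:

* **Counts**: truncated Gaussian with mean `dose/k` and SD `cv·mean`.
  Relative (not Poisson) noise is deliberate — at ~1e8 counts Poisson
  scatter would be ~0.01%, two orders below observed replicate CVs, which
  are dominated by chip-to-chip sensitivity variation.
* **Dose tables**: per-organ uniform draws in the configured mGy band.
* **DVHs**: the cumulative form is a logistic fall-off pinned to 1 at zero
  dose and 0 at `Dmax`, with two interpretable knobs (centre, steepness);
  the centre is solved by bisection so the realised Dmean matches the
  requested value within 2%. Default families reproduce the published
  per-organ mean-dose pattern across techniques (e.g. heart 16 Gy under
  conformal delivery vs 6.6 Gy under arc therapy).

What the generator does **not** emulate: spatial dose correlation, organ
anatomy, scanner geometry, multi-peak DVHs from field junctions, or OSL
fading/angular physics beyond scalar factors. Passing recovery tests on
synthetic data therefore demonstrates the correctness of the estimators and
accounting arithmetic, not the realism of any particular clinical plan.

## Numerical choices

* Internal canonical dose unit is Gy; conversions are decimal scalings, with
  down-scaling performed by dividing by the exact integer power of ten so
  unit round trips agree to the last floating-point digit.
* NTCP is evaluated on the log scale, so extreme dose ratios underflow
  gracefully to 0/1 instead of overflowing.
* `EUD` with `a < 0` is undefined on zero-dose bins (the power mean
  diverges); this raises a domain error rather than silently flooring.
* The pinned-logistic cumulative DVH is evaluated in log space
  (`expm1`/softplus form). The naive sigmoid-difference ratio loses all
  precision when the centre solver probes centres far outside `[0, Dmax]`
  — all three sigmoids then share one tail — while in the rewritten form
  the common exponential factor cancels analytically.
* `Vx` thresholds are inclusive (`≥ x`), matching the convention that lets
  `V_x = 0` coexist with `Dmax < x`.
* Differential↔cumulative DVH conversion is an exact suffix-sum/first-
  difference on shared bin doses; tiny negative volumes from cancellation
  (< 1e-9) are clamped before revalidation.
* Monte-Carlo uncertainty propagation perturbs each multiplicative factor
  independently (`1 + ε`, `ε ~ N(0, s)`) with a fixed default seed recorded
  in the budget; it agrees with quadrature within a few percent for
  component SDs ≤ 0.1 and is the more faithful combination when components
  grow beyond the linearised regime.
* Per-organ/technique synthetic seeds derive from CRC32 of the labels, not
  Python's salted `hash()`, so fixed-seed runs are byte-identical across
  processes.

## Report conventions

Full precision is kept internally; the report layer rounds imaging totals to
whole mGy and percents to two decimals (the precision at which such tables
are conventionally quoted), and logs each rounding at INFO level. NTCP is
stored as a fraction and rendered as percent in matrices.

## Problem sizes

Default test and demonstration runs use 200-bin DVHs, 5 calibration dose
levels × 5–10 replicates, 10–20 organs and 3 techniques; the full synthetic
pipeline completes in seconds at these sizes.

## Known limitations

* The logistic NTCP is the only dose-response model; Lyman-probit,
  relative-seriality and Poisson-TCP formalisms are out of scope.
* Only the CSV dialects documented in the README are read; DICOM-RT plan
  exports are not parsed.
* The bundled organ parameter defaults are illustrative literature values
  for adult endpoints unless tagged otherwise; pediatric risk estimates
  require user-supplied parameters.
* Imaging dose is treated as homogeneous within an organ (one OSL-measured
  mean per organ), so no imaging DVH is formed.
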