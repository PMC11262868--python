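# Methods

## Model

`mkrbe` implements a microdosimetric-kinetic (MK) dose-response for
tissue reactions. The assumptions, in order of consequence:

1. **Field quality enters only through `d(y)`.** A radiation field is
   reduced to its dose probability density of lineal energy in a
   subnuclear domain; all track-structure detail beyond that is ignored.
2. **Saturation (overkill).** Events above the saturation scale
   `y₀` contribute with diminishing effectiveness through the factor
   `1 − exp(−y²/y₀²)`, giving the corrected lineal energy `y*` and the
   specific energy `z* = y*/(π r_d²)`.
3. **Threshold-LQ survival.** Cell survival is linear-quadratic up to a
   threshold dose `D_t` and purely log-linear above it, with the tail
   slope `α_t = α₀ + βz* + 2βD_t` chosen so that log-survival and its
   derivative are continuous at `D_t`.
4. **Clinical anchoring.** The intrinsic low-LET ratio is eliminated via
   `α₀/β = (α/β)_c − z*_c`, so the only free parameter left is the
   domain radius `r_d`; the quadratic coefficient β cancels from RBE
   entirely (it is required only when evaluating survival itself, and no
   default is shipped).
5. **`d(y)` is independent of `r_d`.** Spectra are taken at a nominal
   site size (0.25 μm by default, recorded as metadata); along the fit
   only the `1/(π r_d²)` prefactor varies. This keeps the fit a cheap
   1-D problem and reflects the weak site-size dependence of `d(y)` over
   the fitted range.

RBE is a function of the *reference*-radiation dose. Doses exactly at
`D_t` are routed to the LQ branch (closed interval); continuity at the
branch point is exact by construction and verified to 1e-9 in tests.

## Parameters

| parameter | meaning | unit | default |
|---|---|---|---|
| `y0` | saturation scale of the overkill correction | keV/μm | 100 |
| `d_t` | threshold dose, LQ → linear switch | Gy | 7 |
| `alpha_beta_clinical` | clinically evaluated (α/β)_c | Gy | 10 |
| `r_d` | domain radius (the fitted parameter) | μm | — |
| `density_mass` | domain mass density | g/cm³ | 1.0 |
| `kev_um_to_gy` | geometry/unit factor in `z*` | Gy·μm³/keV·g⁻¹cm³ | 0.16022 |

The defaults for `y0`, `d_t` and `(α/β)_c` are the values established
for skin reactions, reused for circulatory disease so that disease
differences are carried entirely by `r_d`. The conversion constant
follows from 1 keV = 1.6022×10⁻¹⁶ J with a mass per unit track length of
`ρ π r_d²` (cylindrical-domain convention); it is exposed in
`SaturationParams` so an alternative geometry factor (e.g. spherical
mean-chord weighting) can be substituted without touching the code.

Sensitivity of conclusions to `(α/β)_c` and `D_t` is explored with
`sensitivity_scan`, which refits every experiment on a parameter grid
rather than changing defaults. Note a structural property of the
two-branch response: increasing `D_t` *steepens* the dose dependence of
RBE — the `D_t → 0` limit is a constant RBE equal to `A_test/A_ref`, the
`D_t → ∞` limit the full LQ decline toward 1, and the high-dose
asymptote is strictly decreasing in `D_t`. Only the `(α/β)_c` direction
("larger values flatten the dose response") holds; the tests assert both
directions and the `D_t` flattening check documents this as an expected
failure of the flattening intuition, not of the implementation.

## Synthetic spectra

The generator emulates the *shape families* of real microdosimetric
spectra, not any particular transport calculation:

- **photon-like** — a single log-normal in `y` with median ~1 keV/μm
  (sparse electron tracks);
- **neutron-like** — a mixture of a photon-like component (the
  secondary-gamma dose fraction, `admixture`) and a recoil-proton
  log-normal with median ~10–100 keV/μm;
- **ion-like** — a narrow high-LET log-normal (median ~120 keV/μm).

A seeded log-scale jitter (sd 0.05) on the medians makes distinct
experiments distinct while keeping generation bit-deterministic per
`(kind, params, seed)`. What the generator does **not** reproduce:
phantom- and organ-dependent moderation of neutron fields, the
energy-dependent gamma dose fraction in deep organs, delta-ray escape at
small site sizes, or any correlation between `d(y)` and `r_d`. Passing
tests therefore demonstrate correctness of the *pipeline* (saturation
integral, RBE algebra, fitting, statistics, bands) under realistic
spectrum shapes — they do not validate transport-dependent absolute RBE
values for any specific organ or neutron energy, which require a
transport code plus anatomical phantoms and are out of scope.

Default study conditions for synthetic experiments: 8 reference doses
spanning 1–20 Gy (both RBE branches), 5% multiplicative Gaussian noise
on measured RBE — a typical relative error for animal tissue-reaction
endpoints — and generating radii in the 0.17–0.28 μm range observed for
tissue reactions.

## Numerics

- **One quadrature rule.** Trapezoid on the stored grid everywhere
  (normalization, `y*`); no silent resampling (`resample_log` is
  explicit). The integrand vanishes like `y` at the origin, so no
  extrapolation below the first grid point is needed. Synthetic spectra
  use 400 log-spaced points on [0.01, 1000] keV/μm; agreement with
  adaptive quadrature is tested at 1e-4 relative.
- **Delta-like fixtures** are raised-cosine bumps of relative half-width
  1e-3, whose `y*` converges monotonically to the closed form
  `y₀²(1 − exp(−y₁²/y₀²))/y₁`.
- **Fit.** `r_d ∈ [0.02, 2.0] μm`, bracket tolerance 1e-6 μm: a
  128-point log-grid presearch locates the global basin (the objective
  can be multi-modal with noisy data), bounded Brent refines within the
  bracketing cells; a 1000-point grid oracle in the tests guards the
  global claim. Squared residuals are sorted before summation so the SSE
  — and hence the fit — is exactly invariant under permutation of the
  observations. Optimizer failures are returned as `converged=False`
  with diagnostics, never raised.
- **Undefined R².** With zero variance in the measured values R² is
  returned as NaN (an undefined marker), not an exception.
- **t-test.** Default is the pooled-variance Student test, the generic
  reading of "unpaired t-test"; Welch is available via
  `variant="welch"` and the variant used is recorded in the result.
- **Weights.** The fit is unweighted by default; optional per-point
  weights multiply the squared residuals.
- **Guards.** Spectra must integrate to 1 within 1e-3 before `y*`;
  `A_test, A_ref > 0` is enforced in `rbe` (a clinical `z*_c` exceeding
  `(α/β)_c` flips the survival exponent sign); band construction rejects
  `mean − sd ≤ 0` radii and band orderings that would indicate a test
  field softer than the reference.

## Problem sizes

The recovery Monte Carlo uses 200 replicates of 8-dose experiments (the
calibration behind the |bias| < 0.005 μm and RMSE < 0.02 μm recovery
bands); the synthetic study uses five experiments of 5–8 observations;
property tests draw up to 1000 random parameter sets. The whole suite
runs in a few seconds on one CPU.

## Known limitations

- No radiation transport: all shipped spectra are synthetic stand-ins
  labelled as such, and absolute RBE values for named organs or neutron
  energies are outside what this package can produce.
- The per-experiment radii for circulatory disease (0.173–0.284 μm) are
  used as stated inputs to the statistics; recomputing them from first
  principles would require the original animal-phantom transport
  calculations.
- Measured RBE observations are assumed already extracted as
  (dose, RBE) pairs; figure digitization is not provided.
- The model inherits the MK framework's assumptions (domain-level dose
  averaging, a single quality-independent β, survival as the mediator of
  tissue reactions); none of these are tested here.
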