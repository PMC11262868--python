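# mkrbe

Microdosimetric-kinetic estimation of relative biological effectiveness
(RBE) for tissue reactions — circulatory disease, skin reactions and
similar threshold-type radiation effects.

Radiological-protection bodies need RBE values for tissue reactions in
arbitrary radiation fields (neutrons, heavy ions, mixed fields), but
measured RBE exists only for a handful of experimental conditions.
`mkrbe` bridges that gap with a microdosimetric-kinetic (MK) model: the
radiation field enters only through its lineal-energy spectrum, the
tissue enters through a single fitted parameter — the radius `r_d` of a
subnuclear domain — and everything else is fixed by clinically evaluated
constants.

## The model

A radiation field is described by its dose probability density of lineal
energy, `d(y)`. The saturation-corrected dose-mean specific energy in a
domain of radius `r_d` is

    z* = y*/(π r_d²),   y* = y₀² ∫ [1 − exp(−y²/y₀²)] d(y)/y dy

with saturation parameter `y₀ = 100 keV/μm` down-weighting overkill
events (in units: `z*[Gy] = 0.16022 · y*/(ρ π r_d²)` for `y*` in keV/μm,
`r_d` in μm, `ρ` in g/cm³). Survival follows a linear-quadratic curve up
to a threshold dose `D_t = 7 Gy` and a matched log-linear tail above it:

    S(D) = exp[−(α₀ + βz*)D − βD²]              D ≤ D_t
         = S_LQ(D_t) exp[−α_t (D − D_t)],  α_t = α₀ + βz* + 2βD_t

The intrinsic ratio `α₀/β = (α/β)_c − z*_c` is anchored to a clinical
field with `(α/β)_c = 10 Gy`. Equating survival between a test and a
reference field gives a closed-form, β-free RBE as a function of the
reference dose `D`, with `A_x = (α/β)_c − z*_c + z*_x`:

    RBE(D) = [A_test + √(A_test² + 4(A_ref + D)D)] / [2(A_ref + D)]   D ≤ D_t

and the corresponding linear-branch expression above `D_t`. `r_d` is
fitted per experiment by least squares against measured (dose, RBE)
pairs; per-disease radii are summarized as mean ± SD, compared across
diseases with an unpaired t-test, and propagated into RBE uncertainty
bands (radius and RBE are anti-correlated, so `r̄_d + σ` gives the lower
band edge).

## Worked example

Fit a domain radius to synthetic noisy measurements and turn the
published circulatory-disease radii into RBE bands
(`examples/03_fit_domain_radius.py`, `examples/05_uncertainty_bands.py`):

```text
true r_d   = 0.231 um
fitted r_d = 0.233 um  (SSE 0.0880, R^2 0.939, converged=True)

circulatory disease: r_d = 0.231 +/- 0.039 um
  D_ref = 0.5 Gy   RBE = 2.98 [2.46, 3.83]
  D_ref = 5.0 Gy   RBE = 2.25 [1.90, 2.84]
```

The fit recovers the generating radius to within the noise; the bands say
that for this neutron-like field a reference gamma dose of 0.5 Gy is
matched in effect by roughly 3× less neutron dose, with the spread coming
from the scatter of per-experiment radii, and that RBE (and its
uncertainty) shrinks as the reference dose grows.

Each script in `examples/` demonstrates one capability: spectrum
synthesis and `y*`/`z*` (01), the RBE dose response (02), radius fitting
(03), disease statistics and t-tests (04), uncertainty bands (05) and the
full config-driven pipeline (06). The same pipeline is exposed as a CLI:

```sh
mkrbe run --config examples/demo_config.yaml --out results --seed 1
```

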