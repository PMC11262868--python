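"""Recover the domain radius from noisy measured RBE values.

The domain radius r_d is the model's only free parameter: z* of every
field scales as 1/r_d^2, so one bounded 1-D least-squares fit per
experiment determines it.  Here a synthetic experiment is generated at a
known radius with 5% multiplicative noise and refit.
"""

import numpy as np

from mkrbe import (
    MKParameters,
    fit_domain_radius,
    make_synthetic_experiment,
    make_synthetic_field,
)

params = MKParameters()
true_r_d = 0.231
doses = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0])

experiment = make_synthetic_experiment(
    "demo",
    true_r_d=true_r_d,
    doses=doses,
    test_spectrum=make_synthetic_field("neutron-like", {"admixture": 0.2}, seed=2),
    ref_spectrum=make_synthetic_field("photon-like", {"median": 1.0}, seed=1),
    clin_spectrum=make_synthetic_field("photon-like", {"median": 0.5}, seed=3),
    params_base=params,
    noise_sigma=0.05,
    seed=42,
)
for d, r in experiment.observations:
    print(f"  D_ref = {d:5.1f} Gy   measured RBE = {r:.3f}")

fit = fit_domain_radius(experiment, params)
print(f"\ntrue r_d   = {true_r_d:.3f} um")
print(f"fitted r_d = {fit.r_d_hat:.3f} um  (SSE {fit.sse:.4f}, "
      f"R^2 {fit.r_squared:.3f}, converged={fit.converged})")
# With 8 doses and 5% noise the radius typically comes back within
# ~0.005 um of the generating value.
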