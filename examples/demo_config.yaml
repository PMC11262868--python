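# All-synthetic demonstration pipeline: five noisy experiments emulating a
# circulatory-disease RBE study, compared against a skin-reaction group and
# evaluated as uncertainty bands at the 0.5 Gy threshold and a 5 Gy
# radiotherapy-level dose.
seed: 1
disease_label: circulatory-synthetic

parameters:
  y0_keV_um: 100.0
  d_t_Gy: 7.0
  alpha_beta_clinical_Gy: 10.0
  kev_um_to_gy: 0.16022
  density_g_cm3: 1.0
  bounds_um: [0.02, 2.0]
  tol_um: 1.0e-6

spectra:
  co60:                 # reference radiation, Co-60 gamma stand-in
    kind: photon-like
    params: {median: 1.0}
  clinical_10mv:        # typical clinical field, 10 MV X-ray stand-in
    kind: photon-like
    params: {median: 0.5}
  fission_neutron:
    kind: neutron-like
    params: {median: 40.0, admixture: 0.35}
  fast_neutron_15mev:
    kind: neutron-like
    params: {median: 25.0, admixture: 0.15}
  heavy_ion:
    kind: ion-like
    params: {median: 120.0}

experiments:
  - id: synth-rabbit-15MeV
    test: fast_neutron_15mev
    ref: co60
    clin: clinical_10mv
    synthetic: {true_r_d: 0.17, doses: [1, 2, 4, 8, 12, 16, 20], noise_sigma: 0.05}
  - id: synth-rat-15MeV
    test: fast_neutron_15mev
    ref: co60
    clin: clinical_10mv
    synthetic: {true_r_d: 0.23, doses: [1, 2, 4, 8, 12, 16, 20], noise_sigma: 0.05}
  - id: synth-mouse-fission-a
    test: fission_neutron
    ref: co60
    clin: clinical_10mv
    synthetic: {true_r_d: 0.24, doses: [0.5, 1, 2, 4, 6, 10], noise_sigma: 0.05}
  - id: synth-mouse-fission-b
    test: fission_neutron
    ref: co60
    clin: clinical_10mv
    synthetic: {true_r_d: 0.23, doses: [0.5, 1, 2, 4, 6, 10], noise_sigma: 0.05}
  - id: synth-rat-ion
    test: heavy_ion
    ref: co60
    clin: clinical_10mv
    synthetic: {true_r_d: 0.28, doses: [1, 3, 6, 10, 15], noise_sigma: 0.05}

compare:
  label: skin-synthetic
  r_d_values: [0.14, 0.17, 0.19, 0.21, 0.23]
  variant: pooled

scenario:
  ref: co60
  clin: clinical_10mv
  doses_Gy: [0.5, 5.0]
  points:
    - {label: fission neutron, spectrum: fission_neutron}
    - {label: 15 MeV neutron, spectrum: fast_neutron_15mev}
    - {label: heavy ion, spectrum: heavy_ion}
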