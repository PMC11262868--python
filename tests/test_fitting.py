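import math

import numpy as np
import pytest

from mkrbe import (
    FieldTriplet,
    MKParameters,
    compare_diseases,
    fit_domain_radius,
    make_synthetic_experiment,
    pooled_r_squared,
    r_squared,
    rbe,
    sensitivity_scan,
    summarize_disease,
    z_star,
)
from mkrbe.fitting import (
    ExperimentRecord,
    fit_results_frame,
    load_observations,
    _experiment_ystars,
    _predicted_rbe,
)
from mkrbe.microdosimetry import SaturationParams

#: Reference-radiation dose grid (Gy) spanning both RBE branches.
DOSES = np.array([1.0, 2.0, 4.0, 6.0, 8.0, 12.0, 16.0, 20.0])

#: Per-experiment best-fit domain radii (um) for circulatory disease from
#: five published animal experiments; the statistics inputs.
DCS_RADII = [0.173, 0.233, 0.237, 0.227, 0.284]


def _grid_sse(experiment, params, n=1000, bounds=(0.02, 2.0)):
    sat = SaturationParams(y0=params.y0)
    ystars = _experiment_ystars(experiment, sat)
    best = math.inf
    for r in np.geomspace(*bounds, n):
        resid = experiment.rbe_measured - _predicted_rbe(
            experiment.doses, ystars, r, params, sat
        )
        best = min(best, float(np.sum(resid**2)))
    return best


class TestFitDomainRadius:
    def test_noiseless_recovery_to_optimizer_tolerance(self, noiseless_experiment, params):
        fit = fit_domain_radius(noiseless_experiment, params, tol=1e-6)
        assert fit.converged and not fit.bounds_hit
        assert fit.r_d_hat == pytest.approx(0.231, abs=2e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_single_replicate(self, params, photon_spectrum,
                                             neutron_spectrum, clinical_spectrum):
        exp = make_synthetic_experiment(
            "noisy", 0.231, DOSES, neutron_spectrum, photon_spectrum,
            clinical_spectrum, params, noise_sigma=0.05, seed=42,
        )
        fit = fit_domain_radius(exp, params)
        assert abs(fit.r_d_hat - 0.231) < 0.02

    def test_matches_thousand_point_grid_oracle(self, noisy_experiments, params):
        for exp in noisy_experiments:
            fit = fit_domain_radius(exp, params)
            assert fit.sse <= _grid_sse(exp, params) + 1e-6

    def test_permutation_invariance(self, noisy_experiments, params):
        exp = noisy_experiments[0]
        perm = np.random.default_rng(0).permutation(exp.observations.shape[0])
        shuffled = ExperimentRecord(
            exp.id, exp.observations[perm], exp.test_spectrum,
            exp.ref_spectrum, exp.clin_spectrum,
        )
        a, b = fit_domain_radius(exp, params), fit_domain_radius(shuffled, params)
        assert a.r_d_hat == b.r_d_hat and a.sse == b.sse

    def test_bias_vanishes_with_noise(self, params, photon_spectrum,
                                      neutron_spectrum, clinical_spectrum):
        biases = []
        for sigma in (0.10, 0.02, 0.0):
            errs = [
                fit_domain_radius(
                    make_synthetic_experiment(
                        "b", 0.231, DOSES, neutron_spectrum, photon_spectrum,
                        clinical_spectrum, params, noise_sigma=sigma,
                        seed=500 + rep,
                    ),
                    params,
                ).r_d_hat - 0.231
                for rep in range(30)
            ]
            biases.append(abs(float(np.mean(errs))))
        assert biases[2] < biases[0] and biases[2] < 1e-5

    def test_constant_measured_rbe_yields_nan_r_squared(self, params, photon_spectrum,
                                                        neutron_spectrum,
                                                        clinical_spectrum):
        obs = np.column_stack([DOSES, np.full_like(DOSES, 2.5)])
        exp = ExperimentRecord("flat", obs, neutron_spectrum, photon_spectrum,
                               clinical_spectrum)
        fit = fit_domain_radius(exp, params)
        assert math.isnan(fit.r_squared) and fit.sse >= 0.0

    def test_bad_bounds_and_weights_rejected(self, noiseless_experiment, params):
        with pytest.raises(ValueError, match="bounds"):
            fit_domain_radius(noiseless_experiment, params, bounds=(0.5, 0.1))
        with pytest.raises(ValueError, match="weights"):
            fit_domain_radius(noiseless_experiment, params,
                              weights=np.ones(3))


class TestRSquared:
    @pytest.mark.parametrize(
        "measured, predicted, expected",
        [
            ([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], 1.0),
            ([1.0, 2.0, 3.0], [2.0, 2.0, 2.0], 0.0),
            ([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], -3.0),
        ],
    )
    def test_convention_allows_negative_values(self, measured, predicted, expected):
        assert r_squared(measured, predicted) == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_marked_undefined(self):
        assert math.isnan(r_squared([2.0, 2.0], [1.0, 3.0]))

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            r_squared([1.0, 2.0], [1.0])


class TestDiseaseStatistics:
    def test_published_radii_reproduce_printed_mean_and_sd(self):
        s = summarize_disease(DCS_RADII)
        assert round(s.mean, 3) == 0.231
        assert round(s.sd, 3) == 0.039

    def test_degenerate_pair(self):
        s = summarize_disease([0.2, 0.2])
        assert s.mean == 0.2 and s.sd == 0.0

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            summarize_disease([0.2])

    def test_identical_samples_give_p_one(self):
        a = summarize_disease([0.1, 0.2, 0.3])
        res = compare_diseases(a, a)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0, abs=1e-12)

    def test_equal_means_give_p_one_pooled(self):
        a = summarize_disease([0.1, 0.3])
        b = summarize_disease([0.15, 0.25])
        assert compare_diseases(a, b, "pooled").p_value == pytest.approx(1.0)

    def test_pooled_t_hand_computation(self):
        a = summarize_disease([1.0, 2.0, 3.0])
        b = summarize_disease([4.0, 5.0, 6.0])
        res = compare_diseases(a, b, "pooled")
        assert res.statistic == pytest.approx(-3.6742346, rel=1e-6)
        assert res.p_value == pytest.approx(0.021312, rel=1e-4)
        assert res.df == 4.0

    def test_welch_variant_recorded_and_differs(self):
        a = summarize_disease([1.0, 2.0, 3.0, 10.0])
        b = summarize_disease([4.0, 5.0])
        pooled = compare_diseases(a, b, "pooled")
        welch = compare_diseases(a, b, "welch")
        assert welch.variant == "welch" and welch.df != pooled.df
        with pytest.raises(ValueError):
            compare_diseases(a, b, "bootstrap")


class TestSensitivityScan:
    def test_degenerate_scan_reproduces_default_fit(self, noisy_experiments, params):
        fits = [fit_domain_radius(e, params) for e in noisy_experiments]
        table = sensitivity_scan(noisy_experiments, alpha_beta_grid=[10.0])
        assert table.loc[0, "r_d_mean"] == pytest.approx(
            np.mean([f.r_d_hat for f in fits]), abs=1e-12
        )
        assert table.loc[0, "n_failed"] == 0

    def test_rbe_dose_dependence_flattens_with_alpha_beta(self, noisy_experiments,
                                                          params, photon_spectrum,
                                                          neutron_spectrum):
        table = sensitivity_scan(noisy_experiments, alpha_beta_grid=[4.0, 10.0, 20.0])
        spans = []
        for _, row in table.iterrows():
            p = MKParameters(alpha_beta_clinical=row["value"])
            r_d = row["r_d_mean"]
            fields = FieldTriplet(
                z_star(neutron_spectrum, r_d), z_star(photon_spectrum, r_d),
                z_star(photon_spectrum, r_d),
            )
            spans.append(abs(rbe(1.0, fields, p) - rbe(20.0, fields, p)))
        assert spans[0] > spans[1] > spans[2]

    def test_goodness_of_fit_insensitive_to_threshold_dose(self, noisy_experiments):
        table = sensitivity_scan(noisy_experiments, d_t_grid=[5.0, 6.0, 7.0, 8.0, 9.0])
        r2 = table["r_squared_pooled"].to_numpy()
        assert np.ptp(r2) < 0.05

    def test_empty_scan_rejected(self, noisy_experiments):
        with pytest.raises(ValueError):
            sensitivity_scan(noisy_experiments)


def test_observation_csv_round_trip(tmp_path, noisy_experiments, params):
    exp = noisy_experiments[0]
    path = tmp_path / "obs.csv"
    path.write_text(
        "D_ref_Gy,RBE\n"
        + "\n".join(f"{d},{r}" for d, r in exp.observations)
    )
    obs = load_observations(path)
    assert np.allclose(obs, exp.observations)
    with pytest.raises(ValueError, match="missing columns"):
        bad = tmp_path / "bad.csv"
        bad.write_text("dose,rbe\n1,2\n")
        load_observations(bad)


def test_fit_results_frame_is_tidy(noisy_experiments, params):
    fits = [fit_domain_radius(e, params) for e in noisy_experiments]
    frame = fit_results_frame(fits)
    assert list(frame["experiment_id"]) == [e.id for e in noisy_experiments]
    assert frame.shape == (len(fits), 7)
    r2 = pooled_r_squared(noisy_experiments, frame["r_d_hat_um"].mean())
    assert r2 > 0  # the common-radius model beats predicting the pooled mean
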