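"""Parameter recovery, profiles, and the mixed-composition fits."""

import numpy as np
import pytest

from ringising import (
    IsingParameters,
    MixingWeights,
    binomial_null,
    closed_form_correlation,
    enrichment,
    fit_correlation,
    fit_delta_J,
    fit_mixing_weights,
    fit_pure,
    mixed_distribution,
    pattern_distribution,
    profile_r2_over_J,
    r_squared,
    scenario_weights,
)


def model_pair(params):
    return (
        pattern_distribution(params, labels="AA"),
        pattern_distribution(params, labels="EE"),
    )


class TestRSquared:
    def test_perfect_fit(self, study_params):
        d = pattern_distribution(study_params)
        assert r_squared(d, d) == pytest.approx(1.0)

    def test_mean_only_predictor_scores_zero(self, patterns, study_params):
        from ringising import PatternDistribution

        obs = pattern_distribution(study_params)
        flat = PatternDistribution(np.full(13, 1 / 13))
        assert r_squared(flat, obs) == pytest.approx(0.0, abs=1e-12)

    def test_joint_concatenation(self, study_params):
        obs = model_pair(study_params)
        assert r_squared(list(obs), list(obs)) == pytest.approx(1.0)

    def test_zero_variance_rejected(self):
        from ringising import PatternDistribution

        flat = PatternDistribution(np.full(13, 1 / 13))
        with pytest.raises(ValueError, match="zero variance"):
            r_squared(flat, flat)


class TestFitPure:
    def test_noise_free_inverse_consistency(self, study_params):
        obs_aa, obs_ee = model_pair(study_params)
        fit = fit_pure(obs_aa, obs_ee, profile_fields=False)
        assert fit.params.J == pytest.approx(0.14, abs=5e-3)
        assert fit.params.B_AA == pytest.approx(0.19, abs=5e-3)
        assert fit.params.B_EE == pytest.approx(-0.25, abs=5e-3)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_null_data_recovers_zero_coupling(self):
        obs_aa = binomial_null(0.55)
        obs_ee = binomial_null(0.42)
        fit = fit_pure(obs_aa, obs_ee, profile_fields=False)
        assert fit.params.J <= 0.005

    def test_estimates_inside_own_intervals(self, study_params):
        obs_aa, obs_ee = model_pair(study_params)
        fit = fit_pure(obs_aa, obs_ee)
        lo, hi = fit.uncertainty["J"]
        assert lo <= fit.params.J <= hi
        for name in ("B_AA", "B_EE"):
            lo, hi = fit.uncertainty[name]
            assert lo <= getattr(fit.params, name) <= hi

    def test_forcing_zero_coupling_degrades_fit(self, study_params):
        # cooperativity is necessary: J pinned at 0 fits strictly worse
        obs_aa, obs_ee = model_pair(study_params)
        prof = profile_r2_over_J(obs_aa, obs_ee, j_grid=np.array([0.0, 0.14]))
        assert prof["r2"][0] < prof["r2"][1]
        assert prof["r2"][1] == pytest.approx(1.0, abs=1e-9)


class TestProfile:
    def test_maximum_at_generating_coupling(self, study_params):
        obs_aa, obs_ee = model_pair(study_params)
        grid = np.round(np.arange(0.0, 0.3001, 0.005), 6)
        prof = profile_r2_over_J(obs_aa, obs_ee, grid)
        assert grid[np.argmax(prof["r2"])] == pytest.approx(0.14, abs=0.0051)

    def test_unimodal_on_noise_free_data(self, study_params):
        obs_aa, obs_ee = model_pair(study_params)
        grid = np.round(np.arange(0.0, 0.3001, 0.01), 6)
        r2 = profile_r2_over_J(obs_aa, obs_ee, grid)["r2"]
        peak = int(np.argmax(r2))
        assert (np.diff(r2[: peak + 1]) > -1e-12).all()
        assert (np.diff(r2[peak:]) < 1e-12).all()

    def test_estimator_consistency_with_sample_size(self, study_params):
        # larger samples pull the fitted J toward the generating value
        from ringising import SimulationSpec, simulate_dataset, tabulate_patterns

        errors = {}
        for n in (2_000, 200_000):
            errs = []
            for s in range(4):
                spec_a = SimulationSpec(params=study_params, composition="AA",
                                        n_rings=n, seed=410 + s)
                spec_e = SimulationSpec(params=study_params, composition="EE",
                                        n_rings=n, seed=420 + s)
                da, _ = tabulate_patterns(simulate_dataset(spec_a))
                de, _ = tabulate_patterns(simulate_dataset(spec_e))
                fit = fit_pure(da, de, profile_fields=False)
                errs.append(abs(fit.params.J - study_params.J))
            errors[n] = np.mean(errs)
        assert errors[200_000] < errors[2_000]


class TestFitCorrelation:
    def test_exact_recovery_from_closed_form(self):
        from ringising import mean_spin

        truth = {"AA": (0.15, 0.21), "EE": (0.15, -0.22)}
        observed = {
            k: closed_form_correlation(IsingParameters(J=j, B_AA=b))[0]
            for k, (j, b) in truth.items()
        }
        means = {k: mean_spin(IsingParameters(J=j), b)
                 for k, (j, b) in truth.items()}
        fit = fit_correlation(observed, mean_spin=means)
        assert fit.params.J == pytest.approx(0.15, abs=1e-6)
        assert fit.params.B_AA == pytest.approx(0.21, abs=1e-6)
        assert fit.params.B_EE == pytest.approx(-0.22, abs=1e-6)

    def test_zero_correlation_gives_zero_coupling(self):
        from ringising.ising import CorrelationFunction

        flat = CorrelationFunction(
            lags=np.arange(4), values=np.array([1.0, 0.0, 0.0, 0.0]), raw_c0=1.0
        )
        fit = fit_correlation({"AA": flat})
        assert fit.params.J == 0.0

    def test_recovery_from_simulated_rings(self, study_params):
        from ringising import SimulationSpec, empirical_correlation, simulate_dataset

        observed, hints = {}, {}
        for label, seed in (("AA", 7), ("EE", 8)):
            spec = SimulationSpec(params=study_params, composition=label,
                                  n_rings=100_000, seed=seed)
            data = simulate_dataset(spec)
            observed[label] = empirical_correlation(data)
            hints[label] = np.nanmean(data.spins())
        fit = fit_correlation(observed, mean_spin=hints)
        assert fit.params.J == pytest.approx(study_params.J, abs=0.05)
        assert np.sign(fit.params.B_EE) == -1.0


class TestMixedModel:
    def test_pure_delta_reduces_to_pure_distribution(self, study_params, arrangements):
        q = np.zeros(14)
        q[0] = 1.0  # all-AA arrangement
        mix = mixed_distribution(study_params, MixingWeights(q=q))
        pure = pattern_distribution(study_params, labels="AA")
        np.testing.assert_allclose(mix.probabilities, pure.probabilities, atol=1e-12)

    def test_no_mixing_is_arithmetic_mean(self, study_params):
        mix = mixed_distribution(study_params, scenario_weights("no_mixing", 0.5))
        mean = 0.5 * (
            pattern_distribution(study_params, labels="AA").probabilities
            + pattern_distribution(study_params, labels="EE").probabilities
        )
        np.testing.assert_allclose(mix.probabilities, mean, atol=1e-12)

    def test_fully_mixed_multiplicity_weights(self, arrangements):
        w = scenario_weights("fully_mixed", 0.5)
        np.testing.assert_allclose(
            w.q, np.array([a.multiplicity for a in arrangements]) / 64, atol=1e-15
        )
        assert scenario_weights("fully_mixed", 0.0).q[0] == pytest.approx(1.0)

    def test_fully_mixed_zero_coupling_binomial_oracle(self):
        # J=0, independent labels: each site is exposed w.p. the label-mixture
        params = IsingParameters(J=0.0, B_AA=0.19, B_EE=-0.25)
        mix = mixed_distribution(params, scenario_weights("fully_mixed", 0.5))
        p_aa = np.exp(0.19) / (np.exp(0.19) + np.exp(-0.19))
        p_ee = np.exp(-0.25) / (np.exp(-0.25) + np.exp(0.25))
        oracle = binomial_null(0.5 * p_aa + 0.5 * p_ee)
        np.testing.assert_allclose(mix.probabilities, oracle.probabilities, atol=1e-12)


class TestFitMixingWeights:
    def test_distribution_recovered_from_known_weights(self, study_params, rng):
        q_true = rng.dirichlet(np.ones(14))
        observed = mixed_distribution(study_params, MixingWeights(q=q_true))
        weights, fit = fit_mixing_weights(observed, study_params, lambda_weight=0.0)
        assert fit.r_squared >= 0.99  # q itself may differ; the distribution is the contract

    def test_penalty_dominance_pins_composition(self, study_params):
        observed = mixed_distribution(study_params, scenario_weights("fully_mixed", 0.5))
        weights, _ = fit_mixing_weights(observed, study_params, lambda_weight=1e4)
        assert weights.ee_fraction == pytest.approx(0.5, abs=1e-3)

    def test_pure_sample_concentrates_weights(self, study_params):
        observed = pattern_distribution(study_params, labels="AA")
        weights, _ = fit_mixing_weights(observed, study_params, lambda_weight=0.0)
        assert weights.q[0] > 0.95

    def test_nesting_free_beats_fixed_scenarios(self, study_params, rng):
        q_true = rng.dirichlet(np.full(14, 2.0))
        observed = mixed_distribution(study_params, MixingWeights(q=q_true))
        _, free = fit_mixing_weights(observed, study_params, lambda_weight=0.0)
        for scenario in ("no_mixing", "fully_mixed"):
            fixed = mixed_distribution(study_params, scenario_weights(scenario, 0.5))
            assert free.r_squared >= r_squared(fixed, observed) - 1e-9


class TestFitDeltaJ:
    def test_zero_offset_recovered(self, study_params):
        observed = mixed_distribution(study_params, scenario_weights("fully_mixed"))
        dj, _ = fit_delta_J(observed, study_params)
        assert abs(dj) <= 0.005

    def test_known_offset_recovered(self, study_params):
        gen = IsingParameters(J=0.14, B_AA=0.19, B_EE=-0.25, delta_J=0.09)
        observed = mixed_distribution(gen, scenario_weights("fully_mixed"))
        dj, fit = fit_delta_J(observed, study_params)
        assert dj == pytest.approx(0.09, abs=0.02)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_nested_model_ordering(self, study_params, rng):
        q = rng.dirichlet(np.ones(14))
        observed = mixed_distribution(study_params, MixingWeights(q=q))
        base = mixed_distribution(study_params, scenario_weights("fully_mixed"))
        _, fit = fit_delta_J(observed, study_params)
        assert fit.r_squared >= r_squared(base, observed) - 1e-9


class TestEnrichment:
    def test_identity_when_equal(self):
        fm = scenario_weights("fully_mixed")
        np.testing.assert_allclose(enrichment(fm, fm), 1.0)

    def test_pure_concentration_scaling(self):
        nm = scenario_weights("no_mixing", 0.5)
        fm = scenario_weights("fully_mixed", 0.5)
        alpha = enrichment(nm, fm)
        assert alpha[0] == pytest.approx(0.5 * 64)  # m=1 for the pure classes
        assert alpha[-1] == pytest.approx(0.5 * 64)

    def test_weighted_mean_is_one(self, rng):
        q = MixingWeights(q=rng.dirichlet(np.ones(14)))
        fm = scenario_weights("fully_mixed")
        assert (enrichment(q, fm) * fm.q).sum() == pytest.approx(1.0)
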