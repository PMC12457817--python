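"""Unit tests for the synthetic data-generating mechanisms."""

import dataclasses

import numpy as np
import pytest
from scipy.special import expit

from causalcf import dgm, presets
from causalcf.dgm import (
    CalibrationError,
    ConfigurationError,
    ConfounderModel,
    DGMParams,
)

from conftest import tiny_complex_params, tiny_simple_params


def _independent_params():
    """All cross-variable coefficients zero: columns are independent."""
    models = (
        ConfounderModel("b1", "bernoulli-logistic", intercept=0.5),
        ConfounderModel("z1", "gaussian-linear", intercept=-0.7, coefs=(0.0,)),
        ConfounderModel("z2", "gaussian-linear", intercept=1.2, coefs=(0.0, 0.0)),
    )
    return DGMParams(
        name="indep", complexity="simple", p=3, n_continuous=2,
        confounder_models=models,
        exposure_intercept=0.0, exposure_main=(0.0, 0.0, 0.0),
        outcome_main=(0.0, 0.0, 0.0), residual_sd=1.0,
    )


class TestGenerateConfounders:
    def test_independence_case_means(self):
        p = _independent_params()
        W = dgm.generate_confounders(p, 100_000, seed=7)
        se = 1.0 / np.sqrt(100_000)
        assert abs(W[:, 1].mean() - (-0.7)) < 4 * se
        assert abs(W[:, 2].mean() - 1.2) < 4 * se
        assert abs(W[:, 0].mean() - expit(0.5)) < 4 * 0.5 * se

    def test_small_set_composition(self):
        params = presets.default_params("simple-1")
        W = dgm.generate_confounders(params, 200, seed=3)
        assert W.shape == (200, 14)
        n_cont = sum(len(np.unique(W[:, j])) > 2 for j in range(14))
        assert n_cont == 13

    def test_determinism(self, tiny_complex):
        W1 = dgm.generate_confounders(tiny_complex, 500, seed=42)
        W2 = dgm.generate_confounders(tiny_complex, 500, seed=42)
        np.testing.assert_array_equal(W1, W2)

    def test_coefficient_mismatch_names_variable(self):
        models = (
            ConfounderModel("b1", "bernoulli-logistic"),
            ConfounderModel("zbad", "gaussian-linear", coefs=(0.1, 0.2)),
        )
        with pytest.raises(ConfigurationError, match="zbad"):
            DGMParams(name="bad", complexity="simple", p=2, n_continuous=1,
                      confounder_models=models,
                      exposure_intercept=0.0, exposure_main=(0.0, 0.0),
                      outcome_main=(0.0, 0.0))

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError, match="family"):
            ConfounderModel("w", "poisson-log")

    def test_categorical_emits_indicators(self):
        models = (
            ConfounderModel("cat", "categorical-multinomial",
                            level_intercepts=(0.0, 0.0)),
        )
        p = DGMParams(name="cat", complexity="simple", p=1, n_continuous=0,
                      confounder_models=models,
                      exposure_intercept=0.0, exposure_main=(0.0, 0.0),
                      outcome_main=(0.0, 0.0))
        W = dgm.generate_confounders(p, 30_000, seed=5)
        assert W.shape == (30_000, 2)
        assert set(np.unique(W)) <= {0.0, 1.0}
        # equal utilities: each of the three levels has probability 1/3
        shares = [1 - W.sum(axis=1).mean(), W[:, 0].mean(), W[:, 1].mean()]
        assert np.allclose(shares, 1 / 3, atol=0.02)


class TestGenerateExposure:
    def test_logit_zero_gives_half(self):
        p = _independent_params()
        W = dgm.generate_confounders(p, 100_000, seed=1)
        X = dgm.generate_exposure(W, p, seed=2)
        assert abs(X.mean() - 0.5) < 4 * 0.5 / np.sqrt(100_000)

    def test_degenerate_intercept_all_zero(self):
        p = dataclasses.replace(_independent_params(), exposure_intercept=-40.0)
        W = dgm.generate_confounders(p, 100, seed=1)
        assert dgm.generate_exposure(W, p, seed=2).sum() == 0

    def test_complex_design_matches_oracle(self):
        """Independent re-implementation of the design expansion with the
        same RNG stream reproduces the generated exposure exactly."""
        params = tiny_complex_params(multiplier=2.0)
        W = dgm.generate_confounders(params, 2_000, seed=11)
        X = dgm.generate_exposure(W, params, seed=13)

        lp = np.full(W.shape[0], params.exposure_intercept)
        for j, c in enumerate(params.exposure_main):
            lp += c * W[:, j]
        for (i, j), c in zip(params.exposure_ww_pairs, params.exposure_ww_coefs):
            lp += params.interaction_multiplier * c * W[:, i] * W[:, j]
        for k, j in enumerate(params.exposure_nl_idx):
            lp += params.exposure_sq_coefs[k] * W[:, j] ** 2
            lp += params.exposure_log_coefs[k] * np.log(np.abs(W[:, j]) + 1)
        oracle = (np.random.default_rng(13).random(W.shape[0]) < expit(lp)).astype(float)
        np.testing.assert_array_equal(X, oracle)


class TestGenerateOutcome:
    def test_zero_coefs_standard_normal(self):
        p = _independent_params()
        p = dataclasses.replace(p, outcome_intercept=0.0, outcome_effect=0.0)
        W = dgm.generate_confounders(p, 100_000, seed=1)
        X = dgm.generate_exposure(W, p, seed=2)
        Y = dgm.generate_outcome(W, X, p, seed=3)
        assert abs(Y.mean()) < 4 / np.sqrt(100_000)
        assert abs(Y.std(ddof=1) - 1.0) < 0.02

    def test_noiseless_unconfounded_effect(self):
        p = dataclasses.replace(_independent_params(), outcome_effect=0.7,
                                residual_sd=0.0)
        W = dgm.generate_confounders(p, 5_000, seed=1)
        X = dgm.generate_exposure(W, p, seed=2)
        Y = dgm.generate_outcome(W, X, p, seed=3)
        assert Y[X == 1].mean() - Y[X == 0].mean() == pytest.approx(0.7, abs=1e-12)

    def test_multiplier_matches_bruteforce_oracle(self):
        """Brute-force design expansion with interaction multiplier 4."""
        params = tiny_complex_params(multiplier=4.0)
        W = dgm.generate_confounders(params, 1_000, seed=21)
        X = dgm.generate_exposure(W, params, seed=22)
        Y = dgm.generate_outcome(W, X, params, seed=23)

        mu = np.full(W.shape[0], params.outcome_intercept)
        mu += params.outcome_effect * X
        for j, c in enumerate(params.outcome_main):
            mu += c * W[:, j]
        for (i, j), c in zip(params.outcome_ww_pairs, params.outcome_ww_coefs):
            mu += 4.0 * c * W[:, i] * W[:, j]
        for k, j in enumerate(params.outcome_xw_idx):
            mu += 4.0 * params.outcome_xw_coefs[k] * X * W[:, j]
        for k, j in enumerate(params.outcome_nl_idx):
            mu += params.outcome_sq_coefs[k] * W[:, j] ** 2
            mu += params.outcome_log_coefs[k] * np.log(np.abs(W[:, j]) + 1)
        oracle = mu + np.random.default_rng(23).standard_normal(W.shape[0])
        np.testing.assert_allclose(Y, oracle, atol=1e-12)


class TestNesting:
    def test_zeroed_complex_equals_simple_bytewise(self):
        """A complex mechanism with its interaction and non-linear blocks
        zeroed reproduces the simple mechanism exactly, seed for seed."""
        simple = tiny_simple_params()
        complex_zeroed = dataclasses.replace(
            tiny_complex_params(multiplier=2.0),
            exposure_ww_coefs=(0.0, 0.0), exposure_sq_coefs=(0.0,),
            exposure_log_coefs=(0.0,), outcome_ww_coefs=(0.0,),
            outcome_xw_coefs=(0.0, 0.0), outcome_sq_coefs=(0.0,),
            outcome_log_coefs=(0.0,))
        d1 = dgm.simulate_dataset(simple, 400, seed=77)
        d2 = dgm.simulate_dataset(complex_zeroed, 400, seed=77)
        np.testing.assert_array_equal(d1.W, d2.W)
        np.testing.assert_array_equal(d1.X, d2.X)
        np.testing.assert_array_equal(d1.Y, d2.Y)


class TestCalibration:
    def test_intercept_trivial_zero(self):
        p = dataclasses.replace(_independent_params(), outcome_intercept=5.0)
        p = dataclasses.replace(
            p, outcome_main=(0.0, 0.0, 0.0), outcome_effect=0.0)
        assert dgm.calibrate_intercept(p, n=50_000) == pytest.approx(0.0, abs=1e-12)

    def test_intercept_recentres_simple_preset(self):
        params = presets.default_params("simple-1")
        data = dgm.simulate_dataset(params, 400_000, seed=314159)
        assert abs(data.Y.mean()) < 0.005

    def test_intercept_recentres_tiny_complex(self, tiny_complex):
        p = dgm.with_calibrated_intercept(tiny_complex, n=400_000)
        data = dgm.simulate_dataset(p, 400_000, seed=2718)
        assert abs(data.Y.mean()) < 0.005

    def test_intercept_idempotent(self, tiny_complex):
        b0 = dgm.calibrate_intercept(tiny_complex, n=200_000)
        p = dataclasses.replace(tiny_complex, outcome_intercept=b0)
        b0_again = dgm.calibrate_intercept(p, n=200_000)
        assert b0_again == pytest.approx(b0, abs=1e-9)

    def test_null_effect_rejects_at_alpha(self, tiny_simple):
        p = dataclasses.replace(tiny_simple, outcome_effect=0.0)
        rate = dgm.rejection_rate(p, n=300, reps=300, seed=5)
        # Wald test size; allow generous Monte Carlo + small-sample slack
        assert 0.01 <= rate <= 0.10

    def test_power_monotone_in_n(self, tiny_simple):
        beta = dgm.calibrate_effect(tiny_simple, n=150, reps=250, seed=8,
                                    tol=0.04)
        p = dataclasses.replace(tiny_simple, outcome_effect=beta)
        power_2n = dgm.rejection_rate(p, n=300, reps=250, seed=9)
        assert power_2n > 0.80

    def test_unreachable_target_errors(self, tiny_simple):
        with pytest.raises(CalibrationError, match="achieved power"):
            dgm.calibrate_effect(tiny_simple, n=30, reps=50, seed=3,
                                 target_power=0.999, beta_max=0.05)


class TestTrueACE:
    def test_simple_collapsible_equals_betax(self, tiny_simple):
        truth = dgm.true_ace(tiny_simple, n_truth=50_000, seed=4)
        assert truth.theta == pytest.approx(tiny_simple.outcome_effect, abs=1e-12)

    def test_all_zero_coefs_gives_zero(self):
        truth = dgm.true_ace(_independent_params(), n_truth=20_000, seed=4)
        assert truth.theta == 0.0

    def test_complex_self_consistency(self, tiny_complex):
        """Two independent Monte-Carlo evaluations agree within 3 MC-SEs."""
        n = 200_000
        t1 = dgm.true_ace(tiny_complex, n_truth=n, seed=10)
        t2 = dgm.true_ace(tiny_complex, n_truth=n, seed=20)
        W = dgm.generate_confounders(tiny_complex, 50_000, seed=30)
        diff = (dgm.conditional_outcome_mean(W, np.ones(50_000), tiny_complex)
                - dgm.conditional_outcome_mean(W, np.zeros(50_000), tiny_complex))
        mcse = diff.std(ddof=1) / np.sqrt(n)
        assert abs(t1.theta - t2.theta) < 3 * np.sqrt(2) * mcse

    def test_deterministic_given_seed(self, tiny_complex):
        a = dgm.true_ace(tiny_complex, n_truth=30_000, seed=6)
        b = dgm.true_ace(tiny_complex, n_truth=30_000, seed=6)
        assert a.theta == b.theta
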