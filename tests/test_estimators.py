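"""Unit tests for the doubly robust estimators and cross-fitting."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar
from scipy.special import expit, logit

from causalcf import dgm, estimators
from causalcf.data import DataValidationError, ObservedData
from causalcf.estimators import (
    NuisanceEstimates,
    OracleNuisance,
    ParametricNuisance,
    PositivityError,
    SparseExposureError,
    aipw,
    analyze,
    crossfit,
    estimate_ace,
    make_folds,
    tmle,
)


def _toy_zero_residual():
    data = ObservedData(W=np.zeros((2, 1)), X=[1, 0], Y=[1.0, 0.0])
    nuis = NuisanceEstimates(e1=[1.0, 1.0], e0=[0.0, 0.0], g=[0.5, 0.5])
    return data, nuis


def _random_inputs(seed, n=50):
    rng = np.random.default_rng(seed)
    W = rng.normal(size=(n, 3))
    X = (rng.random(n) < 0.4).astype(float)
    Y = rng.normal(size=n) * 2 + 1
    e1 = rng.normal(size=n) * 2 + 1.2  # deliberately rough, some out of range
    e0 = rng.normal(size=n) * 2 + 0.8
    g = rng.uniform(0.05, 0.95, size=n)
    return ObservedData(W, X, Y), NuisanceEstimates(e1=e1, e0=e0, g=g)


class TestAIPW:
    def test_zero_residual_toy(self):
        data, nuis = _toy_zero_residual()
        est = aipw(data, nuis)
        assert est.psi == pytest.approx(1.0, abs=1e-14)
        assert est.se == pytest.approx(0.0, abs=1e-14)

    def test_reduces_to_ipw_with_zero_outcome_predictions(self, rng):
        n = 40
        data = ObservedData(rng.normal(size=(n, 2)),
                            (rng.random(n) < 0.5).astype(float),
                            rng.normal(size=n))
        nuis = NuisanceEstimates(e1=np.zeros(n), e0=np.zeros(n),
                                 g=np.full(n, 0.5))
        est = aipw(data, nuis)
        ipw = np.mean(2 * (2 * data.X - 1) * data.Y)
        assert est.psi == pytest.approx(ipw, abs=1e-12)

    def test_reduces_to_gcomp_under_zero_residuals(self, rng):
        n = 30
        W = rng.normal(size=(n, 2))
        X = (rng.random(n) < 0.5).astype(float)
        e1 = W[:, 0] * 0.5 + 1
        e0 = W[:, 1] * 0.2
        Y = np.where(X == 1, e1, e0)  # outcome equals its prediction
        data = ObservedData(W, X, Y)
        nuis = NuisanceEstimates(e1=e1, e0=e0, g=rng.uniform(0.2, 0.8, n))
        est = aipw(data, nuis)
        assert est.psi == pytest.approx(np.mean(e1 - e0), abs=1e-12)

    def test_matches_term_by_term_oracle_fixture(self, fixture_dir):
        df = pd.read_csv(fixture_dir / "aipw_oracle_6rec.csv")
        data = ObservedData(np.zeros((6, 1)), df["x"], df["y"])
        nuis = NuisanceEstimates(e1=df["e1"], e0=df["e0"], g=df["g"])
        est = aipw(data, nuis)
        # straight-line evaluation, term by term
        terms = []
        for y, x, e1, e0, g in df[["y", "x", "e1", "e0", "g"]].itertuples(index=False):
            t = e1 - e0
            if x == 1:
                t += (y - e1) / g
            else:
                t -= (y - e0) / (1 - g)
            terms.append(t)
        psi = sum(terms) / 6
        var = sum((t - psi) ** 2 for t in terms) / (6 * 5)
        assert est.psi == pytest.approx(psi, abs=1e-10)
        assert est.se == pytest.approx(np.sqrt(var), abs=1e-10)

    def test_positivity_violation_names_records(self):
        with pytest.raises(PositivityError, match=r"\[1\]"):
            NuisanceEstimates(e1=[0.0, 0.0], e0=[0.0, 0.0], g=[0.5, 1.0])

    def test_wald_interval_construction(self, rng):
        data, nuis = _random_inputs(3)
        est = aipw(data, nuis)
        assert est.ci_high - est.ci_low == pytest.approx(2 * 1.96 * est.se,
                                                         abs=1e-12)
        assert est.ci_low == pytest.approx(est.psi - 1.96 * est.se, abs=1e-12)


class TestTMLE:
    def test_zero_residual_targeting_is_identity(self):
        data, nuis = _toy_zero_residual()
        est = tmle(data, nuis)
        fit = est.diagnostics["targeting"]
        assert fit.epsilon == pytest.approx(0.0, abs=1e-8)
        assert est.psi == pytest.approx(1.0, abs=1e-8)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4, 5, 6, 7, 8])
    def test_mean_eif_zero_and_bounded(self, seed):
        data, nuis = _random_inputs(seed)
        est = tmle(data, nuis)
        assert abs(est.eif.mean()) < 1e-8
        a, b = data.Y.min(), data.Y.max()
        fit = est.diagnostics["targeting"]
        assert np.all(fit.e1_star >= a - 1e-9) and np.all(fit.e1_star <= b + 1e-9)
        assert np.all(fit.e0_star >= a - 1e-9) and np.all(fit.e0_star <= b + 1e-9)
        assert -(b - a) - 1e-9 <= est.psi <= (b - a) + 1e-9

    def test_matches_generic_optimizer_oracle(self):
        """The Newton fluctuation agrees with a generic 1-d likelihood
        maximizer applied to the same targeting recipe."""
        data, nuis = _random_inputs(99)
        est = tmle(data, nuis)
        a, b = data.Y.min(), data.Y.max()
        span = b - a
        y_s = np.clip((data.Y - a) / span, 0, 1)
        clip = lambda p: np.clip(np.where(p < 0, 1e-4, np.where(p > 1, 1 - 1e-4, p)),
                                 1e-12, 1 - 1e-12)
        e1_s = clip((nuis.e1 - a) / span)
        e0_s = clip((nuis.e0 - a) / span)
        ex_s = np.where(data.X == 1, e1_s, e0_s)
        H = data.X / nuis.g - (1 - data.X) / (1 - nuis.g)
        off = logit(ex_s)

        def negloglik(eps):
            p = np.clip(expit(off + eps * H), 1e-12, 1 - 1e-12)
            return -np.mean(y_s * np.log(p) + (1 - y_s) * np.log(1 - p))

        res = minimize_scalar(negloglik, bounds=(-10, 10), method="bounded",
                              options={"xatol": 1e-12})
        e1_star = a + span * expit(logit(e1_s) + res.x / nuis.g)
        e0_star = a + span * expit(logit(e0_s) - res.x / (1 - nuis.g))
        psi_oracle = np.mean(e1_star - e0_star)
        assert est.psi == pytest.approx(psi_oracle, abs=1e-6)

    def test_degenerate_outcome_rejected(self):
        data = ObservedData(np.zeros((3, 1)), [1, 0, 1], [2.0, 2.0, 2.0])
        nuis = NuisanceEstimates(e1=[2, 2, 2], e0=[2, 2, 2], g=[0.5] * 3)
        with pytest.raises(Exception, match="degenerate"):
            tmle(data, nuis)


class TestFolds:
    def test_even_split(self):
        fa = make_folds(10, 2, seed=0)
        sizes = np.bincount(fa.fold, minlength=2)
        assert sizes.tolist() == [5, 5]
        assert set(fa.fold) == {0, 1}

    def test_near_even_split(self):
        fa = make_folds(101, 5, seed=1)
        sizes = np.bincount(fa.fold, minlength=5)
        assert sorted(sizes.tolist()) == [20, 20, 20, 20, 21]

    def test_deterministic(self):
        a = make_folds(57, 3, seed=9).fold
        b = make_folds(57, 3, seed=9).fold
        np.testing.assert_array_equal(a, b)

    def test_stratified_balance(self, rng):
        strata = (rng.random(200) < 0.25).astype(int)
        fa = make_folds(200, 5, seed=2, strata=strata)
        per_fold = [strata[fa.fold == k].sum() for k in range(5)]
        assert max(per_fold) - min(per_fold) <= 1

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            make_folds(10, 1, seed=0)
        with pytest.raises(ValueError, match="too small"):
            make_folds(5, 3, seed=0)


class TestCrossfit:
    def test_oracle_injection_matches_pooled_aipw(self, tiny_simple):
        """With injected true nuisance functions, out-of-fold predictions
        equal full-sample predictions, so cross-fitted AIPW must equal the
        plain estimator exactly."""
        data = dgm.simulate_dataset(tiny_simple, 120, seed=5)
        oracle = OracleNuisance(tiny_simple)
        cf = crossfit(data, 2, "aipw", oracle, seed=1, truncate=False)
        plain = estimate_ace(data, "aipw", folds=None, library=oracle,
                             seed=1, truncate=False)
        assert cf.psi == pytest.approx(plain.psi, abs=1e-12)
        assert cf.se == pytest.approx(plain.se, abs=1e-12)

    def test_deterministic(self, tiny_simple):
        data = dgm.simulate_dataset(tiny_simple, 150, seed=6)
        a = crossfit(data, 3, "tmle", ParametricNuisance(), seed=4)
        b = crossfit(data, 3, "tmle", ParametricNuisance(), seed=4)
        assert a.psi == b.psi and a.se == b.se

    def test_tmle_mean_eif_zero_per_fold_pooling(self, tiny_simple):
        data = dgm.simulate_dataset(tiny_simple, 200, seed=7)
        est = crossfit(data, 4, "tmle", ParametricNuisance(), seed=8)
        # per-fold targeting solves each fold's score; pooled mean EIF is
        # the weighted fold-score sum and must vanish as well
        assert abs(est.eif.mean()) < 1e-8

    def test_sparse_exposure_complement_raises(self):
        n = 24
        W = np.random.default_rng(0).normal(size=(n, 2))
        X = np.zeros(n)
        X[0] = 1  # single exposed record
        Y = np.random.default_rng(1).normal(size=n)
        data = ObservedData(W, X, Y)
        with pytest.raises(SparseExposureError, match="fewer folds"):
            crossfit(data, 2, "aipw", ParametricNuisance(), seed=0)


class TestAnalyze:
    def test_missing_cell_refused(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("y,x,w1\n1.0,1,0.5\n,0,0.2\n")
        with pytest.raises(DataValidationError, match="[Mm]issing"):
            analyze(str(path), library="glm")

    def test_nonbinary_exposure_refused(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("y,x,w1\n1.0,1,0.5\n0.3,2,0.2\n")
        with pytest.raises(DataValidationError, match="0/1"):
            analyze(str(path), library="glm")

    def test_demo_analysis_reports_overlap(self, fixture_dir):
        est, diag = analyze(str(fixture_dir / "demo_simple1_n300.csv"),
                            method="aipw", library="glm", seed=3)
        assert np.isfinite(est.psi) and est.se > 0
        for grp in ("exposed", "unexposed"):
            s = diag["ps_summary"][grp]
            assert 0 <= s["min"] <= s["median"] <= s["max"] <= 1

    def test_aipw_equals_tmle_when_outcome_model_exact(self, fixture_dir):
        """On a noiseless linear outcome, a GLM outcome model has zero
        residuals, collapsing both estimators to g-computation."""
        path = str(fixture_dir / "linear_noiseless.csv")
        a, _ = analyze(path, method="aipw", library="glm", seed=1)
        t, _ = analyze(path, method="tmle", library="glm", seed=1)
        assert a.psi == pytest.approx(t.psi, abs=1e-8)

    def test_calibrated_ci_contains_truth(self, tiny_simple):
        """|psi - theta| < 4 se on a typical draw from a known mechanism."""
        data = dgm.simulate_dataset(tiny_simple, 1000, seed=31)
        est, _ = analyze(data.to_frame(), method="tmle", library="glm", seed=2)
        assert abs(est.psi - tiny_simple.outcome_effect) < 4 * est.se
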