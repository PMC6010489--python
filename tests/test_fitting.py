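"""MLE fitting, AICc arithmetic, Akaike weights, sign test, rank frequency."""

import math

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from stepcue.families import ModelSpec, SupportBounds, sample
from stepcue.fitting import (
    InsufficientStepsError,
    StepLengthModel,
    StepSample,
    _akaike_weights,
    aicc,
    fit,
    multi_model_weights,
    pairwise_weight,
    pooled_fit,
    rank_frequency,
    sign_test,
)
from stepcue.datasets import load_bagoti_summary, recompute_pairwise_weights


class TestAicc:
    def test_forced_arithmetic(self):
        assert aicc(-27.79, 2, 20) == pytest.approx(60.28588235294117, abs=1e-10)
        assert aicc(-49.24, 2, 49) == pytest.approx(4 + 98.48 + 12 / 46, abs=1e-10)

    def test_penalty_difference_k3_vs_k2(self):
        diff = aicc(0.0, 3, 28) - aicc(0.0, 2, 28)
        assert diff == pytest.approx(2.0 + 24 / 24 - 12 / 25, abs=1e-12)

    def test_undefined_for_tiny_samples(self):
        with pytest.raises(ValueError):
            aicc(-5.0, 2, 3)


class TestPairwiseWeights:
    def test_published_rows_recompute(self):
        """AICc weights from the published per-ant log-likelihoods."""
        df = recompute_pairwise_weights().set_index("ant")
        assert df.loc[4, "w_recomputed_vs_biexp"] == pytest.approx(0.78, abs=0.005)
        assert df.loc[22, "w_recomputed_vs_biexp"] == pytest.approx(0.86, abs=0.005)
        assert df.loc[22, "w_recomputed_vs_free"] == pytest.approx(0.75, abs=0.005)

    def test_symmetry_for_equal_fits(self):
        model = ModelSpec("EXP", {"lam": 1.0})
        b = SupportBounds(0.1, 10.0)
        from stepcue.fitting import FitResult

        fa = FitResult(model=model, log_likelihood=-10.0, n=30, bounds=b)
        fb = FitResult(model=model, log_likelihood=-10.0, n=30, bounds=b)
        assert pairwise_weight(fa, fb) == pytest.approx(0.5)

    def test_mismatched_samples_rejected(self):
        from stepcue.fitting import FitResult

        model = ModelSpec("EXP", {"lam": 1.0})
        b = SupportBounds(0.1, 10.0)
        fa = FitResult(model=model, log_likelihood=-10.0, n=30, bounds=b)
        fb = FitResult(model=model, log_likelihood=-10.0, n=40, bounds=b)
        with pytest.raises(ValueError):
            pairwise_weight(fa, fb)


class TestMultiModelWeights:
    def test_two_models_reduce_to_pairwise(self):
        from stepcue.fitting import FitResult

        b = SupportBounds(0.1, 10.0)
        fa = FitResult(ModelSpec("EXP", {"lam": 1.0}), -20.0, 30, b)
        fb = FitResult(ModelSpec("GSE_CONSTRAINED", {"lam": 1.0, "D": 1.5}), -19.5, 30, b)
        comp = multi_model_weights([fa, fb])
        assert comp.weights[0] == pytest.approx(pairwise_weight(fa, fb), abs=1e-12)
        assert comp.weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_equal_aicc_gives_equal_weights(self):
        w = _akaike_weights(np.array([10.0, 10.0, 10.0]))
        assert np.allclose(w, 1 / 3)

    def test_invariant_under_common_aicc_shift(self):
        a = np.array([12.0, 15.5, 13.1])
        assert np.allclose(_akaike_weights(a), _akaike_weights(a + 37.0))

    def test_exponential_data_favors_exponential(self):
        """Penalty dominance: nested families tie in logL, EXP wins on k."""
        bounds = SupportBounds(0.01, 30.0)
        x = sample(ModelSpec("EXP", {"lam": 2.0}), bounds, 500, seed=21)
        s = StepSample(x, bounds=bounds)
        fits = [fit(s, fam, bounds=bounds)
                for fam in ("EXP", "GSE_CONSTRAINED", "BIEXP", "POWER")]
        comp = multi_model_weights(fits)
        w_exp = comp.weight_of("EXP")
        for fam in ("GSE_CONSTRAINED", "BIEXP", "POWER"):
            assert w_exp > comp.weight_of(fam)


class TestSignTest:
    def test_exact_tail_sum(self):
        # 2 * sum_{k=18}^{22} C(22,k) / 2^22
        expect = 2 * sum(math.comb(22, k) for k in range(18, 23)) / 2**22
        assert sign_test(18, 22) == pytest.approx(expect, abs=1e-12)
        assert sign_test(18, 22) <= 0.01

    def test_central_value_capped_at_one(self):
        assert sign_test(11, 22) == 1.0

    @pytest.mark.parametrize("s,n", [(18, 22), (3, 10), (0, 5), (7, 7), (10, 20)])
    def test_agrees_with_scipy_binomtest(self, s, n):
        # independent check: for p=1/2 the symmetric binomial makes scipy's
        # minlike two-sided p equal to the doubled smaller tail (capped)
        ours = sign_test(s, n)
        scipys = stats.binomtest(s, n, 0.5).pvalue
        assert ours == pytest.approx(min(1.0, scipys), abs=1e-12)


class TestMleFit:
    def test_exponential_rate_recovery(self, exp_steps_10k):
        x, bounds = exp_steps_10k
        est = StepLengthModel("EXP", bounds=bounds).fit(x)
        assert 1.94 <= est.params_["lam"] <= 2.06

    def test_gse_fit_matches_grid_search_oracle(self, gse_steps_small):
        """Exhaustive 400x400 (lambda, D) grid never beats the optimizer."""
        x, bounds = gse_steps_small
        est = StepLengthModel("GSE_CONSTRAINED", bounds=bounds).fit(x)
        lams = np.geomspace(1e-2, 1e2, 400)
        ds = np.linspace(0.5 + 1e-6, 3.0, 400)
        lgrid = np.geomspace(bounds.lower, bounds.upper, 1500)
        logx = np.log(x)
        best = -np.inf
        for d in ds:
            gamma, mu = d - 1.0, d - 2.0
            # kernel on quadrature grid for all lambdas at once
            lk = -np.power(np.outer(lams, lgrid), gamma) + mu * np.log(lgrid)
            shift = lk.max(axis=1, keepdims=True)
            z = np.trapezoid(np.exp(lk - shift), lgrid, axis=1)
            logz = shift[:, 0] + np.log(z)
            data_term = (
                -np.power(np.outer(lams, x), gamma).sum(axis=1) + mu * logx.sum()
            )
            ll = data_term - x.size * logz
            best = max(best, ll.max())
        assert est.log_likelihood_ >= best - 1e-3

    def test_insufficient_steps_refused(self):
        with pytest.raises(InsufficientStepsError):
            StepLengthModel("GSE_CONSTRAINED").fit([0.3, 0.7])

    def test_nested_families_monotone_log_likelihood(self, gse_steps_small):
        x, bounds = gse_steps_small
        ll = {
            fam: StepLengthModel(fam, bounds=bounds).fit(x).log_likelihood_
            for fam in ("EXP", "GSE_CONSTRAINED", "GSE_FREE", "BIEXP")
        }
        assert ll["GSE_CONSTRAINED"] >= ll["EXP"] - 1e-6
        assert ll["GSE_FREE"] >= ll["GSE_CONSTRAINED"] - 1e-6
        assert ll["BIEXP"] >= ll["EXP"] - 1e-6

    def test_biexp_reports_ordered_rates(self):
        bounds = SupportBounds(0.01, 30.0)
        x = sample(ModelSpec("BIEXP", {"w": 0.4, "lam1": 0.5, "lam2": 6.0}),
                   bounds, 800, seed=5)
        est = StepLengthModel("BIEXP", bounds=bounds).fit(x)
        assert est.params_["lam1"] < est.params_["lam2"]

    def test_model_recovery_across_families(self):
        """Data simulated from a family gets top weight for that family."""
        bounds = SupportBounds(0.02, 30.0)
        truth = {
            "EXP": ModelSpec("EXP", {"lam": 1.5}),
            "GSE_CONSTRAINED": ModelSpec("GSE_CONSTRAINED", {"lam": 1.5, "D": 1.4}),
            "BIEXP": ModelSpec("BIEXP", {"w": 0.5, "lam1": 0.3, "lam2": 8.0}),
            "POWER": ModelSpec("POWER", {"mu": -1.7}),
        }
        hits = trials = 0
        for seed in range(5):
            for true_fam, model in truth.items():
                x = sample(model, bounds, 1000, seed=100 + seed)
                s = StepSample(x, bounds=bounds)
                fits = [fit(s, fam, bounds=bounds) for fam in truth]
                comp = multi_model_weights(fits)
                hits += comp.best.model.family == true_fam
                trials += 1
        assert hits / trials >= 0.8

    def test_sklearn_estimator_contract(self, gse_steps_small):
        x, bounds = gse_steps_small
        est = StepLengthModel("GSE_CONSTRAINED", bounds=bounds)
        cloned = clone(est)
        assert cloned.get_params()["family"] == "GSE_CONSTRAINED"
        est.set_params(tol=1e-9)
        assert est.tol == 1e-9
        est.fit(x.reshape(-1, 1))  # column input accepted
        logp = est.score_samples(x)
        assert logp.shape == x.shape and np.all(np.isfinite(logp))
        assert est.score(x) == pytest.approx(est.log_likelihood_, rel=1e-9)
        drawn = est.sample(100, random_state=0)
        assert bounds.contains(drawn).all()


class TestPooling:
    def test_single_sample_identity(self, gse_steps_small):
        x, _ = gse_steps_small
        s = StepSample(x)
        single = fit(s, "EXP")
        pooled = pooled_fit([s], "EXP")
        assert pooled.log_likelihood == pytest.approx(single.log_likelihood, abs=1e-8)

    def test_pooled_rate_between_individual_extremes(self):
        bounds = SupportBounds(0.005, 60.0)
        a = StepSample(sample(ModelSpec("EXP", {"lam": 1.5}), bounds, 400, seed=1))
        b = StepSample(sample(ModelSpec("EXP", {"lam": 3.0}), bounds, 400, seed=2))
        lam_a = fit(a, "EXP", bounds=bounds).model.params["lam"]
        lam_b = fit(b, "EXP", bounds=bounds).model.params["lam"]
        lam_pool = pooled_fit([a, b], "EXP").model.params["lam"]
        assert min(lam_a, lam_b) <= lam_pool <= max(lam_a, lam_b)

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            pooled_fit([], "EXP")


class TestRankFrequency:
    def test_definition_on_small_sample(self):
        lens, frac = rank_frequency(StepSample([1.0, 2.0, 3.0, 4.0]))
        assert np.allclose(lens, [1, 2, 3, 4])
        assert np.allclose(frac, [1.0, 0.75, 0.5, 0.25])

    def test_ties_collapse(self):
        lens, frac = rank_frequency(StepSample([1.0, 2.0, 2.0, 3.0]))
        assert np.allclose(lens, [1, 2, 3])
        assert np.allclose(frac, [1.0, 0.75, 0.25])

    def test_exponential_linearity(self, exp_steps_10k):
        x, _ = exp_steps_10k
        lens, frac = rank_frequency(StepSample(x))
        keep = frac > 1e-3
        slope, _ = np.polyfit(lens[keep], -np.log(frac[keep]), 1)
        assert slope == pytest.approx(2.0, rel=0.05)


def test_published_summary_shape():
    df = load_bagoti_summary()
    assert len(df) == 23
    assert df.w_gse_vs_biexp.notna().sum() == 22  # one individual unfitted
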