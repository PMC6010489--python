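"""Distribution families: normalization, nesting, sampling, encounter theory."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import integrate

from stepcue.families import (
    CueGeometry,
    ModelSpec,
    SupportBounds,
    NonNormalizableError,
    cdf,
    encounter_rate,
    free_path_pdf,
    free_path_survival,
    log_pdf,
    mean_free_path_uniform,
    normalization,
    pdf,
    sample,
    survival,
)

B = SupportBounds(0.1, 10.0)


class TestNormalization:
    def test_truncated_exponential_closed_form(self):
        N = normalization(ModelSpec("EXP", {"lam": 1.0}), B)
        assert N == pytest.approx(1.0 / (math.exp(-0.1) - math.exp(-10.0)), rel=1e-10)

    def test_constrained_gse_at_d2_equals_exponential(self):
        n_gse = normalization(ModelSpec("GSE_CONSTRAINED", {"lam": 1.0, "D": 2.0}), B)
        n_exp = normalization(ModelSpec("EXP", {"lam": 1.0}), B)
        assert n_gse == pytest.approx(n_exp, rel=1e-10)

    def test_gse_matches_riemann_sum_oracle(self):
        # brute-force Riemann sum of the kernel at 1e6 nodes
        model = ModelSpec("GSE_CONSTRAINED", {"lam": 1.0, "D": 1.5})
        grid = np.linspace(0.1, 10.0, 1_000_001)
        kernel = np.exp(model.log_kernel(grid))
        Z = np.trapezoid(kernel, grid)
        assert normalization(model, B) == pytest.approx(1.0 / Z, rel=1e-6)

    def test_power_law_non_normalizable_on_infinite_support(self):
        with pytest.raises(NonNormalizableError):
            normalization(ModelSpec("POWER", {"mu": -0.5}), SupportBounds(0.1))

    @pytest.mark.parametrize(
        "family,params",
        [
            ("EXP", {"lam": 2.3}),
            ("BIEXP", {"w": 0.3, "lam1": 0.8, "lam2": 5.0}),
            ("STRETCHED", {"lam": 1.2, "gamma": 0.6}),
            ("GSE_CONSTRAINED", {"lam": 0.9, "D": 1.62}),
            ("GSE_FREE", {"lam": 1.1, "gamma": 0.8, "mu": -0.7}),
            ("POWER", {"mu": -1.8}),
        ],
    )
    def test_pdf_integrates_to_one(self, family, params):
        model = ModelSpec(family, params)
        total, _ = integrate.quad(
            lambda l: pdf(model, B, np.array(l)), B.lower, B.upper, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-6)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(
    lam=st.floats(0.05, 20.0),
    d=st.floats(0.6, 2.8),
    a=st.floats(0.02, 0.5),
    width=st.floats(1.0, 30.0),
)
def test_normalization_property_constrained_gse(lam, d, a, width):
    """For random valid parameters the truncated pdf has unit mass."""
    model = ModelSpec("GSE_CONSTRAINED", {"lam": lam, "D": d})
    bounds = SupportBounds(a, a + width)
    total, _ = integrate.quad(
        lambda l: pdf(model, bounds, np.array(l)), bounds.lower, bounds.upper,
        limit=300,
    )
    assert total == pytest.approx(1.0, abs=1e-5)


class TestLogPdf:
    def test_exponential_slope_of_log_density(self):
        # D=2 constrained GSE with lam=2: log p differences are -2 * dl
        model = ModelSpec("GSE_CONSTRAINED", {"lam": 2.0, "D": 2.0})
        l1, l2 = 0.7, 3.1
        diff = log_pdf(model, B, l1) - log_pdf(model, B, l2)
        assert diff == pytest.approx(-2.0 * (l1 - l2), rel=1e-9)

    def test_d1_reduces_to_inverse_power(self):
        # D = 1: the stretch factor is constant, leaving kernel ~ 1/l
        model = ModelSpec("GSE_CONSTRAINED", {"lam": 3.0, "D": 1.0})
        l1, l2 = 0.5, 4.0
        diff = log_pdf(model, B, l1) - log_pdf(model, B, l2)
        assert diff == pytest.approx(-(math.log(l1) - math.log(l2)), rel=1e-9)

    def test_biexp_matches_hand_computed_mixture(self):
        model = ModelSpec("BIEXP", {"w": 0.5, "lam1": 1.0, "lam2": 5.0})
        mix = 0.5 * 1.0 * math.exp(-0.5) + 0.5 * 5.0 * math.exp(-2.5)
        Z, _ = integrate.quad(
            lambda l: 0.5 * math.exp(-l) + 0.5 * 5 * math.exp(-5 * l),
            B.lower, B.upper,
        )
        assert log_pdf(model, B, 0.5) == pytest.approx(math.log(mix / Z), rel=1e-7)

    def test_equal_rates_forbidden_in_biexp(self):
        with pytest.raises(ValueError):
            ModelSpec("BIEXP", {"w": 0.5, "lam1": 2.0, "lam2": 2.0})

    def test_outside_bounds_is_minus_infinity(self):
        model = ModelSpec("EXP", {"lam": 1.0})
        assert log_pdf(model, B, 0.01) == -np.inf
        assert log_pdf(model, B, 11.0) == -np.inf


class TestSurvival:
    @pytest.mark.parametrize(
        "family,params",
        [
            ("GSE_CONSTRAINED", {"lam": 1.0, "D": 1.585}),
            ("BIEXP", {"w": 0.4, "lam1": 0.5, "lam2": 4.0}),
        ],
    )
    def test_monotone_from_one_to_zero(self, family, params):
        model = ModelSpec(family, params)
        l = np.linspace(B.lower, B.upper, 200)
        s = survival(model, B, l)
        assert s[0] == pytest.approx(1.0, abs=1e-9)
        assert s[-1] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(s) <= 1e-12)


class TestSampling:
    @pytest.mark.parametrize(
        "family,params",
        [
            ("EXP", {"lam": 2.0}),
            ("GSE_CONSTRAINED", {"lam": 1.0, "D": 1.585}),
            ("BIEXP", {"w": 0.3, "lam1": 0.5, "lam2": 4.0}),
            ("POWER", {"mu": -2.0}),
        ],
    )
    def test_ecdf_matches_numeric_cdf(self, family, params):
        model = ModelSpec(family, params)
        x = sample(model, B, 100_000, seed=3)
        assert np.all((x >= B.lower) & (x <= B.upper))
        grid = np.linspace(B.lower, B.upper, 400)
        ecdf = np.searchsorted(np.sort(x), grid, side="right") / x.size
        assert np.max(np.abs(ecdf - cdf(model, B, grid))) < 0.01

    def test_truncated_exponential_mean(self):
        bounds = SupportBounds(0.01, 50.0)
        model = ModelSpec("EXP", {"lam": 2.0})
        x = sample(model, bounds, 100_000, seed=11)
        mean_theory, _ = integrate.quad(
            lambda l: l * pdf(model, bounds, np.array(l)), bounds.lower, bounds.upper,
            limit=200,
        )
        assert x.mean() == pytest.approx(mean_theory, rel=0.01)

    def test_single_draw_in_narrow_support(self):
        bounds = SupportBounds(1.0, 1.0 + 1e-6)
        x = sample(ModelSpec("EXP", {"lam": 1.0}), bounds, 1, seed=0)
        assert bounds.contains(x).all()

    def test_reproducible_for_fixed_seed(self):
        model = ModelSpec("EXP", {"lam": 1.0})
        assert np.array_equal(sample(model, B, 50, seed=9), sample(model, B, 50, seed=9))


class TestEncounterTheory:
    def test_uniform_rate_is_constant(self):
        geom = CueGeometry(rho=0.05, delta=1.0, D=2.0)
        q = encounter_rate(geom, np.array([1.0, 2.0, 7.0]))
        assert np.allclose(q, 2.0 * 0.05 / math.pi)

    def test_d1_rate_direct_substitution(self):
        geom = CueGeometry(rho=0.1, delta=1.0, D=1.0)
        assert encounter_rate(geom, 4.0) == pytest.approx(0.1 / math.pi / 4.0)

    def test_rate_decay_exponent(self):
        # D = 1.5: q ~ r^{-1/2}, so q(4)/q(1) = 0.5
        geom = CueGeometry(rho=0.1, delta=1.0, D=1.5)
        assert encounter_rate(geom, 4.0) / encounter_rate(geom, 1.0) == pytest.approx(0.5)

    def test_overlap_violation(self):
        with pytest.raises(ValueError, match="overlap"):
            CueGeometry(rho=0.6, delta=1.0, D=2.0)

    def test_dimension_domain(self):
        with pytest.raises(ValueError):
            CueGeometry(rho=0.1, delta=1.0, D=-0.2)

    def test_uniform_free_path_is_exponential(self):
        geom = CueGeometry(rho=0.05, delta=1.0, D=2.0)
        r = np.linspace(2.0, 30.0, 50)
        logp = np.log(free_path_pdf(geom, r))
        slopes = np.diff(logp) / np.diff(r)
        assert np.allclose(slopes, -2.0 * 0.05 / math.pi, atol=1e-10)

    def test_gse_algebraic_identity(self):
        # log p + rho*D/(pi*delta^D) * r^{D-1}/(D-1) - (D-2) log r is constant
        rho, delta, D = 0.02, 0.1, 1.6
        geom = CueGeometry(rho=rho, delta=delta, D=D)
        r = np.linspace(delta, 20 * delta, 100)
        expr = (
            np.log(free_path_pdf(geom, r))
            + rho * D / (math.pi * delta**D) * r ** (D - 1.0) / (D - 1.0)
            - (D - 2.0) * np.log(r)
        )
        assert np.ptp(expr) < 1e-10

    def test_survival_matches_hazard_process_monte_carlo(self):
        # sequential-interval construction: survive each [r, r+dr] w.p. 1-q(r)dr
        rho, delta, D = 0.02, 0.05, 1.6
        geom = CueGeometry(rho=rho, delta=delta, D=D)
        rng = np.random.default_rng(123)
        dr = 1e-4
        n_walkers = 20_000
        r_grid = np.arange(delta, 60 * delta, dr)
        alive = np.ones(n_walkers, dtype=bool)
        emp = np.empty(r_grid.size)
        for i, r in enumerate(r_grid):
            emp[i] = alive.mean()
            q = encounter_rate(geom, r)
            alive &= rng.random(n_walkers) >= q * dr
        theo = free_path_survival(geom, r_grid)
        assert np.max(np.abs(emp - theo)) < 0.03

    def test_mean_free_path_identity(self):
        geom = CueGeometry(rho=0.05, delta=1.0, D=2.0)
        assert mean_free_path_uniform(geom) == pytest.approx(math.pi / 0.1)
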