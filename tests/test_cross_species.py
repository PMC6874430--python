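"""Cross-species trendlines, multivariate regression and the very-old-individual
metric, checked against hand-built matrix oracles and printed worked examples."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from damagerates import (
    PUBLISHED_GH2AX_RATES,
    SpeciesTraits,
    correlate_rates,
    fit_linear_trend,
    fit_multivariate,
    fit_power_trend,
    load_traits,
    old_abundance,
)
from damagerates.cross_species import example_traits_path


class TestLinearTrend:
    def test_exact_line_recovered(self):
        fit = fit_linear_trend([1, 2, 3], [4, 7, 10])
        assert fit.coefficients == pytest.approx((3.0, 1.0))
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            fit_linear_trend([2, 2, 2], [1, 2, 3])

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_trend([1, 2], [1, 2])

    def test_missing_species_dropped_pairwise(self):
        fit = fit_linear_trend([1, 2, 3, np.nan], [2, 4, 6, 8])
        assert fit.n_species == 3
        assert fit.coefficients[0] == pytest.approx(2.0)

    def test_published_rate_vector_against_normal_equation_oracle(self):
        rates = [0.115, 0.668, 1.24, 0.180, 0.427]
        lifespans = [51.6, 20.8, 21.8, 44.0, 41.4]
        fit = fit_linear_trend(rates, lifespans)
        X = np.column_stack([np.ones(5), rates])
        beta = np.linalg.solve(X.T @ X, X.T @ np.asarray(lifespans))
        assert fit.coefficients[0] == pytest.approx(beta[1], abs=1e-9)
        assert fit.coefficients[1] == pytest.approx(beta[0], abs=1e-9)
        assert fit.coefficients[0] < 0  # longer lifespan, slower damage rate


class TestPowerTrend:
    def test_exact_power_law_recovered(self):
        fit = fit_power_trend([1, 4, 9], [2 * 1**0.5, 2 * 4**0.5, 2 * 9**0.5])
        a, b = fit.coefficients
        assert a == pytest.approx(2.0)
        assert b == pytest.approx(0.5)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.r_squared_original == pytest.approx(1.0)

    def test_constant_response_flags_undefined_r2(self):
        fit = fit_power_trend([1, 2, 4], [3.0, 3.0, 3.0])
        a, b = fit.coefficients
        assert b == pytest.approx(0.0)
        assert a == pytest.approx(3.0)
        assert not fit.r_squared_defined

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_power_trend([1, 2, 3], [1, -1, 2])

    def test_random_instance_matches_log_residual_minimisation(self, rng):
        from scipy.optimize import minimize

        x = rng.uniform(0.5, 10, 6)
        y = 3.0 * x**-0.8 * np.exp(rng.normal(0, 0.2, 6))
        fit = fit_power_trend(x, y)
        res = minimize(
            lambda p: ((np.log(y) - p[0] - p[1] * np.log(x)) ** 2).sum(),
            x0=[0.0, 0.0],
            method="Nelder-Mead",
            options={"xatol": 1e-12, "fatol": 1e-16, "maxiter": 20_000},
        )
        assert np.log(fit.coefficients[0]) == pytest.approx(res.x[0], abs=1e-6)
        assert fit.coefficients[1] == pytest.approx(res.x[1], abs=1e-6)

    def test_scale_equivariance_in_x(self, rng):
        x = rng.uniform(1, 20, 6)
        y = 5 * x**-0.6 * np.exp(rng.normal(0, 0.1, 6))
        base = fit_power_trend(x, y)
        for c in (0.1, 3.0, 40.0):
            scaled = fit_power_trend(c * x, y)
            a, b = base.coefficients
            assert scaled.coefficients[1] == pytest.approx(b, rel=1e-9)
            assert scaled.coefficients[0] == pytest.approx(a * c**-b, rel=1e-9)


class TestRateVsRate:
    def test_identical_vectors_give_unit_r2(self):
        v = [0.1, 0.4, 0.9, 1.3]
        assert correlate_rates(v, v).r_squared == pytest.approx(1.0)

    def test_orthogonalised_vectors_give_zero_r2(self, rng):
        a = rng.uniform(0, 2, 5)
        b = rng.uniform(0, 2, 5)
        X = np.column_stack([np.ones(5), a])
        resid = b - X @ np.linalg.lstsq(X, b, rcond=None)[0]
        assert correlate_rates(a, resid).r_squared == pytest.approx(0.0, abs=1e-12)

    def test_same_r2_as_linear_trend_and_closed_form(self, rng):
        latent = rng.uniform(0, 1, 5)
        a = 0.2 + latent + rng.normal(0, 0.05, 5)
        b = 0.1 + 0.8 * latent + rng.normal(0, 0.05, 5)
        fit = correlate_rates(a, b)
        assert fit.r_squared == pytest.approx(fit_linear_trend(a, b).r_squared, rel=1e-12)
        assert fit.r_squared == pytest.approx(np.corrcoef(a, b)[0, 1] ** 2, rel=1e-10)


def _mv_oracle(X, y):
    """From-scratch multivariate OLS: coefficients, R², F-test p-value."""
    n, p = X.shape
    D = np.column_stack([np.ones(n), X])
    beta = np.linalg.solve(D.T @ D, D.T @ y)
    resid = y - D @ beta
    ssr = resid @ resid
    sst = ((y - y.mean()) ** 2).sum()
    r2 = 1 - ssr / sst
    f = (sst - ssr) / p / (ssr / (n - p - 1))
    return beta, r2, stats.f.sf(f, p, n - p - 1)


class TestMultivariate:
    def _data(self, rng, noise=0.0):
        x1 = rng.uniform(0, 2, 5)
        x2 = rng.uniform(0, 2, 5)
        y = 10 - 3 * x1 + 2 * x2 + noise * rng.normal(size=5)
        return pd.DataFrame({"x1": x1, "x2": x2, "y": y})

    def test_noise_free_coefficients_recovered_exactly(self, rng):
        fit = fit_multivariate(self._data(rng), "y", ["x1", "x2"])
        assert fit.params["const"] == pytest.approx(10.0, abs=1e-8)
        assert fit.params["x1"] == pytest.approx(-3.0, abs=1e-8)
        assert fit.params["x2"] == pytest.approx(2.0, abs=1e-8)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_duplicate_predictor_raises_named_singularity(self, rng):
        data = self._data(rng)
        data["x1_copy"] = data["x1"]
        with pytest.raises(ValueError, match="collinear"):
            fit_multivariate(data, "y", ["x1", "x1_copy"])

    def test_worked_instance_matches_matrix_oracle(self, rng):
        data = self._data(rng, noise=0.5)
        fit = fit_multivariate(data, "y", ["x1", "x2"])
        beta, r2, f_p = _mv_oracle(data[["x1", "x2"]].to_numpy(), data["y"].to_numpy())
        assert fit.params["const"] == pytest.approx(beta[0], abs=1e-8)
        assert fit.params["x1"] == pytest.approx(beta[1], abs=1e-8)
        assert fit.params["x2"] == pytest.approx(beta[2], abs=1e-8)
        assert fit.r_squared == pytest.approx(r2, abs=1e-8)
        assert fit.f_pvalue == pytest.approx(f_p, abs=1e-8)

    def test_single_predictor_reproduces_linear_trend(self, rng):
        data = self._data(rng, noise=0.5)
        mv = fit_multivariate(data, "y", ["x1"])
        lin = fit_linear_trend(data["x1"], data["y"])
        assert mv.params["x1"] == pytest.approx(lin.coefficients[0], rel=1e-10)
        assert mv.params["const"] == pytest.approx(lin.coefficients[1], rel=1e-10)
        assert mv.r_squared == pytest.approx(lin.r_squared, rel=1e-10)

    def test_too_few_species_rejected(self, rng):
        data = self._data(rng).head(3)
        with pytest.raises(ValueError, match="at least"):
            fit_multivariate(data, "y", ["x1", "x2"])


class TestOldAbundance:
    def test_human_cutoff_is_seventy_percent_of_max_lifespan(self):
        out = old_abundance([50.0], 122.5)
        assert out.cutoff_age == pytest.approx(0.7 * 122.5)

    def test_dolphin_like_fraction(self):
        # 3 of 8 sampled ages above the cutoff (0.7 * 51.6 = 36.12) -> 37.5%
        ages = [10, 20, 30, 35, 36.12, 40, 45, 50]
        out = old_abundance(ages, 51.6, species="dolphin")
        assert (out.n_old, out.n_total) == (3, 8)
        assert out.fraction_old == pytest.approx(0.375)

    def test_no_old_individuals(self):
        out = old_abundance(np.linspace(0, 10, 15), 20.8)
        assert out.n_old == 0 and out.fraction_old == 0.0

    def test_tie_at_cutoff_is_not_old(self):
        assert old_abundance([7.0], 10.0).n_old == 0

    def test_permutation_invariant_and_monotone_in_lifespan(self, rng):
        ages = rng.uniform(0, 60, 12)
        base = old_abundance(ages, 50.0).fraction_old
        assert old_abundance(rng.permutation(ages), 50.0).fraction_old == base
        fracs = [old_abundance(ages, ml).fraction_old for ml in (20, 40, 60, 80)]
        assert fracs == sorted(fracs, reverse=True)

    @pytest.mark.parametrize("ages,ml", [([], 10.0), ([1.0], 0.0)])
    def test_invalid_inputs_rejected(self, ages, ml):
        with pytest.raises(ValueError):
            old_abundance(ages, ml)


class TestTraits:
    def test_example_traits_table_loads_with_published_species(self):
        traits = load_traits(example_traits_path())
        assert set(PUBLISHED_GH2AX_RATES) <= set(traits["species"])
        assert (traits["max_lifespan_years"] >= traits["avg_lifespan_years"]).all()

    def test_traits_invariant_enforced(self):
        with pytest.raises(ValueError):
            SpeciesTraits(species="x", max_lifespan=10.0, avg_lifespan=20.0)
        t = SpeciesTraits(species="x", max_lifespan=30.0, avg_lifespan=20.0)
        assert np.isnan(t.heart_rate)  # missing covariates allowed
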