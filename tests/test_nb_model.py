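import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aortrend.io_survey import build_catch_table
from aortrend.nb_model import (
    K_CAP,
    STATUS_BOUNDARY,
    STATUS_NOT_FIT,
    STATUS_OK,
    NBParams,
    ParamTable,
    fit_nb,
    fit_yearly_params,
    median_params,
    nb_pmf,
    p_from_mu_k,
    parameter_series,
    parameter_trend,
)


def pmf_oracle(x, mu, k):
    """Independent gamma-function evaluation of the NB pmf."""
    p = k / (k + mu)
    log_coeff = math.lgamma(x + k) - math.lgamma(k) - math.lgamma(x + 1)
    return math.exp(log_coeff + k * math.log(p) + x * math.log(1 - p))


def loglik(counts, mu, k):
    return sum(math.log(pmf_oracle(int(x), mu, k)) for x in counts)


class TestPmf:
    def test_zero_count_probability_simple_case(self):
        # pmf(0) = (k/(k+mu))^k = (1/2)^1
        assert nb_pmf(0, mu=1, k=1) == pytest.approx(0.5)

    def test_normalization(self):
        total = nb_pmf(np.arange(501), mu=3, k=0.7).sum()
        assert total == pytest.approx(1.0, abs=1e-9)

    @pytest.mark.parametrize("x,mu,k", [(2, 2, 2), (0, 0.4, 0.3), (7, 5, 0.5), (3, 10, 4)])
    def test_matches_gamma_function_oracle(self, x, mu, k):
        assert nb_pmf(x, mu, k) == pytest.approx(pmf_oracle(x, mu, k), rel=1e-12)

    @pytest.mark.parametrize("mu,k", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_domain_errors(self, mu, k):
        with pytest.raises(ValueError):
            nb_pmf(1, mu, k)

    def test_lower_k_concentrates_mass_at_zero(self):
        # aggregation semantics: smaller k -> more empty sites at fixed mu
        p0 = [nb_pmf(0, mu=2.0, k=k) for k in (5.0, 2.0, 1.0, 0.5, 0.2)]
        assert all(a < b for a, b in zip(p0, p0[1:]))


class TestPFromMuK:
    @pytest.mark.parametrize("mu,k,expected", [(3, 3, 0.5), (0, 2, 1.0), (3, 1, 0.25)])
    def test_values(self, mu, k, expected):
        assert p_from_mu_k(mu, k) == pytest.approx(expected)

    def test_nonpositive_k_rejected(self):
        with pytest.raises(ValueError):
            p_from_mu_k(1.0, 0.0)


class TestFitNB:
    def test_underdispersed_sample_hits_k_boundary(self):
        params = fit_nb([4] * 10)
        assert params.status == STATUS_BOUNDARY
        assert params.mu == pytest.approx(4.0)
        assert params.k == K_CAP

    def test_all_zero_counts_not_fit(self):
        assert fit_nb([0, 0, 0, 0]).status == STATUS_NOT_FIT

    def test_too_few_counts_not_fit(self):
        assert fit_nb([3, 1]).status == STATUS_NOT_FIT

    def test_parameter_recovery_at_large_n(self):
        rng = np.random.default_rng(2026)
        mu, k = 5.0, 0.5
        draws = rng.negative_binomial(k, k / (k + mu), size=10_000)
        params = fit_nb(draws)
        assert params.status == STATUS_OK
        assert 4.7 <= params.mu <= 5.3
        assert 0.45 <= params.k <= 0.55

    def test_mu_hat_equals_sample_mean(self):
        rng = np.random.default_rng(5)
        draws = rng.negative_binomial(1.0, 0.25, size=200)
        assert fit_nb(draws).mu == pytest.approx(draws.mean(), abs=1e-12)

    def test_small_sample_matches_grid_search_oracle(self):
        rng = np.random.default_rng(17)
        mu, k = 3.0, 0.8
        draws = rng.negative_binomial(k, k / (k + mu), size=20)
        fit = fit_nb(draws)
        assert fit.status == STATUS_OK
        mean = draws.mean()
        mus = np.linspace(mean * 0.02, 3 * mean, 150)
        ks = np.exp(np.linspace(math.log(0.01), math.log(50), 200))
        best = max(
            ((loglik(draws, m, kk), m, kk) for m in mus for kk in ks),
            key=lambda t: t[0],
        )
        # MLE log-likelihood dominates every grid point
        assert loglik(draws, fit.mu, fit.k) >= best[0] - 1e-9
        # and the grid optimum lands next to the MLE, within grid resolution
        assert abs(best[1] - fit.mu) <= mus[1] - mus[0]
        assert abs(math.log(best[2] / fit.k)) <= math.log(ks[1] / ks[0]) + 1e-9

    def test_mean_variance_relation_of_generated_draws(self):
        mu, k = 5.0, 1.0
        rng = np.random.default_rng(3)
        draws = rng.negative_binomial(k, k / (k + mu), size=100_000)
        assert draws.var() == pytest.approx(mu + mu**2 / k, rel=0.05)


class TestYearlyFitting:
    def _table_with_occupied(self, n_occupied):
        rows = [("R", 2000, f"t{j}", "other", 1) for j in range(10)]
        rows += [("R", 2000, f"t{j}", "sp", 2) for j in range(n_occupied)]
        return build_catch_table(
            pd.DataFrame(rows, columns=["region", "year", "tow", "species", "count"])
        )

    def test_species_in_two_tows_filtered_out(self):
        table = self._table_with_occupied(2)
        pt = fit_yearly_params(table, ["sp"])
        assert pt.frame["status"].tolist() == [STATUS_NOT_FIT]

    def test_species_in_three_tows_is_fitted(self):
        table = self._table_with_occupied(3)
        pt = fit_yearly_params(table, ["sp"])
        assert pt.frame["status"].iloc[0] in (STATUS_OK, STATUS_BOUNDARY)

    def test_individuals_filter_rule_counts_totals(self):
        # 3 individuals in a single tow: fails the tows rule, passes individuals
        rows = [("R", 2000, f"t{j}", "other", 1) for j in range(10)]
        rows += [("R", 2000, "t0", "sp", 3)]
        table = build_catch_table(
            pd.DataFrame(rows, columns=["region", "year", "tow", "species", "count"])
        )
        tows = fit_yearly_params(table, ["sp"], filter_rule="tows")
        indiv = fit_yearly_params(table, ["sp"], filter_rule="individuals")
        assert tows.frame["status"].iloc[0] == STATUS_NOT_FIT
        assert indiv.frame["status"].iloc[0] != STATUS_NOT_FIT

    def test_counts_assembled_over_full_roster(self):
        table = self._table_with_occupied(3)
        pt = fit_yearly_params(table, ["sp"])
        assert int(pt.frame["n_tows"].iloc[0]) == 10
        assert int(pt.frame["n_occupied"].iloc[0]) == 3

    def test_param_table_csv_round_trip(self, tmp_path, small_survey):
        community = sorted(small_survey.species("R1"))[:5]
        pt = fit_yearly_params(small_survey, community)
        path = tmp_path / "params.csv"
        pt.to_csv(path)
        back = ParamTable.from_csv(path)
        pd.testing.assert_frame_equal(back.frame, pt.frame)


def _param_table(rows):
    frame = pd.DataFrame(
        rows, columns=["region", "year", "species", "mu", "k", "status", "n_tows", "n_occupied"]
    )
    return ParamTable(frame=frame)


class TestMedianParams:
    def test_single_year_returns_that_year(self):
        pt = _param_table([("R", 2000, "A", 2.0, 1.0, STATUS_OK, 10, 5)])
        med = median_params(pt, "R")
        assert med["A"].mu == 2.0 and med["A"].k == 1.0

    def test_odd_count_median(self):
        pt = _param_table(
            [("R", y, "A", mu, 1.0, STATUS_OK, 10, 5) for y, mu in [(1, 1.0), (2, 2.0), (3, 9.0)]]
        )
        assert median_params(pt, "R")["A"].mu == 2.0

    def test_even_count_midpoint_convention(self):
        pt = _param_table(
            [("R", y, "A", mu, 1.0, STATUS_OK, 10, 5) for y, mu in [(1, 1.0), (2, 2.0), (3, 3.0), (4, 4.0)]]
        )
        assert median_params(pt, "R")["A"].mu == 2.5

    def test_not_fit_years_excluded_from_median(self):
        pt = _param_table(
            [
                ("R", 1, "A", 1.0, 1.0, STATUS_OK, 10, 5),
                ("R", 2, "A", 100.0, 1.0, STATUS_NOT_FIT, 10, 1),
                ("R", 3, "A", 3.0, 1.0, STATUS_OK, 10, 5),
            ]
        )
        assert median_params(pt, "R")["A"].mu == 2.0

    @given(st.permutations([1, 2, 3, 4, 5]))
    @settings(max_examples=20, deadline=None)
    def test_invariant_to_year_ordering(self, years):
        mus = {1: 1.0, 2: 5.0, 3: 2.0, 4: 8.0, 5: 3.0}
        pt = _param_table([("R", y, "A", mus[y], 1.0, STATUS_OK, 10, 5) for y in years])
        assert median_params(pt, "R")["A"].mu == 3.0


class TestParameterTrend:
    def test_strictly_increasing_series_has_tau_one(self):
        pt = _param_table(
            [("R", y, "A", float(y), 1.0, STATUS_OK, 10, 5) for y in range(1, 8)]
        )
        trend = parameter_trend(pt, "R", "mu")
        assert trend.tau == pytest.approx(1.0)
        assert trend.p_value < 0.05

    def test_constant_series_has_tau_zero(self):
        pt = _param_table(
            [("R", y, "A", 2.0, 1.0, STATUS_OK, 10, 5) for y in range(1, 8)]
        )
        trend = parameter_trend(pt, "R", "k")
        assert trend.tau == 0.0
        assert trend.p_value == 1.0

    def test_yearly_series_is_cross_species_mean(self):
        pt = _param_table(
            [
                ("R", 1, "A", 2.0, 1.0, STATUS_OK, 10, 5),
                ("R", 1, "B", 4.0, 1.0, STATUS_OK, 10, 5),
                ("R", 2, "A", 6.0, 1.0, STATUS_OK, 10, 5),
            ]
        )
        series = parameter_series(pt, "R", "mu")
        assert series.loc[1] == 3.0 and series.loc[2] == 6.0

    def test_fewer_than_three_years_rejected(self):
        pt = _param_table(
            [("R", y, "A", float(y), 1.0, STATUS_OK, 10, 5) for y in (1, 2)]
        )
        with pytest.raises(ValueError):
            parameter_trend(pt, "R", "mu")
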