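import math

import numpy as np
import pytest

from lunghist.progression import (
    ProgressionParams,
    TumorCourse,
    cells_at,
    detached_cells,
    diameter_from_volume,
    doubling_time_days,
    marginal_met_mode,
    marginal_met_pdf,
    met_cdf,
    nodal_only_pdf,
    sample_growth_rate,
    sample_met_times,
    volume_at,
    volume_from_diameter,
)

from _oracles import met_time_mc


class TestGrowth:
    def test_single_cell_start(self):
        assert cells_at(4.0, 0.0) == pytest.approx(1.0)
        assert volume_at(4.0, 0.0) == pytest.approx(1e-9)

    def test_one_doubling(self):
        lam = 3.3
        assert cells_at(lam, math.log(2.0) / lam) == pytest.approx(2.0)

    def test_closed_form(self):
        assert cells_at(4.37, 6.0) == pytest.approx(math.exp(26.22))

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            cells_at(4.0, -1.0)

    @pytest.mark.parametrize(
        "lam,days",
        [
            (6.30, 40.2),  # median localized-stage growth rate
            (365.0 * math.log(2.0), 1.0),
        ],
    )
    def test_doubling_time(self, lam, days):
        assert doubling_time_days(lam) == pytest.approx(days, abs=0.05)

    def test_mean_growth_rate_doubling_time_in_printed_range(self, pp):
        # E[lambda] = K theta = 4.37 -> doubling time inside 55-60 days
        assert 55.0 <= doubling_time_days(pp.K * pp.theta) <= 60.0

    def test_doubling_time_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            doubling_time_days(0.0)


class TestSphere:
    @pytest.mark.parametrize("v,d", [(0.06, 0.49), (0.16, 0.67)])
    def test_median_met_volumes_to_diameters(self, v, d):
        assert diameter_from_volume(v) == pytest.approx(d, abs=0.005)

    def test_round_trip(self):
        for v in (1e-9, 0.06, 4.2, 113.0):
            assert volume_from_diameter(diameter_from_volume(v)) == pytest.approx(
                v, rel=1e-12
            )

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            diameter_from_volume(0.0)
        with pytest.raises(ValueError):
            volume_from_diameter(-1.0)


class TestDetachment:
    def test_zero_at_onset(self):
        assert detached_cells(4.0, 0.01, 0.0) == 0.0

    def test_one_doubling_closed_form(self):
        lam = 2.0
        t = math.log(2.0) / lam
        assert detached_cells(lam, 0.01, t) == pytest.approx(0.01)

    def test_bounded_by_cell_count_at_xi_one(self):
        lam = 5.0
        for t in (0.5, 2.0, 7.0):
            assert detached_cells(lam, 1.0, t) < cells_at(lam, t)


class TestMetCdf:
    def test_cdf_properties(self):
        t = np.linspace(0.0, 20.0, 500)
        F = met_cdf(4.0, 0.01, 8.05e-9, t)
        assert F[0] == 0.0
        assert np.all(np.diff(F) >= 0.0)
        assert F[-1] > 0.999

    def test_matches_thinned_poisson_oracle(self):
        """Conditional c.d.f. vs first-event times of a simulated
        inhomogeneous Poisson process, within 3 SEs pointwise."""
        lam, xi, mu = 4.0, 0.01, 8.05e-9
        rng = np.random.default_rng(77)
        n = 20_000
        times = met_time_mc(lam, xi, mu, n, rng)
        for t in (4.5, 5.5, 6.5):
            emp = float((times <= t).mean())
            exact = float(met_cdf(lam, xi, mu, t))
            se = math.sqrt(exact * (1 - exact) / n)
            assert abs(emp - exact) < 3 * se + 0.003

    def test_nodal_stochastically_earlier_than_distant(self, pp):
        t = np.linspace(0.1, 15.0, 100)
        for lam in (2.0, 4.37, 8.0):
            Fn = met_cdf(lam, pp.xi, pp.mu_n, t)
            Fm = met_cdf(lam, pp.xi, pp.mu_m, t)
            assert np.all(Fn >= Fm)


class TestSampling:
    def test_growth_rate_moments(self, pp, rng):
        n = 100_000
        lam = sample_growth_rate(pp, rng, n)
        mean, var = pp.K * pp.theta, pp.K * pp.theta**2
        se_mean = math.sqrt(var / n)
        assert abs(lam.mean() - mean) < 3 * se_mean
        # SE of the sample variance of a gamma via 4th central moment
        m4 = (3 + 6 / pp.K) * var**2
        se_var = math.sqrt((m4 - var**2) / n)
        assert abs(lam.var() - var) < 3 * se_var

    def test_met_time_inversion_matches_cdf(self, pp):
        rng = np.random.default_rng(123)
        lam = np.full(50_000, 4.37)
        t_n, t_m = sample_met_times(lam, pp, rng)
        for t in (4.0, 5.0, 6.0):
            for times, mu in ((t_n, pp.mu_n), (t_m, pp.mu_m)):
                exact = float(met_cdf(4.37, pp.xi, mu, t))
                emp = float((times <= t).mean())
                se = math.sqrt(exact * (1 - exact) / len(times))
                assert abs(emp - exact) < 3 * se + 1e-4

    def test_nodal_ordering_in_distribution(self, pp, rng):
        lam = np.full(20_000, 3.0)
        t_n, t_m = sample_met_times(lam, pp, rng)
        for t in (5.0, 7.0, 9.0):
            assert (t_n <= t).mean() >= (t_m <= t).mean() - 0.01

    def test_reproducible(self, pp):
        lam = np.array([3.0, 4.0])
        a = sample_met_times(lam, pp, np.random.default_rng(9))
        b = sample_met_times(lam, pp, np.random.default_rng(9))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestMarginalDensities:
    def test_normalization(self, pp):
        # dense where the density lives, sparse on the slow-grower tail
        t = np.concatenate(
            [np.linspace(1e-3, 30.0, 900), np.linspace(30.1, 200.0, 400)]
        )
        for site in ("nodal", "distant"):
            f = marginal_met_pdf(pp, t, site=site)
            assert np.all(f >= 0.0)
            total = np.trapezoid(f, t)
            assert total == pytest.approx(1.0, abs=1e-3)

    def test_modes_with_calibrated_parameters(self, pp):
        """Nodal mode precedes the distant mode, both in the mid-single-digit
        years, with the nodal/distant spacing set by ln(mu_n/mu_m)."""
        m_n = marginal_met_mode(pp, "nodal")
        m_m = marginal_met_mode(pp, "distant")
        assert m_n < m_m
        ratio = (math.log(1.0 / (pp.xi * pp.mu_m)))/(math.log(1.0 / (pp.xi * pp.mu_n)))
        assert m_m / m_n == pytest.approx(ratio, rel=0.02)

    def test_degenerate_gamma_recovers_conditional_mode(self):
        """As the gamma law concentrates at lambda = c, the marginal mode
        converges to the conditional mode ln(1/(mu xi))/c."""
        c = 4.0
        K = 4000.0
        pp = ProgressionParams(K=K, theta=c / K)
        mode = marginal_met_mode(pp, "nodal")
        expected = math.log(1.0 / (pp.mu_n * pp.xi)) / c
        assert mode == pytest.approx(expected, rel=0.02)

    def test_nodal_only_bounded_by_marginal(self, pp):
        t = np.array([1.0, 3.0, 4.1, 6.0, 9.0])
        f_only = nodal_only_pdf(pp, t)
        f_marg = marginal_met_pdf(pp, t, site="nodal")
        assert np.all(f_only <= f_marg + 1e-12)

    def test_nodal_only_limit_no_distant_process(self):
        pp = ProgressionParams(mu_n=8.05e-9, mu_m=1e-16)
        t = np.array([2.0, 4.0, 6.0])
        assert np.allclose(nodal_only_pdf(pp, t), marginal_met_pdf(pp, t, "nodal"), rtol=1e-6)

    def test_nodal_only_matches_simulation(self, pp):
        """Binned nodal-only density vs direct simulation of both met
        processes, within 3 SEs per bin."""
        rng = np.random.default_rng(2024)
        n = 100_000
        lam = sample_growth_rate(pp, rng, n)
        t_n, t_m = sample_met_times(lam, pp, rng)
        edges = np.array([2.0, 3.0, 4.0, 5.0, 6.0, 8.0])
        for lo, hi in zip(edges, edges[1:]):
            p_emp = float(((t_n >= lo) & (t_n < hi) & (t_m > t_n)).mean())
            tt = np.linspace(lo, hi, 40)
            p_exact = np.trapezoid(nodal_only_pdf(pp, tt), tt)
            se = math.sqrt(p_exact * (1 - p_exact) / n)
            assert abs(p_emp - p_exact) < 3 * se + 1e-3


class TestParams:
    def test_ordering_enforced(self):
        with pytest.raises(ValueError):
            ProgressionParams(mu_n=1e-9, mu_m=2e-9)

    def test_xi_range(self):
        with pytest.raises(ValueError):
            ProgressionParams(xi=1.5)

    def test_course_validation(self):
        with pytest.raises(ValueError):
            TumorCourse(person_id=0, onset_age=60.0, lam=-1.0)
        with pytest.raises(ValueError):
            TumorCourse(person_id=0, onset_age=60.0, lam=4.0, t_nodal=-2.0)
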