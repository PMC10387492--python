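"""Structured population ODEs: discretization, integration, readouts."""

import numpy as np
import pytest

from pascar.kinetics import BindingParams, KPParams, ResponseParams
from pascar.population import (
    AbundanceGrid,
    PopulationParams,
    StructuredPopulation,
    car_moments,
    discretize_lognormal,
    integrate,
    percent_lysis,
    rate_tables,
    subpopulation_rates,
)

BINDING = BindingParams(k_off=9e-5, K_D=2.39)
KP = KPParams(k_p=0.0072, N=7.0)


def make_params(lambda_c=0.0, rho_c=0.0, r=0.0, delta=0.0, variant="KP",
                binding=BINDING, kp=KP):
    return PopulationParams(
        binding=binding, resp=ResponseParams(lambda_c, rho_c),
        kp=kp if variant == "KP" else None, r=r, delta=delta,
        model_variant=variant)


def single_bin_pop(T0=1000.0, U0=2000.0, R=1500.0, H=1e5):
    eps = 1e-6
    gR = AbundanceGrid(np.array([R * (1 - eps), R * (1 + eps)]))
    gH = AbundanceGrid(np.array([H * (1 - eps), H * (1 + eps)]))
    return StructuredPopulation(gR, gH, np.array([T0]), np.array([U0]))


class TestAbundanceGrid:
    def test_log_spaced_covers_six_sigma(self):
        g = AbundanceGrid.log_spaced(7.0, 0.5, n_bins=50)
        assert g.bin_edges[0] == pytest.approx(np.exp(7.0 - 3.0))
        assert g.bin_edges[-1] == pytest.approx(np.exp(7.0 + 3.0))
        assert g.n_bins == 50

    def test_centers_are_geometric_means(self):
        g = AbundanceGrid(np.array([1.0, 4.0, 16.0]))
        assert g.bin_centers == pytest.approx([2.0, 8.0])

    def test_non_monotone_edges_rejected(self):
        with pytest.raises(ValueError):
            AbundanceGrid(np.array([1.0, 3.0, 2.0]))

    def test_nearest_bin(self):
        g = AbundanceGrid.log_spaced(np.log(1000.0), 1.0, n_bins=30)
        j = g.nearest_bin(1000.0)
        assert abs(np.log(g.bin_centers[j]) - np.log(1000.0)) <= \
            np.diff(np.log(g.bin_edges)).max() / 2 + 1e-12


class TestDiscretizeLognormal:
    def test_sums_to_total(self):
        g = AbundanceGrid.log_spaced(7.0, 0.5, n_bins=80)
        v = discretize_lognormal(7.0, 0.5, 12345.0, g)
        assert v.sum() == pytest.approx(12345.0, rel=1e-9)

    def test_median_split(self):
        g = AbundanceGrid.log_spaced(7.0, 0.5, n_bins=200)
        v = discretize_lognormal(7.0, 0.5, 1.0, g)
        below = v[g.bin_edges[1:] <= np.exp(7.0)].sum()
        assert below == pytest.approx(0.5, abs=0.01)

    def test_mean_matches_analytic(self):
        mu, sig = 7.0, 0.5
        g = AbundanceGrid.log_spaced(mu, sig, n_bins=100)
        v = discretize_lognormal(mu, sig, 1000.0, g)
        mean = np.dot(v, g.bin_centers) / v.sum()
        assert mean == pytest.approx(np.exp(mu + sig ** 2 / 2), rel=0.01)

    def test_uncovering_grid_rejected(self):
        g = AbundanceGrid.log_spaced(7.0, 0.5, n_bins=20, span=1.0)
        with pytest.raises(ValueError, match="covers only"):
            discretize_lognormal(7.0, 2.0, 100.0, g)


class TestRateTables:
    def test_zero_receptor_row_is_zero(self):
        gR = AbundanceGrid(np.array([0.0, 1e-9, 100.0, 1000.0]))
        gH = AbundanceGrid.log_spaced(10.0, 0.5, n_bins=5)
        lam, rho = rate_tables(gR, gH, make_params(1e-8, 1e-8))
        assert np.all(lam[0] == 0.0)
        assert np.all(rho[0] == 0.0)

    def test_kp_with_n_zero_equals_nkp(self):
        gR = AbundanceGrid.log_spaced(7.0, 0.5, n_bins=10)
        gH = AbundanceGrid.log_spaced(11.0, 0.5, n_bins=10)
        lam_kp, _ = rate_tables(gR, gH, make_params(
            1e-8, 1e-8, kp=KPParams(k_p=0.0072, N=0.0)))
        lam_nkp, _ = rate_tables(gR, gH, make_params(
            1e-8, 1e-8, variant="NKP"))
        assert lam_kp == pytest.approx(lam_nkp, rel=1e-12)

    def test_monotone_in_both_axes(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            gR = AbundanceGrid.log_spaced(rng.uniform(5, 9),
                                          rng.uniform(0.3, 1.0), n_bins=12)
            gH = AbundanceGrid.log_spaced(rng.uniform(9, 14),
                                          rng.uniform(0.3, 1.0), n_bins=12)
            lam, _ = rate_tables(gR, gH, make_params(1e-8, 1e-8))
            assert np.all(np.diff(lam, axis=0) >= -1e-15)
            assert np.all(np.diff(lam, axis=1) >= -1e-15)


class TestIntegrate:
    def test_decoupled_exponentials(self):
        gR = AbundanceGrid.log_spaced(7.0, 0.5, n_bins=10)
        gH = AbundanceGrid.log_spaced(11.0, 0.5, n_bins=10)
        T0 = discretize_lognormal(7.0, 0.5, 1000.0, gR)
        U0 = discretize_lognormal(11.0, 0.5, 2000.0, gH)
        pop0 = StructuredPopulation(gR, gH, T0, U0)
        params = make_params(0.0, 0.0, r=0.4, delta=0.25)
        traj = integrate(pop0, params, [0.0, 1.0, 3.0])
        for i, t in enumerate(traj.times):
            assert traj.U[i] == pytest.approx(U0 * np.exp(0.4 * t), rel=1e-7)
            assert traj.T[i] == pytest.approx(T0 * np.exp(-0.25 * t), rel=1e-7)

    def test_single_bin_closed_form_decay(self):
        # constant T: U(t) = U(0) exp(-lam * T0 * t)
        pop0 = single_bin_pop()
        params = make_params(lambda_c=1e-8, rho_c=0.0)
        from pascar.kinetics import kp_active_complex
        lam = 1e-8 * kp_active_complex(
            pop0.grid_R.bin_centers[0], pop0.grid_H.bin_centers[0],
            BINDING, KP)
        traj = integrate(pop0, params, [0.0, 1.0, 2.0, 3.0])
        for i, t in enumerate(traj.times):
            expected = 2000.0 * np.exp(-lam * 1000.0 * t)
            assert traj.U[i, 0] == pytest.approx(expected, rel=1e-6)

    def test_matches_fine_step_euler_oracle(self):
        gR = AbundanceGrid(np.array([500.0, 1500.0, 4000.0]))
        gH = AbundanceGrid(np.array([3e4, 1e5, 4e5]))
        T0 = np.array([600.0, 400.0])
        U0 = np.array([1200.0, 800.0])
        params = make_params(2e-8, 1.5e-8, r=0.1, delta=0.05)
        lam, rho = rate_tables(gR, gH, params)

        dt = 1e-4
        T, U = T0.copy(), U0.copy()
        for _ in range(int(round(3.0 / dt))):
            kill = lam.T @ T
            grow = rho @ U
            T, U = (T + dt * ((grow - params.delta) * T),
                    U + dt * ((params.r - kill) * U))

        traj = integrate(StructuredPopulation(gR, gH, T0, U0), params,
                         [0.0, 3.0])
        assert traj.T[-1] == pytest.approx(T, rel=1e-4)
        assert traj.U[-1] == pytest.approx(U, rel=1e-4)

    def test_rk4_matches_adaptive(self):
        gR = AbundanceGrid.log_spaced(7.0, 0.5, n_bins=15)
        gH = AbundanceGrid.log_spaced(11.0, 0.7, n_bins=15)
        pop0 = StructuredPopulation(
            gR, gH, discretize_lognormal(7.0, 0.5, 1e4, gR),
            discretize_lognormal(11.0, 0.7, 2e4, gH))
        params = make_params(2e-8, 5e-9)
        t_adapt = integrate(pop0, params, [0.0, 3.0], method="RK45",
                            rtol=1e-10, atol=1e-10)
        t_fixed = integrate(pop0, params, [0.0, 3.0], method="rk4",
                            n_steps=120)
        assert t_fixed.U[-1] == pytest.approx(t_adapt.U[-1], rel=1e-6)
        assert t_fixed.T[-1] == pytest.approx(t_adapt.T[-1], rel=1e-6)

    def test_conservation_without_proliferation_or_death(self):
        gR = AbundanceGrid.log_spaced(7.0, 0.5, n_bins=12)
        gH = AbundanceGrid.log_spaced(11.0, 0.5, n_bins=12)
        pop0 = StructuredPopulation(
            gR, gH, discretize_lognormal(7.0, 0.5, 1e4, gR),
            discretize_lognormal(11.0, 0.5, 2e4, gH))
        traj = integrate(pop0, make_params(3e-8, 0.0), [0.0, 2.0, 5.0])
        for i in range(len(traj.times)):
            assert traj.T[i].sum() == pytest.approx(1e4, rel=1e-8)

    def test_no_mixing_empty_bins_stay_empty(self):
        gR = AbundanceGrid.log_spaced(7.0, 0.5, n_bins=10)
        gH = AbundanceGrid.log_spaced(11.0, 0.5, n_bins=10)
        T0 = discretize_lognormal(7.0, 0.5, 1e4, gR)
        T0[[0, 7]] = 0.0
        pop0 = StructuredPopulation(
            gR, gH, T0, discretize_lognormal(11.0, 0.5, 2e4, gH))
        traj = integrate(pop0, make_params(2e-8, 2e-8), [0.0, 3.0])
        assert traj.T[-1][0] == 0.0
        assert traj.T[-1][7] == 0.0

    def test_nonnegative_throughout(self):
        gR = AbundanceGrid.log_spaced(7.0, 0.5, n_bins=10)
        gH = AbundanceGrid.log_spaced(11.0, 0.5, n_bins=10)
        pop0 = StructuredPopulation(
            gR, gH, discretize_lognormal(7.0, 0.5, 1e4, gR),
            discretize_lognormal(11.0, 0.5, 2e4, gH))
        traj = integrate(pop0, make_params(1e-6, 1e-8), np.linspace(0, 3, 13))
        assert np.all(traj.U >= 0.0)
        assert np.all(traj.T >= 0.0)


class TestPercentLysis:
    def test_no_effectors(self):
        pop0 = single_bin_pop(T0=0.0)
        traj = integrate(pop0, make_params(1e-8, 0.0), [0.0, 3.0])
        assert percent_lysis(traj, 3.0) == pytest.approx(0.0, abs=1e-9)

    def test_single_bin_closed_form(self):
        pop0 = single_bin_pop()
        params = make_params(lambda_c=1e-8)
        from pascar.kinetics import kp_active_complex
        lam = 1e-8 * kp_active_complex(
            pop0.grid_R.bin_centers[0], pop0.grid_H.bin_centers[0],
            BINDING, KP)
        traj = integrate(pop0, params, [0.0, 3.0])
        assert percent_lysis(traj, 3.0) == pytest.approx(
            100.0 * (1.0 - np.exp(-lam * 1000.0 * 3.0)), rel=1e-6)

    def test_bounded_above_by_100(self):
        pop0 = single_bin_pop()
        traj = integrate(pop0, make_params(lambda_c=1e-4), [0.0, 3.0])
        assert 99.0 < percent_lysis(traj, 3.0) <= 100.0

    def test_control_accounts_for_target_growth(self):
        # with no killing but r > 0, lysis stays 0 (targets match control)
        pop0 = single_bin_pop()
        traj = integrate(pop0, make_params(0.0, 0.0, r=0.5), [0.0, 3.0])
        assert percent_lysis(traj, 3.0) == pytest.approx(0.0, abs=1e-4)

    def test_grid_refinement_converged(self):
        results = []
        for n_bins in (100, 200):
            gR = AbundanceGrid.log_spaced(7.3589, 0.4672, n_bins=n_bins)
            gH = AbundanceGrid.log_spaced(6.2 * np.log(10), 0.69,
                                          n_bins=n_bins)
            pop0 = StructuredPopulation(
                gR, gH, discretize_lognormal(7.3589, 0.4672, 1e4, gR),
                discretize_lognormal(6.2 * np.log(10), 0.69, 2e4, gH))
            traj = integrate(pop0, make_params(2.09e-8, 5.31e-9),
                             [0.0, 3.0], method="rk4", n_steps=150)
            results.append(percent_lysis(traj, 3.0))
        assert abs(results[1] - results[0]) < 0.5


class TestCarMoments:
    def test_single_occupied_bin(self):
        gR = AbundanceGrid(np.array([50.0, 200.0, 450.0]))
        gH = AbundanceGrid(np.array([1.0, 2.0]))
        pop = StructuredPopulation(gR, gH, np.array([100.0, 0.0]),
                                   np.array([1.0]))
        mean, var = car_moments(pop)
        assert mean == pytest.approx(gR.bin_centers[0])
        assert var == 0.0

    def test_two_equal_bins(self):
        gR = AbundanceGrid(np.array([50.0, 200.0, 450.0]))
        gH = AbundanceGrid(np.array([1.0, 2.0]))
        pop = StructuredPopulation(gR, gH, np.array([5.0, 5.0]),
                                   np.array([1.0]))
        # centers 100 and 300: mean 200, variance 10000
        mean, var = car_moments(pop)
        assert mean == pytest.approx(200.0)
        assert var == pytest.approx(10_000.0)

    def test_recovers_lognormal_moments(self):
        mu, sig = 7.3589, 0.4672
        gR = AbundanceGrid.log_spaced(mu, sig, n_bins=120)
        gH = AbundanceGrid(np.array([1.0, 2.0]))
        pop = StructuredPopulation(
            gR, gH, discretize_lognormal(mu, sig, 1e4, gR), np.array([1.0]))
        mean, var = car_moments(pop)
        m_true = np.exp(mu + sig ** 2 / 2)
        v_true = (np.exp(sig ** 2) - 1) * np.exp(2 * mu + sig ** 2)
        assert mean == pytest.approx(m_true, rel=0.01)
        assert var == pytest.approx(v_true, rel=0.05)
        mean_log, var_log = car_moments(pop, log_scale=True)
        assert mean_log == pytest.approx(mu, abs=0.01)
        assert np.sqrt(var_log) == pytest.approx(sig, rel=0.02)

    def test_empty_population_signals(self):
        gR = AbundanceGrid(np.array([1.0, 2.0]))
        gH = AbundanceGrid(np.array([1.0, 2.0]))
        pop = StructuredPopulation(gR, gH, np.array([0.0]), np.array([1.0]))
        with pytest.raises(ValueError, match="empty"):
            car_moments(pop)


class TestSubpopulationRates:
    @staticmethod
    def setup_traj():
        gR = AbundanceGrid.log_spaced(7.3589, 0.4672, n_bins=40)
        gH = AbundanceGrid.log_spaced(6.2 * np.log(10), 0.69, n_bins=30)
        pop0 = StructuredPopulation(
            gR, gH, discretize_lognormal(7.3589, 0.4672, 1e4, gR),
            discretize_lognormal(6.2 * np.log(10), 0.69, 2e4, gH))
        params = make_params(2.09e-8, 5.31e-9)
        times = [0.0, 1.0, 2.0, 3.0]
        return integrate(pop0, params, times, method="rk4",
                         n_steps=150), params

    def test_empty_bin_contributes_nothing(self):
        traj, params = self.setup_traj()
        pop = traj.state_at(0.0)
        pop.T[5] = 0.0
        rates = subpopulation_rates(pop, params, H_bar=10 ** 6.2)
        assert rates.c_lysis[5] == 0.0

    def test_lysis_contribution_grows_with_proliferation(self):
        # effector subpopulations grow while targets persist (day 0 -> 3)
        traj, params = self.setup_traj()
        r0 = subpopulation_rates(traj.state_at(0.0), params, 10 ** 6.2)
        r3 = subpopulation_rates(traj.state_at(3.0), params, 10 ** 6.2)
        i_mode = int(np.argmax(r0.c_lysis))
        assert r3.c_lysis[i_mode] > r0.c_lysis[i_mode]

    def test_proliferation_rate_falls_as_targets_die(self):
        traj, params = self.setup_traj()
        r0 = subpopulation_rates(traj.state_at(0.0), params, 10 ** 6.2)
        r3 = subpopulation_rates(traj.state_at(3.0), params, 10 ** 6.2)
        assert np.all(r3.c_prolif <= r0.c_prolif + 1e-15)

    def test_peak_persists_at_intermediate_abundance(self):
        # growth advantage of high-R bins cannot overcome their small
        # initial size by day 3: the modal bin stays put
        traj, params = self.setup_traj()
        i0 = int(np.argmax(traj.T[0]))
        i3 = int(np.argmax(traj.T[-1]))
        assert abs(i3 - i0) <= 1
        g = np.log(traj.T[-1] / traj.T[0]) / 3.0   # realized growth rates
        i_hi = len(g) - 5
        ratio0 = traj.T[0, i0] / traj.T[0, i_hi]
        assert ratio0 > np.exp((g[i_hi] - g[i0]) * 3.0)
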