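"""Regressions, Price partition and the spandrel assay."""

import numpy as np
import pytest

from quorumevo.analysis import (
    assortment_analysis,
    compare_slopes,
    constraint_regression,
    cooperative_investment,
    on_fraction_curve,
    price_decomposition,
    spandrel_assay,
)
from quorumevo.core_dynamics import DynamicsParams, SignalEnvironment
from quorumevo.fitness import DEFAULT_N_TH, PayoffParams, evaluate_group
from quorumevo.population import Genotype, Population, make_cheat


class TestOnFractionCurve:
    def test_constitutive_pool_is_on_everywhere(self, default_grid, env, dyn):
        pop = Population.uniform(10, Genotype(p=0.0, S_Th=50.0))
        curve = on_fraction_curve(pop, default_grid, env, dyn, PayoffParams(mode="constitutive"))
        assert np.all(curve == 1.0)

    def test_signal_free_pool_is_off_everywhere(self, default_grid, env, dyn):
        pop = Population.uniform(10, Genotype(p=0.0, S_Th=1.0))
        curve = on_fraction_curve(pop, default_grid, env, dyn, PayoffParams())
        assert np.all(curve == 0.0)

    def test_tuned_genotype_steps_at_threshold_density(self, default_grid, env, dyn):
        p = 5e-9
        pop = Population.uniform(1, Genotype(p=p, S_Th=p * DEFAULT_N_TH / env.u))
        curve = on_fraction_curve(pop, default_grid, env, dyn, PayoffParams())
        np.testing.assert_array_equal(curve, (default_grid.densities > DEFAULT_N_TH) * 1.0)


class TestConstraintRegression:
    def test_exact_line_recovers_predicted_slope(self):
        # points generated exactly on S_Th = p N_Th / u must return the
        # parameter-free slope N_Th / u = 5.0016e8
        p = np.array([1e-9, 3e-9, 5e-9, 8e-9, 1.2e-8])
        slope_true = DEFAULT_N_TH / 1e-4
        fit = constraint_regression(p, p * slope_true, N_Th=DEFAULT_N_TH, u=1e-4)
        assert fit.predicted_slope == pytest.approx(5.0016e8, rel=1e-5)
        assert fit.slope == pytest.approx(slope_true, rel=1e-10)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_has_low_r_squared(self, rng):
        x = rng.uniform(0, 1, 200)
        y = rng.uniform(0, 1, 200)
        fit = constraint_regression(x, y, N_Th=DEFAULT_N_TH, u=1e-4)
        assert fit.r_squared < 0.1

    def test_degenerate_predictor_rejected(self):
        with pytest.raises(ValueError):
            constraint_regression(np.ones(5), np.arange(5.0), N_Th=1e4, u=1e-4)


class TestAssortment:
    def test_clonal_groups_have_unit_slope(self, default_grid, env, dyn):
        # every individual alone: group mean investment equals individual
        # investment, so the regression is the identity
        rng = np.random.default_rng(5)
        inds, grps = [], []
        for _ in range(30):
            p = rng.uniform(1e-9, 1e-8)
            g = Genotype(p=p, S_Th=rng.uniform(0.5, 5.0))
            ev = evaluate_group([g], default_grid, env, dyn, PayoffParams())
            ind, grp = cooperative_investment(ev)
            inds.append(ind[0])
            grps.append(grp[0])
        fit = assortment_analysis(np.array(inds), np.array(grps))
        assert fit.slope == pytest.approx(1.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_investment_extremes(self, default_grid, env, dyn):
        always = Genotype(p=0.0, S_Th=50.0)
        ev = evaluate_group([always], default_grid, env, dyn, PayoffParams(mode="constitutive"))
        assert cooperative_investment(ev)[0][0] == 1.0
        ev = evaluate_group([make_cheat()], default_grid, env, dyn, PayoffParams())
        assert cooperative_investment(ev)[0][0] == 0.0

    def test_identical_datasets_have_equal_slopes(self, rng):
        x = rng.uniform(0, 1, 100)
        y = 0.5 * x + rng.normal(0, 0.05, 100)
        f_stat, p_value = compare_slopes(x, y, x, y)
        assert f_stat == pytest.approx(0.0, abs=1e-20)
        assert p_value > 0.99

    def test_different_slopes_detected(self, rng):
        x = rng.uniform(0, 1, 200)
        y_a = 0.2 * x + rng.normal(0, 0.02, 200)
        y_b = 0.9 * x + rng.normal(0, 0.02, 200)
        f_stat, p_value = compare_slopes(x, y_a, x, y_b)
        assert p_value < 1e-6


class TestPriceDecomposition:
    def test_two_group_hand_example(self):
        # brute-force oracle: totals computed directly from definitions
        gid = np.array([0, 0, 1, 1])
        w = np.array([1.0, 2.0, 1.0, 2.0])
        z = np.array([0.0, 1.0, 1.0, 0.0])
        terms = price_decomposition(gid, w, z)
        total = float(np.sum(w * z) / w.sum() - z.mean())
        w_bar = w.mean()
        W_g = np.array([w[:2].mean(), w[2:].mean()])
        z_g = np.array([z[:2].mean(), z[2:].mean()])
        between = float(np.mean(W_g * z_g) - w_bar * np.mean(z_g)) / w_bar
        dz_g = np.array(
            [np.sum(w[:2] * z[:2]) / w[:2].sum() - z_g[0],
             np.sum(w[2:] * z[2:]) / w[2:].sum() - z_g[1]]
        )
        within = float(np.mean(W_g * dz_g)) / w_bar
        assert terms.between_group == pytest.approx(between, abs=1e-15)
        assert terms.within_group == pytest.approx(within, abs=1e-15)
        assert terms.total == pytest.approx(total, abs=1e-15)
        assert terms.between_group + terms.within_group == pytest.approx(total, abs=1e-12)

    def test_internally_clonal_groups_have_no_within_term(self):
        gid = np.array([0, 0, 1, 1, 2, 2])
        z = np.array([1.0, 1.0, 0.2, 0.2, 0.7, 0.7])
        w = np.array([2.0, 2.0, 1.0, 1.0, 3.0, 3.0])
        terms = price_decomposition(gid, w, z)
        assert terms.within_group == pytest.approx(0.0, abs=1e-15)

    def test_uniform_fitness_means_no_selection(self):
        gid = np.array([0, 0, 1, 1])
        z = np.array([0.1, 0.9, 0.4, 0.6])
        terms = price_decomposition(gid, np.ones(4), z)
        assert terms.between_group == pytest.approx(0.0, abs=1e-15)
        assert terms.within_group == pytest.approx(0.0, abs=1e-15)
        assert terms.total == pytest.approx(0.0, abs=1e-15)

    def test_identity_on_random_populations(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n_groups = rng.integers(2, 12)
            sizes = rng.integers(1, 9, n_groups)
            gid = np.repeat(np.arange(n_groups), sizes)
            n = gid.size
            w = rng.uniform(0, 5, n)
            if w.sum() == 0:
                w[0] = 1.0
            z = rng.normal(0, 1, n)
            zp = z + rng.normal(0, 0.1, n)
            terms = price_decomposition(gid, w, z, zp)
            lhs = terms.between_group + terms.within_group
            scale = max(1.0, abs(terms.total))
            assert abs(lhs - terms.total) / scale < 1e-10

    def test_zero_mean_fitness_rejected(self):
        with pytest.raises(ValueError):
            price_decomposition(np.array([0, 1]), np.zeros(2), np.array([0.0, 1.0]))


class TestSpandrelAssay:
    def test_reference_strain_thresholds(self):
        # thresholds follow m* = pN/S_Th - u from the strain parameters
        cases = {
            "clonal": (Genotype(p=4.37e-9, S_Th=2.15), 7.277e-5),
            "intermediate": (Genotype(p=9.27e-9, S_Th=4.63), 7.018e-5),
            "low_relatedness": (Genotype(p=8.71e-9, S_Th=7.27), 1.836e-6),
        }
        m_stars = {}
        for name, (strain, expected) in cases.items():
            prof = spandrel_assay(strain, N=8.5e4, u=1e-4)
            assert prof.m_star == pytest.approx(expected, rel=1e-3)
            m_stars[name] = prof.m_star
        # clonal and intermediate strains share a near-identical boundary;
        # the low-relatedness strain is far more sensitive to signal loss
        assert abs(m_stars["clonal"] - m_stars["intermediate"]) < 0.05 * m_stars["clonal"]
        assert m_stars["low_relatedness"] < 0.1 * m_stars["clonal"]

    def test_signal_curve_strictly_decreasing(self):
        prof = spandrel_assay(Genotype(p=4.37e-9, S_Th=2.15), N=8.5e4, u=1e-4)
        assert (np.diff(prof.s_star) < 0).all()
        assert prof.s_star[0] == pytest.approx(4.37e-9 * 8.5e4 / 1e-4, rel=1e-12)

    def test_on_region_consistent_with_threshold(self):
        prof = spandrel_assay(Genotype(p=4.37e-9, S_Th=2.15), N=8.5e4, u=1e-4)
        np.testing.assert_array_equal(prof.on, prof.m < prof.m_star)

    def test_unreachable_threshold_is_never_on(self):
        prof = spandrel_assay(Genotype(p=1e-10, S_Th=10.0), N=1e4, u=1e-4)
        assert prof.m_star is None
        assert not prof.on.any()

    def test_autoregulating_strain_threshold_by_root_finding(self):
        strain = Genotype(p=1.2e-9, S_Th=2.0, r=8.0)
        prof = spandrel_assay(strain, N=8.5e4, u=1e-4, dyn=DynamicsParams(K=10.0))
        assert prof.m_star is not None
        # at m = m* the equilibrium equals the threshold
        from quorumevo.core_dynamics import equilibrium_auto

        env = SignalEnvironment(N=8.5e4, u=1e-4, m=prof.m_star)
        s = equilibrium_auto(strain.p * 8.5e4, strain.p * strain.r * 8.5e4, DynamicsParams(K=10.0), env)
        assert s == pytest.approx(strain.S_Th, rel=1e-9)
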