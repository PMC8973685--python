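"""Class construction, HMF dynamics, stationary solver, and thresholds."""

import numpy as np
import pytest

from spreadrank.centrality import betweenness, degree
from spreadrank.generators import fixture_graph
from spreadrank.meanfield import (
    EpidemicParams,
    MetricClasses,
    build_classes,
    epidemic_threshold,
    hmf_rhs,
    integrate_hmf,
    prevalence_curve,
    stationary_prevalence,
    theta,
)


def random_classes(seed: int, n: int = 6) -> MetricClasses:
    rng = np.random.default_rng(seed)
    values = np.sort(rng.choice(np.arange(1, 60), size=n, replace=False)).astype(float)
    probs = rng.dirichlet(np.ones(n))
    probs = probs / probs.sum()
    return MetricClasses(
        values=values,
        probs=probs,
        first_moment=float(values @ probs),
        second_moment=float(values**2 @ probs),
    )


class TestBuildClasses:
    def test_star_degree(self, star4):
        cl = build_classes(degree(star4))
        assert cl.values == pytest.approx([1, 4])
        assert cl.probs == pytest.approx([0.8, 0.2])
        assert cl.first_moment == pytest.approx(1.6)
        assert cl.second_moment == pytest.approx(4.0)

    def test_star_betweenness_keeps_zero_class(self, star4):
        cl = build_classes(betweenness(star4))
        assert cl.values == pytest.approx([0, 6])
        assert cl.probs == pytest.approx([0.8, 0.2])
        assert cl.first_moment == pytest.approx(1.2)
        assert cl.second_moment == pytest.approx(7.2)

    def test_regular_single_class(self):
        cl = build_classes(degree(fixture_graph("regular", n=20, k=10)))
        assert cl.n_classes == 1
        assert (cl.first_moment, cl.second_moment) == (10.0, 100.0)

    def test_all_zero_metric_rejected(self):
        cl_input = betweenness(fixture_graph("complete", n=4))
        with pytest.raises(ValueError, match="zero"):
            build_classes(cl_input)

    def test_moments_recomputable(self, ba_small):
        cl = build_classes(degree(ba_small))
        assert cl.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert cl.first_moment == pytest.approx(cl.values @ cl.probs)
        assert cl.second_moment == pytest.approx(cl.values**2 @ cl.probs)


class TestThresholdAndTheta:
    def test_threshold_formulas(self, star4):
        reg = build_classes(degree(fixture_graph("regular", n=20, k=10)))
        assert epidemic_threshold(reg) == pytest.approx(0.1)
        assert epidemic_threshold(build_classes(degree(star4))) == pytest.approx(0.4)
        assert epidemic_threshold(build_classes(betweenness(star4))) == pytest.approx(1 / 6)

    def test_theta_limits(self, star4):
        cl = build_classes(degree(star4))
        assert theta(cl, [0.0, 0.0]) == 0.0
        assert theta(cl, [1.0, 1.0]) == pytest.approx(1.0)
        reg = build_classes(degree(fixture_graph("regular", n=20, k=10)))
        assert theta(reg, [0.37]) == pytest.approx(0.37)

    def test_rhs(self, star4):
        cl = build_classes(degree(star4))
        params = EpidemicParams(lam=0.5)
        assert hmf_rhs(cl, params, np.zeros(2)) == pytest.approx([0.0, 0.0])
        reg = build_classes(degree(fixture_graph("regular", n=20, k=10)))
        rho = np.array([0.3])
        # single class: -rho + lam*k*rho*(1-rho)
        assert hmf_rhs(reg, params, rho) == pytest.approx(-0.3 + 0.5 * 10 * 0.3 * 0.7)

    def test_zero_valued_class_decays(self, star4):
        cl = build_classes(betweenness(star4))
        rates = hmf_rhs(cl, EpidemicParams(lam=2.0), np.array([0.4, 0.0]))
        assert rates[0] == pytest.approx(-0.4)  # x=0 class: pure recovery


class TestStationary:
    def test_single_class_closed_form(self):
        reg = build_classes(degree(fixture_graph("regular", n=20, k=10)))
        st = stationary_prevalence(reg, 0.2)
        assert st.rho == pytest.approx(0.5, abs=1e-10)

    def test_star_fixed_point_hand_checkable(self, star4):
        st = stationary_prevalence(build_classes(degree(star4)), 1.0)
        assert st.theta == pytest.approx(0.5, abs=1e-10)
        assert st.rho == pytest.approx(0.4, abs=1e-10)
        assert st.rho_per_class == pytest.approx([1 / 3, 2 / 3], abs=1e-10)

    def test_below_threshold_is_zero(self):
        for seed in range(4):
            cl = random_classes(seed)
            lam = 0.5 * epidemic_threshold(cl)
            assert stationary_prevalence(cl, lam).rho == 0.0

    def test_monotone_in_lambda(self):
        for seed in range(4):
            cl = random_classes(seed)
            lam_c = epidemic_threshold(cl)
            curve = prevalence_curve(cl, np.linspace(0, 4 * lam_c, 30))
            rho = curve["rho"].to_numpy()
            assert (np.diff(rho) >= -1e-12).all()

    def test_monotone_in_class_values(self):
        cl = random_classes(1)
        bigger = MetricClasses(
            values=cl.values * 1.5,
            probs=cl.probs,
            first_moment=cl.first_moment * 1.5,
            second_moment=cl.second_moment * 1.5**2,
        )
        lam = 2 * epidemic_threshold(cl)
        assert stationary_prevalence(bigger, lam).rho >= stationary_prevalence(cl, lam).rho


class TestIntegration:
    def test_lambda_zero_is_pure_decay(self, star4):
        cl = build_classes(degree(star4))
        traj = integrate_hmf(cl, EpidemicParams(lam=0.0, rho0=0.3), t_max=5.0)
        expected = 0.3 * np.exp(-traj.times)
        assert traj.rho[:, 0] == pytest.approx(expected, abs=1e-6)
        assert traj.rho[:, 1] == pytest.approx(expected, abs=1e-6)

    def test_single_class_logistic_fixed_point(self):
        reg = build_classes(degree(fixture_graph("regular", n=20, k=10)))
        traj = integrate_hmf(reg, EpidemicParams(lam=0.2, rho0=0.05), t_max=200.0)
        assert traj.final_state()[0] == pytest.approx(0.5, abs=1e-6)

    @pytest.mark.parametrize("seed", range(3))
    def test_ode_agrees_with_fixed_point(self, seed):
        cl = random_classes(seed)
        lam = 2.5 * epidemic_threshold(cl)
        traj = integrate_hmf(cl, EpidemicParams(lam=lam, rho0=0.05), t_max=400.0)
        st = stationary_prevalence(cl, lam)
        assert traj.final_state() == pytest.approx(st.rho_per_class, abs=1e-6)

    def test_trajectory_stays_in_unit_interval(self):
        cl = random_classes(2)
        traj = integrate_hmf(cl, EpidemicParams(lam=1.0, rho0=0.5), t_max=50.0)
        assert traj.rho.min() >= 0.0 and traj.rho.max() <= 1.0


class TestEpidemicParams:
    def test_validation(self):
        with pytest.raises(ValueError):
            EpidemicParams(lam=-0.1)
        with pytest.raises(ValueError):
            EpidemicParams(lam=0.1, mu=0.5)
        with pytest.raises(ValueError):
            EpidemicParams(lam=0.1, rho0=0.0)
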