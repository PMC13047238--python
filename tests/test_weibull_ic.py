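import numpy as np
import pytest
from scipy.integrate import quad

import idmauc as m
from idmauc.weibull import _p00, _p11, weibull_hazard

P = m.SIMULATION_TRUTH


def _iv(L, R, tstar, delta, id="s"):
    return m.IntervalSummary(id, L, R, tstar, delta)


class TestLoglikContributions:
    def test_never_positive_censored_at_last_visit(self):
        # L = C: the bracket collapses to P00(0, C)
        C = 30.0
        ll = m.weibull_ic_loglik(P, [_iv(C, None, C, 0)])
        assert ll == pytest.approx(np.log(_p00(P, 0, C)), abs=1e-12)

    def test_never_positive_death_just_after_last_screen(self):
        # L -> T*: contribution tends to P00(0,T*) * lambda02(T*)
        T = 40.0
        ll = m.weibull_ic_loglik(P, [_iv(T - 1e-7, None, T, 1)])
        expected = np.log(_p00(P, 0, T) * weibull_hazard(P, "02", T))
        assert ll == pytest.approx(expected, abs=1e-5)

    def test_constant_hazard_closed_form(self):
        # with all shapes 1 the onset integral is the piecewise model's P01
        q01, q02, q12 = 0.02, 0.01, 0.08
        p = m.WeibullIDMParams(k01=1, k02=1, k12=1, a01=q01, a02=q02, a12=q12)
        L, R, T = 6.0, 12.0, 20.0
        d = R - L
        p01 = q01 / (q01 + q02 - q12) * (np.exp(-q12 * d) - np.exp(-(q01 + q02) * d))
        expected = np.log(np.exp(-(q01 + q02) * L) * p01 * np.exp(-q12 * (T - R)))
        assert m.weibull_ic_loglik(p, [_iv(L, R, T, 0)]) == pytest.approx(expected, abs=1e-8)

    @pytest.mark.parametrize("L,R,T,delta", [(0.0, 3.0, 50.0, 1), (9.0, 12.0, 30.0, 0),
                                             (0.0, 12.0, 100.0, 1), (24.0, 36.0, 40.0, 1)])
    def test_against_adaptive_quadrature(self, L, R, T, delta):
        # oracle: direct adaptive quadrature of the onset integral
        def integrand(u):
            return (
                _p00(P, L, u) * weibull_hazard(P, "01", u) * _p11(P, u, T)
            )

        integral, _ = quad(integrand, L, R, epsabs=1e-12, limit=500)
        factor = weibull_hazard(P, "12", T) if delta else 1.0
        expected = np.log(_p00(P, 0, L) * integral * factor)
        got = m.weibull_ic_loglik(P, [_iv(L, R, T, delta)])
        assert got == pytest.approx(expected, abs=1e-8)

    def test_interval_likelihood_converges_to_exact_density(self):
        # as the censoring interval shrinks onto the true onset time the
        # (iv)-type contribution divided by the interval width converges to
        # the exact-data density P00(0,T1) l01(T1) P11(T1,T*) l12(T*)
        T1, T = 10.0, 42.0
        exact = np.log(
            _p00(P, 0, T1)
            * weibull_hazard(P, "01", T1)
            * _p11(P, T1, T)
            * weibull_hazard(P, "12", T)
        )
        errors = []
        for tau in (1.0, 1e-2, 1e-4):
            ll = m.weibull_ic_loglik(P, [_iv(T1 - tau / 2, T1 + tau / 2, T, 1)])
            errors.append(abs(ll - np.log(tau) - exact))
        assert errors[0] > errors[1] > errors[2]
        assert errors[2] < 1e-6

    def test_invalid_interval_rejected(self):
        with pytest.raises(ValueError):
            m.weibull_ic_loglik(P, [m.IntervalSummary("x", 5.0, 4.0, 10.0, 1)])


class TestTotalProbability:
    def test_observation_categories_sum_to_one(self):
        """Summing the likelihood over every possible observed outcome of one
        subject (visit grid {0,30,..,120}, administrative censoring at 120)
        integrates to 1: the contributions form a proper probability model."""
        tau, y = 30.0, 120.0
        grid = np.arange(0.0, y + 1, tau)

        def lik(iv):
            return np.exp(m.weibull_ic_loglik(P, [iv], n_nodes=30))

        total = 0.0
        # censored alive at y, never positive (=> healthy at y)
        total += lik(_iv(y, None, y, 0))
        # censored alive at y, first positive screen at R
        for R in grid[1:]:
            total += lik(_iv(R - tau, R, y, 0))
        # death in (v*, v*+tau): integrate the death-time density
        for vstar in grid[:-1]:
            hi = min(vstar + tau, y)
            # never positive by the last screen v*
            total += quad(lambda T: lik(_iv(vstar, None, T, 1)), vstar, hi,
                          epsabs=1e-10, limit=200)[0]
            # diagnosed at some R <= v*
            for R in grid[1:]:
                if R > vstar:
                    break
                total += quad(lambda T: lik(_iv(R - tau, R, T, 1)), vstar, hi,
                              epsabs=1e-10, limit=200)[0]
        assert total == pytest.approx(1.0, abs=1e-6)


@pytest.fixture(scope="module")
def fit_a(scenario_a_data):
    return m.fit_weibull_ic(m.summarize_intervals(scenario_a_data), compute_cov=True)


class TestFit:
    def test_parameter_recovery_on_scenario_a(self, fit_a):
        assert fit_a.converged
        se = fit_a.se_log()
        est = np.log([fit_a.params.a01, fit_a.params.a02, fit_a.params.a12,
                      fit_a.params.k01, fit_a.params.k02, fit_a.params.k12])
        truth = np.log([0.05, 0.05, 0.56, 0.5, 0.5, 0.5])
        assert np.all(np.abs(est - truth) < 3 * se)

    def test_matches_per_transition_fit_on_exact_data(self):
        # narrow censoring intervals around the true onset: the MLE agrees
        # with independent per-transition Weibull fits on the exact data
        rng = np.random.default_rng(8)
        from idmauc.simulate import sample_latent_paths

        t1, exit_state, td = sample_latent_paths(P, 600, rng)
        y = 120.0
        eps = 1e-3
        ivs = []
        for i in range(600):
            tstar = min(td[i], y)
            delta = int(td[i] <= y)
            if exit_state[i] == 1 and t1[i] < tstar:
                ivs.append(_iv(max(t1[i] - eps, 0.0), t1[i], tstar, delta, f"s{i}"))
            else:
                ivs.append(_iv(tstar, None, tstar, delta, f"s{i}"))
        fit = m.fit_weibull_ic(ivs)

        # oracle: exact-data Weibull MLE for the 0->1 cause-specific hazard
        # (common exit from state 0 -> fit the minimum-time distribution)
        from scipy.optimize import minimize

        ill = np.array([iv.R is not None for iv in ivs])
        texit = np.array([iv.R if iv.R is not None else iv.tstar for iv in ivs])
        exit_observed = ill | np.array([iv.delta == 1 and iv.R is None for iv in ivs])

        def neg01(theta):
            a, k = np.exp(theta)
            # cause-specific 0->1 likelihood: density for ill, survivor
            # factor exp(-a t^k) for everyone's time in state 0
            ll = np.sum(np.where(ill, np.log(a * k) + (k - 1) * np.log(texit), 0.0))
            ll -= np.sum(a * texit**k)
            return -ll

        res = minimize(neg01, [np.log(0.03), np.log(0.7)], method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-10})
        a01_oracle, k01_oracle = np.exp(res.x)
        assert fit.params.a01 == pytest.approx(a01_oracle, rel=0.02)
        assert fit.params.k01 == pytest.approx(k01_oracle, rel=0.02)

    def test_no_diagnoses_pushes_onset_rate_to_boundary(self):
        rng = np.random.default_rng(9)
        tstars = rng.uniform(5, 100, 150)
        ivs = [_iv(t, None, t, 1, f"s{i}") for i, t in enumerate(tstars)]
        fit = m.fit_weibull_ic(ivs)
        assert fit.params.a01 < 1e-6

    def test_time_dependent_hazard_ratio(self):
        assert m.weibull_time_dependent_hr(
            m.WeibullFit(params=P, loglik=0.0, converged=True), 7.0
        ) == pytest.approx(11.2)
        # equal fitted shapes -> constant ratio
        p = m.WeibullIDMParams(k01=0.4, k02=0.6, k12=0.6, a01=0.1, a02=0.02, a12=0.3)
        f = m.WeibullFit(params=p, loglik=0.0, converged=True)
        assert m.weibull_time_dependent_hr(f, 5.0) == m.weibull_time_dependent_hr(f, 50.0)
        # heavier late shape for 1->2 -> increasing ratio
        p2 = m.WeibullIDMParams(k01=0.5, k02=0.5, k12=0.9, a01=0.1, a02=0.02, a12=0.3)
        f2 = m.WeibullFit(params=p2, loglik=0.0, converged=True)
        assert m.weibull_time_dependent_hr(f2, 50.0) > m.weibull_time_dependent_hr(f2, 5.0)
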