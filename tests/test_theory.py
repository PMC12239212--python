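import math

import numpy as np
import pytest
from scipy import integrate, optimize

from evorescue import theory
from evorescue.params import derived_rates, preset


class TestExtinctionProbabilities:
    def test_subcritical_single_type_dies_surely(self, melanoma):
        ep = theory.extinction_probabilities(melanoma.with_(u=0.0, v=0.0))
        assert ep.q_s == 1.0
        assert ep.p_s == 0.0

    def test_mutant_extinction_probability(self, melanoma):
        assert theory.extinction_probabilities(melanoma).q_m == pytest.approx(0.9)

    def test_closed_form_matches_fixed_point_iteration(self, melanoma):
        ep = theory.extinction_probabilities(melanoma)
        fp = theory.extinction_probabilities_fixed_point(melanoma)
        for name in ("q_s", "q_a", "q_m"):
            assert abs(getattr(ep, name) - getattr(fp, name)) < 1e-10

    def test_random_sweep_closed_vs_iteration(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            lam = rng.uniform(1e-3, 1.0, size=3)
            mu = rng.uniform(1e-3, 1.0, size=3)
            u, v = rng.uniform(0, 0.1, size=2)
            p = preset("melanoma_a375").with_(
                lambda_s=lam[0], mu_s=max(mu[0], lam[0] + 1e-3),
                lambda_a=lam[1], mu_a=mu[1],
                lambda_m=lam[2], mu_m=mu[2],
                u=u, v=v,
            )
            ep = theory.extinction_probabilities(p)
            fp = theory.extinction_probabilities_fixed_point(p)
            assert abs(ep.q_s - fp.q_s) < 1e-10
            assert abs(ep.q_a - fp.q_a) < 1e-10

    def test_p_s_nondecreasing_in_u_and_v(self, melanoma):
        base = theory.extinction_probabilities(melanoma).p_s
        assert theory.extinction_probabilities(melanoma.with_(u=2e-2)).p_s >= base
        assert theory.extinction_probabilities(melanoma.with_(v=2e-7)).p_s >= base


class TestThresholds:
    def test_direct_threshold_melanoma(self, melanoma):
        assert theory.threshold_direct(melanoma) == pytest.approx(4e7, rel=1e-9)

    def test_direct_threshold_scales_inversely_with_v(self, melanoma):
        assert theory.threshold_direct(melanoma.with_(v=2e-7)) == pytest.approx(
            2e7, rel=1e-9
        )

    def test_direct_threshold_agrees_with_exact(self, melanoma):
        p_s = theory.extinction_probabilities(melanoma.with_(u=0.0)).p_s
        nm = theory.threshold_direct(melanoma)
        assert abs(math.log10(nm) - math.log10(1.0 / p_s)) < 0.1

    def test_aneuploid_threshold_tolerant(self, melanoma):
        na, branch = theory.threshold_aneuploid(melanoma)
        assert branch == "tolerant"
        assert na == pytest.approx(4.449e6, rel=1e-3)

    def test_aneuploid_threshold_stationary_exact_zero_growth(self, melanoma):
        na, branch = theory.threshold_aneuploid(melanoma.with_(lambda_a=0.09))
        assert branch == "stationary"
        # prefactor |r_s|/(u lambda_s) = 40; factor sqrt(lambda_m/(v_a r_m)) = 1e4
        assert na == pytest.approx(4e5, rel=1e-9)

    def test_aneuploid_threshold_resistant(self, melanoma):
        na, branch = theory.threshold_aneuploid(melanoma.with_(lambda_a=0.095))
        assert branch == "resistant"
        assert na == pytest.approx(760.0, rel=1e-9)

    def test_ratios_melanoma(self, melanoma):
        r_ad, r_sa, r_sd = theory.threshold_ratios(melanoma)
        assert r_ad == pytest.approx(0.11123, rel=1e-4)
        assert r_sa == pytest.approx(17.5, rel=1e-9)
        assert r_sd == pytest.approx(1.9466, rel=1e-4)
        assert r_sd == pytest.approx(r_sa * r_ad, rel=1e-14)

    def test_standing_ratio_is_one_when_rates_match(self, melanoma):
        p = melanoma.with_(u_pre=melanoma.u, c=abs(melanoma.r_s))
        assert theory.threshold_ratios(p)[1] == pytest.approx(1.0)


class TestRescueProbability:
    def test_empty_tumor_never_rescued(self, melanoma):
        assert theory.rescue_probability(melanoma, 0) == 0.0

    def test_threshold_size_gives_one_minus_inv_e(self, scaled):
        p_s = theory.extinction_probabilities(scaled).p_s
        assert p_s < 1e-3
        val = theory.rescue_probability(scaled, 1.0 / p_s, "exact")
        assert val == pytest.approx(1.0 - math.exp(-1.0), rel=0.01)

    def test_approx_melanoma_tolerant(self, melanoma):
        approx = theory.rescue_probability(melanoma, 1e7, "approx")
        assert approx == pytest.approx(0.918, abs=1e-3)
        exact = theory.rescue_probability(melanoma, 1e7, "exact")
        assert approx == pytest.approx(exact, abs=0.02)

    def test_monotone_in_n(self, melanoma):
        ns = [0, 1e5, 1e6, 1e7, 1e8]
        vals = [theory.rescue_probability(melanoma, n) for n in ns]
        assert all(b >= a for a, b in zip(vals, vals[1:]))


class TestDeterministicTrajectory:
    def test_initial_state(self, melanoma):
        s, a, m = theory.deterministic_trajectory(melanoma, 1e7, [0.0])
        assert (s[0], a[0], m[0]) == (1e7, 0.0, 0.0)

    def test_no_missegregation_means_no_aneuploids(self, melanoma):
        _s, a, _m = theory.deterministic_trajectory(
            melanoma.with_(u=0.0), 1e7, np.linspace(0, 200, 9)
        )
        assert np.all(a == 0)

    def test_aneuploid_peak_location(self, melanoma):
        d = derived_rates(melanoma)
        # dA/dt = 0 at r_s e^{r_s t} = r_a e^{r_a t}
        t_peak = math.log(d.r_a / d.r_s) / (d.r_s - d.r_a)
        res = optimize.minimize_scalar(
            lambda t: -theory.deterministic_trajectory(melanoma, 1e7, [t])[1][0],
            bounds=(1.0, 2e4), method="bounded",
        )
        assert res.x == pytest.approx(t_peak, rel=1e-3)

    def test_mutant_mean_matches_quadrature(self, melanoma):
        d = derived_rates(melanoma)
        n = 1e7
        for t_end in (50.0, 400.0):
            _s, _a, m = theory.deterministic_trajectory(melanoma, n, [t_end])

            def integrand(tau):
                s_t, a_t, _ = theory.deterministic_trajectory(melanoma, n, [tau])
                g = melanoma.v * melanoma.lambda_s * s_t[0] \
                    + melanoma.v_a * melanoma.lambda_a * a_t[0]
                return g * math.exp(d.r_m * (t_end - tau))

            ref, _err = integrate.quad(integrand, 0, t_end, limit=200)
            assert m[0] == pytest.approx(ref, rel=1e-8)


class TestRescueHazard:
    def test_single_path_limit(self, melanoma):
        p = melanoma.with_(u=0.0)
        _lam, lam_inf = theory.rescue_hazard(p, 1e7)
        assert lam_inf == pytest.approx(1e7 / theory.threshold_direct(p), rel=1e-12)

    def test_tolerant_identity(self, melanoma):
        lam, lam_inf = theory.rescue_hazard(melanoma, 1e7)
        na, _ = theory.threshold_aneuploid(melanoma)
        nm = theory.threshold_direct(melanoma)
        assert lam_inf == pytest.approx(1e7 / na + 1e7 / nm, rel=1e-12)
        assert lam_inf == pytest.approx(2.497, rel=1e-3)
        t = np.linspace(0, 1e5, 50)
        vals = lam(t)
        assert vals[0] == 0.0
        assert np.all(np.diff(vals) >= 0)

    def test_refuses_growing_aneuploids(self, melanoma):
        with pytest.raises(ValueError, match="unsupported"):
            theory.rescue_hazard(melanoma.with_(lambda_a=0.095), 1e7)


class TestTimeSummaries:
    def test_small_tumor_rescue_time(self, melanoma):
        est = theory.mean_rescue_time(melanoma, 1e5)
        assert est.method == "asymptotic_small_N"
        assert est.value == pytest.approx(10_025.0, rel=1e-6)

    def test_small_tumor_direct_only(self, melanoma):
        est = theory.mean_rescue_time(melanoma.with_(u=0.0), 1e5)
        assert est.value == pytest.approx(25.0, rel=1e-9)

    def test_large_tumor_rescue_time(self, melanoma):
        est = theory.mean_rescue_time(melanoma, 1e10)
        assert est.method == "asymptotic_large_N"
        assert est.value == pytest.approx(0.1, rel=1e-9)

    def test_survival_curve_limits(self, melanoma):
        _lam, lam_inf = theory.rescue_hazard(melanoma, 1e7)
        surv = theory.rescue_time_survival(melanoma, 1e7, [0.0, 1e7])
        assert surv[0] == 1.0
        assert surv[1] == pytest.approx(math.exp(-lam_inf), rel=1e-9)
        assert surv[1] == pytest.approx(
            1.0 - theory.rescue_probability(melanoma, 1e7, "approx"), rel=1e-9
        )

    def test_small_tumor_recurrence_time(self, melanoma):
        est = theory.mean_recurrence_time(melanoma, 1e5, target=1e5)
        assert est.method == "asymptotic_small_N"
        # -1/r_s - 1/r_a + ln(p_m N)/r_m
        assert est.value == pytest.approx(10_946.0, rel=1e-4)

    def test_large_tumor_recurrence_constant(self, melanoma):
        est = theory.mean_recurrence_time(melanoma, 1e10)
        assert est.method == "asymptotic_large_N"
        assert est.value == pytest.approx(1542.5, rel=1e-3)
        # independent of N in the deterministic regime
        assert theory.mean_recurrence_time(melanoma, 1e12).value == est.value

    def test_recurrence_decreasing_in_mutant_growth_rate(self, melanoma):
        faster = melanoma.with_(lambda_m=0.12)  # r_m: 0.01 -> 0.03
        for n in (1e5, 1e10):
            assert (
                theory.mean_recurrence_time(faster, n, target=n).value
                < theory.mean_recurrence_time(melanoma, n, target=n).value
            )
        slow = theory.mean_recurrence_time(melanoma, 1e6, target=1e6, seed=3)
        fast = theory.mean_recurrence_time(faster, 1e6, target=1e6, seed=3)
        assert fast.method == "monte_carlo" and fast.value < slow.value

    def test_detection_equals_recurrence_when_targets_match(self, melanoma):
        n = 1e5
        det = theory.mean_detection_time(melanoma, n, n, seed=5)
        rec = theory.mean_recurrence_time(melanoma, n, target=n, seed=5)
        assert det.value == rec.value

    def test_large_tumor_detection_precedes_recurrence(self, melanoma):
        det = theory.mean_detection_time(melanoma, 1e10, 1e7)
        rec = theory.mean_recurrence_time(melanoma, 1e10)
        assert det.method == "ode"
        assert det.value < rec.value

    def test_recurrence_survival_shape(self, melanoma):
        t = np.linspace(0, 4e4, 30)
        surv, lo, hi = theory.recurrence_survival(melanoma, 1e6, 1e6, t, draws=500, seed=2)
        assert surv[0] == 1.0
        assert np.all(np.diff(surv) <= 1e-12)
        assert np.all(lo <= surv + 1e-12) and np.all(surv <= hi + 1e-12)

    def test_stationary_regime_refused(self, melanoma):
        with pytest.raises(ValueError, match="stationary"):
            theory.mean_rescue_time(melanoma.with_(lambda_a=0.09), 1e6)
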