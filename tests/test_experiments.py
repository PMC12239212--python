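import math

import numpy as np
import pandas as pd
import pytest

from evorescue import theory
from evorescue.experiments import (
    SweepSpec,
    bootstrap_ci,
    recurrence_experiment,
    rescue_curve_experiment,
    standing_variation_experiment,
    threshold_vs_ra_experiment,
    threshold_vs_rate_ratio_experiment,
    window_of_opportunity_experiment,
)


class TestBootstrapCI:
    def test_constant_input_degenerate_interval(self):
        lo, hi = bootstrap_ci([0.3] * 50, "proportion", b=500, seed=0)
        assert lo == hi
        assert lo == pytest.approx(0.3)

    def test_interval_brackets_the_point_estimate(self):
        rng = np.random.default_rng(3)
        data = rng.normal(5.0, 2.0, size=200)
        lo, hi = bootstrap_ci(data, "mean", b=1000, seed=1)
        assert lo <= data.mean() <= hi

    def test_resample_count_stability(self):
        rng = np.random.default_rng(5)
        data = (rng.random(200) < 0.4).astype(float)
        lo1, hi1 = bootstrap_ci(data, "proportion", b=1000, seed=2)
        lo2, hi2 = bootstrap_ci(data, "proportion", b=10_000, seed=3)
        assert abs(lo1 - lo2) < 0.01 and abs(hi1 - hi2) < 0.01

    def test_median_statistic(self):
        data = np.arange(100, dtype=float)
        lo, hi = bootstrap_ci(data, "median", b=500, seed=4)
        assert lo <= np.median(data) <= hi

    def test_input_validation(self):
        with pytest.raises(ValueError):
            bootstrap_ci([1.0], "mean")
        with pytest.raises(ValueError):
            bootstrap_ci([1.0, 2.0], "mean", b=10)
        with pytest.raises(ValueError):
            bootstrap_ci([1.0, 2.0], "mode")


class TestRescueCurve:
    def test_tables_and_ordering(self, scaled):
        spec = SweepSpec("n_init", (200, 1000, 5000), scaled,
                         replicates=60, base_seed=9)
        out = rescue_curve_experiment(spec)
        t = out.table
        assert list(t["n_init"]) == [200, 1000, 5000]
        assert np.all(t["ci_low"] <= t["sim_fraction"])
        assert np.all(t["sim_fraction"] <= t["ci_high"])
        assert t["theory_exact"].is_monotonic_increasing
        # simulation brackets theory at each point
        assert np.all(np.abs(t["sim_fraction"] - t["theory_exact"]) <= 0.25)
        assert "n_star_direct" in out.manifest

    def test_aneuploidy_never_hurts_rescue(self, scaled):
        ns = np.geomspace(10, 1e5, 12)
        without = [theory.rescue_probability(scaled.with_(u=0.0), n) for n in ns]
        with_u = [theory.rescue_probability(scaled, n) for n in ns]
        assert all(w <= u + 1e-15 for w, u in zip(without, with_u))

    def test_condition_ordering_matches_aneuploid_fitness(self, scaled):
        # resistant >= stationary >= tolerant >= none, at every N
        conditions = [
            scaled.with_(lambda_a=0.095),
            scaled.with_(lambda_a=0.09),
            scaled,
            scaled.with_(u=0.0),
        ]
        for n in (100, 1000, 10_000):
            vals = [theory.rescue_probability(p, n) for p in conditions]
            assert all(a >= b - 1e-15 for a, b in zip(vals, vals[1:]))

    def test_reproducibility(self, scaled):
        spec = SweepSpec("n_init", (500,), scaled, replicates=40, base_seed=17)
        a = rescue_curve_experiment(spec).table
        b = rescue_curve_experiment(spec).table
        pd.testing.assert_frame_equal(a, b)


class TestThresholdSweeps:
    def test_tolerant_branch_tracks_exact_threshold(self, melanoma):
        # lambda_a values keeping u*lambda_a > |r_a| so the aneuploid
        # route stays relevant (tolerant regime, not direct-mutation)
        spec = SweepSpec("lambda_a", (0.0893, 0.0896, 0.0899), melanoma, base_seed=1)
        out = threshold_vs_ra_experiment(spec, simulate=False)
        t = out.table
        assert (t["branch"] == "tolerant").all()
        # both mutational routes contribute to the exact 1/p_s; compare it
        # with the harmonic combination of the branch thresholds
        nm = out.manifest["n_star_direct"]
        combined = 1.0 / (1.0 / t["n_star_branch"] + 1.0 / nm)
        ratio = combined / t["n_star_exact"]
        assert np.all(ratio < 1.5) and np.all(ratio > 1 / 1.5)

    def test_threshold_flat_inside_stationary_window(self, melanoma):
        spec = SweepSpec("lambda_a", (0.0899997, 0.09, 0.0900003), melanoma, base_seed=1)
        t = threshold_vs_ra_experiment(spec, simulate=False).table
        assert (t["branch"] == "stationary").all()
        assert t["n_star_branch"].nunique() == 1

    def test_resistant_branch_decreasing_in_ra(self, melanoma):
        spec = SweepSpec("lambda_a", (0.092, 0.095, 0.1), melanoma, base_seed=1)
        t = threshold_vs_ra_experiment(spec, simulate=False).table
        assert (t["branch"] == "resistant").all()
        assert t["n_star_branch"].is_monotonic_decreasing

    def test_simulated_threshold_close_to_exact(self, scaled):
        spec = SweepSpec("lambda_a", (0.0899,), scaled, replicates=80, base_seed=3)
        t = threshold_vs_ra_experiment(spec, simulate=True).table
        ratio = t["n_star_sim"][0] / t["n_star_exact"][0]
        assert 0.5 < ratio < 2.0

    def test_rate_ratio_sweep_scales_inversely_with_u(self, melanoma):
        spec = SweepSpec("u", (1e-3, 1e-2, 1e-1), melanoma, base_seed=1)
        t = threshold_vs_rate_ratio_experiment(spec).table
        tol = t[t["branch"] == "tolerant"]
        np.testing.assert_allclose(
            tol["n_star_branch"] * tol["u"],
            (tol["n_star_branch"] * tol["u"]).iloc[0],
            rtol=1e-12,
        )


class TestStandingVariation:
    def test_melanoma_ratio(self, melanoma):
        spec = SweepSpec("mu_s", (0.14,), melanoma, base_seed=1)
        t = standing_variation_experiment(spec).table
        assert t["ratio_standing_aneuploid"][0] == pytest.approx(17.5)

    def test_ratio_one_when_rates_match(self, melanoma):
        p = melanoma.with_(u_pre=melanoma.u, c=abs(melanoma.r_s))
        spec = SweepSpec("mu_s", (0.14,), p, base_seed=1)
        t = standing_variation_experiment(spec).table
        assert t["ratio_standing_aneuploid"][0] == pytest.approx(1.0)

    def test_standing_to_direct_ratio_independent_of_u(self, melanoma):
        vals = []
        for u in (5e-3, 1e-2, 5e-2):
            spec = SweepSpec("mu_s", (0.14,), melanoma.with_(u=u), base_seed=1)
            vals.append(
                standing_variation_experiment(spec).table["ratio_standing_direct"][0]
            )
        np.testing.assert_allclose(vals, vals[0], rtol=1e-12)


class TestWindowOfOpportunity:
    def test_survival_curves(self, scaled):
        conditions = {"none": scaled.with_(u=0.0), "tolerant": scaled}
        out = window_of_opportunity_experiment(
            conditions, 1000, [0.0, 50.0, 150.0, 400.0], replicates=60, base_seed=5
        )
        t = out.table
        for name, grp in t.groupby("condition"):
            assert grp.iloc[0]["sim_survival"] == 1.0
            assert grp["sim_survival"].is_monotonic_decreasing or (
                grp["sim_survival"].diff().dropna() <= 0.05
            ).all()
        # the u=0 analytic curve plateaus at exp(-N/Nm*)
        none = t[t["condition"] == "none"]
        plateau = math.exp(-1000 / theory.threshold_direct(scaled.with_(u=0.0)))
        assert none["analytic_survival"].iloc[-1] == pytest.approx(plateau, rel=0.01)
        # tolerant aneuploids keep producing successful mutants at late
        # times, after the direct route is exhausted
        tol = t[t["condition"] == "tolerant"]
        assert tol["analytic_survival"].iloc[-1] < plateau


class TestRecurrenceExperiment:
    def test_decreasing_in_n_with_constant_tail(self, melanoma):
        spec = SweepSpec("n_init", (1e6, 1e7, 1e10, 1e11), melanoma,
                         base_seed=2)
        out = recurrence_experiment(spec, draws=800)
        t = out.table
        means = np.where(t["n_init"] >= 10 * 4e7, t["large_n_constant"], t["mc_mean"])
        assert all(b <= a for a, b in zip(means, means[1:]))
        assert t["large_n_constant"].iloc[0] == pytest.approx(1542.5, rel=1e-3)
        small = t.iloc[0]
        assert small["ci_low"] <= small["mc_mean"] <= small["ci_high"]
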