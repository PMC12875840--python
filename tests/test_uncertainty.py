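"""Distribution fitting, parameter sampling, PSA mechanics, CEAC construction,
one-way sensitivity and threshold analysis."""

import math

import numpy as np
import pandas as pd
import pytest

from oralcea import (DistributionSpec, ceac, fit_dirichlet_row,
                     fit_distribution, one_way_dsa, run_group, run_psa,
                     sample_parameter_set, table1_defaults, threshold_sweep)

WTP = 211_725.0


class TestFitting:
    def test_beta_method_of_moments(self):
        s = fit_distribution(DistributionSpec("beta", 0.23, 0.2, 0.3))
        assert s.fitted["sd"] == pytest.approx((0.3 - 0.2) / 3.92)
        assert s.fitted["alpha"] == pytest.approx(62.4, abs=0.5)
        mean = 0.23
        nu = s.fitted["alpha"] + s.fitted["beta"]
        assert s.fitted["alpha"] / nu == pytest.approx(mean)

    def test_normal_sd_from_interval(self):
        s = fit_distribution(DistributionSpec("normal", 155, 124, 186))
        assert s.fitted["sd"] == pytest.approx(15.82, abs=0.01)

    def test_gamma_moments_match(self):
        s = fit_distribution(DistributionSpec("gamma", 36_870, 33_300, 39_900))
        assert s.fitted["shape"] * s.fitted["scale"] == pytest.approx(36_870)
        var = s.fitted["shape"] * s.fitted["scale"] ** 2
        assert math.sqrt(var) == pytest.approx((39_900 - 33_300) / 3.92)

    def test_fixed_is_degenerate(self):
        s = fit_distribution(DistributionSpec("fixed", 0.008))
        rng = np.random.default_rng(0)
        assert {s.draw(rng) for _ in range(10)} == {0.008}

    def test_beta_rejects_mean_outside_unit_interval(self):
        with pytest.raises(ValueError):
            fit_distribution(DistributionSpec("beta", 1.5, 1.4, 1.6))

    def test_dirichlet_row_concentration(self):
        means = [0.076, 0.083, 0.613]
        sds = [(0.08 - 0.072) / 3.92, (0.087 - 0.079) / 3.92, (0.643 - 0.582) / 3.92]
        alpha = fit_dirichlet_row(means, sds)
        assert len(alpha) == 4  # three exits plus the stay remainder
        total = alpha.sum()
        assert alpha[:3] / total == pytest.approx(means, rel=1e-9)
        # the average marginal sd matches the average interval-implied sd
        marg_sd = [math.sqrt(m * (1 - m) / (total + 1)) for m in means]
        assert np.mean(marg_sd) == pytest.approx(np.mean(sds), rel=0.15)


class TestSampling:
    def test_same_seed_same_draw(self, table1):
        a = sample_parameter_set(table1, 42)
        b = sample_parameter_set(table1, 42)
        assert a.to_dict() == b.to_dict()
        c = sample_parameter_set(table1, 43)
        assert c.to_dict() != a.to_dict()

    def test_fixed_parameters_never_vary(self, table1):
        for seed in range(10):
            s = sample_parameter_set(table1, seed)
            assert s.config.median_age == table1.config.median_age
            assert s.transitions.all_cause_mortality == \
                table1.transitions.all_cause_mortality
            assert s.transitions.dm_median_survival_months == 7.5

    def test_occult_rate_sample_mean_matches_clt(self, table1):
        rng = np.random.default_rng(123)
        sampler = fit_distribution(table1.distributions["config.occult_metastasis_rate"])
        n = 10_000
        draws = np.array([sampler.draw(rng) for _ in range(n)])
        sd = sampler.fitted["sd"]
        assert abs(draws.mean() - 0.23) < 3 * sd / math.sqrt(n)
        # and the joint draw routes the same marginal into the parameter set
        joint = [sample_parameter_set(table1, s).config.occult_metastasis_rate
                 for s in range(200)]
        assert abs(np.mean(joint) - 0.23) < 4 * sd / math.sqrt(200)

    def test_sampled_sets_stay_valid(self, table1):
        from oralcea import validate
        for seed in range(5):
            assert validate(sample_parameter_set(table1, seed)) == []

    def test_transition_rows_drawn_jointly(self, table1):
        s = sample_parameter_set(table1, 7)
        t = s.transitions
        row = t.lrr_to_dm + t.lrr_to_salvage_dissected + t.lrr_to_death_cancer
        assert row < 1.0  # Dirichlet guarantees room for the stay probability


class TestCEAC:
    def test_all_dominant_points_give_probability_one(self):
        pts = pd.DataFrame({"comparison": "A vs B", "delta_cost": [-1.0, -2.0],
                            "delta_qaly": [0.1, 0.2]})
        out = ceac(pts, [0, 1e5, 1e6])
        assert (out["probability_cost_effective"] == 1.0).all()

    def test_zero_wtp_reduces_to_cost_saving_fraction(self):
        pts = pd.DataFrame({"comparison": "A vs B",
                            "delta_cost": [-1.0, 2.0, 3.0, -4.0],
                            "delta_qaly": [0.1, 0.1, 0.1, 0.1]})
        out = ceac(pts, [0.0])
        assert out["probability_cost_effective"].iloc[0] == 0.5

    def test_single_point_steps_at_its_icur(self):
        pts = pd.DataFrame({"comparison": "A vs B", "delta_cost": [100.0],
                            "delta_qaly": [0.5]})
        icur = 200.0
        out = ceac(pts, [icur * 0.9, icur * 1.1])
        assert list(out["probability_cost_effective"]) == [0.0, 1.0]

    def test_monotone_for_positive_qaly_clouds(self):
        rng = np.random.default_rng(5)
        pts = pd.DataFrame({"comparison": "A vs B",
                            "delta_cost": rng.normal(5e3, 2e3, 400),
                            "delta_qaly": rng.uniform(0.01, 0.5, 400)})
        out = ceac(pts, np.linspace(0, 5e5, 40))
        assert (np.diff(out["probability_cost_effective"]) >= 0).all()

    def test_empty_inputs_rejected(self):
        pts = pd.DataFrame({"comparison": [], "delta_cost": [], "delta_qaly": []})
        with pytest.raises(ValueError):
            ceac(pts, [1.0])
        with pytest.raises(ValueError):
            ceac(pd.DataFrame({"comparison": ["x"], "delta_cost": [1.0],
                               "delta_qaly": [0.1]}), [])


class TestPSA:
    def test_degenerate_distributions_collapse_to_base_case(self, params):
        params.distributions = {k: DistributionSpec("fixed", v.mean)
                                for k, v in params.distributions.items()}
        pts = run_psa(params, [("II", "I")], 1, seed=0)
        base = {g: run_group(g, params) for g in ("I", "II")}
        assert pts["delta_cost"].iloc[0] == pytest.approx(
            base["I"].total_cost - base["II"].total_cost)
        assert pts["delta_qaly"].iloc[0] == pytest.approx(
            base["I"].total_qaly - base["II"].total_qaly)

    def test_reproducible_under_seed(self, table1):
        a = run_psa(table1, [("II", "I")], 5, seed=11)
        b = run_psa(table1, [("II", "I")], 5, seed=11)
        pd.testing.assert_frame_equal(a, b)

    def test_iteration_count_validated(self, table1):
        with pytest.raises(ValueError):
            run_psa(table1, [("II", "I")], 0, seed=1)


class TestDSA:
    def test_base_bounds_reproduce_base_icur_exactly(self, params):
        base_i = run_group("I", params)
        base_iii = run_group("III", params)
        base_icur = ((base_i.total_cost - base_iii.total_cost)
                     / (base_i.total_qaly - base_iii.total_qaly))
        keep = ["utilities.lrr", "costs.mnd", "transitions.lrr_to_dm"]
        params.distributions = {
            k: DistributionSpec(params.distributions[k].family,
                                params.distributions[k].mean,
                                params.distributions[k].mean,
                                params.distributions[k].mean)
            for k in keep}
        for e in one_way_dsa(params, ("III", "I")):
            assert e.low_icur == pytest.approx(base_icur, rel=1e-12)
            assert e.high_icur == pytest.approx(base_icur, rel=1e-12)
            assert e.spread == pytest.approx(0.0, abs=1e-9)

    def test_sorted_by_spread_descending(self, table1):
        entries = one_way_dsa(table1, ("III", "I"), horizon_years=10)
        spreads = [e.spread for e in entries]
        assert spreads == sorted(spreads, reverse=True)

    def test_reported_drivers_lead_the_tornado(self, table1):
        """The strongest levers of the sentinel-node comparison include the
        post-resection utility, the occult metastasis rate and the biopsy NPV."""
        top = {e.parameter for e in one_way_dsa(table1, ("III", "I"))[:8]}
        assert "utilities.dfs_primary_resection" in top
        assert "config.occult_metastasis_rate" in top
        assert "accuracy_slnb.npv" in top

    def test_unused_cost_leaves_other_strategy_untouched(self, params):
        """The selective-dissection package is not part of the sentinel-node
        pathway, so varying it cannot move that strategy's absolute cost."""
        before = run_group("I", params).total_cost
        params.costs.snd *= 1.5
        assert run_group("I", params).total_cost == before
        assert run_group("II", params).total_cost > before - before  # sanity


class TestThreshold:
    def test_infinite_wtp_gives_grid_max(self, table1):
        grid = [0.1, 0.2, 0.3]
        res = threshold_sweep(table1, "occult_metastasis_rate", grid,
                              ("III", "I"), wtp=math.inf, horizon_years=10)
        assert res.breakpoint == 0.3

    def test_unreachable_wtp_reports_none(self, table1):
        res = threshold_sweep(table1, "occult_metastasis_rate", [0.1, 0.2],
                              ("III", "I"), wtp=1.0, horizon_years=10)
        assert res.breakpoint is None
        assert "none on grid" in str(res)

    def test_grid_resolution_reported(self, table1):
        res = threshold_sweep(table1, "occult_metastasis_rate", [0.1, 0.15, 0.2],
                              ("III", "I"), wtp=math.inf, horizon_years=5)
        assert res.grid_step == pytest.approx(0.05)
        assert set(res.curve.columns) >= {"value", "icur", "cost_effective"}

    def test_generic_parameter_sweep(self, table1):
        res = threshold_sweep(table1, "costs.slnb", [20_000, 30_000],
                              ("III", "I"), wtp=math.inf, horizon_years=5)
        assert res.breakpoint == 30_000
        assert res.curve["delta_cost"].is_monotonic_increasing
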