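import numpy as np
import pytest

from tcscea.cohort_engine import run_arm
from tcscea.economics import incremental_result
from tcscea.parameters import ALIVE_STATES, MedicalState, ParameterError
from tcscea.sensitivity import (
    CEACurve,
    DsaSpec,
    PSAResult,
    PsaDistribution,
    ceac,
    default_dsa_specs,
    fit_beta_from_range,
    fit_beta_from_sd,
    fit_gamma,
    fit_lognormal_from_ci,
    one_way_dsa,
    plot_ce_plane,
    plot_ceac,
    plot_tornado,
    psa_distributions,
    resolve_parameter,
    run_psa,
    set_parameter,
    tornado_frame,
)
from tcscea.transition_model import Arm

S = MedicalState


class TestFitLognormal:
    def test_copd_rr_median(self):
        dist = fit_lognormal_from_ci(0.421, 0.852)
        assert round(dist.median, 3) == 0.599

    def test_all_readmission_rr_median(self):
        dist = fit_lognormal_from_ci(0.531, 0.978)
        assert dist.median == pytest.approx(0.7207, abs=5e-4)
        assert round(dist.median, 3) == 0.721

    def test_degenerate(self):
        dist = fit_lognormal_from_ci(0.5, 0.5)
        assert dist.family == "point"
        rng = np.random.default_rng(0)
        assert dist.sample(rng) == 0.5

    def test_errors(self):
        with pytest.raises(ParameterError):
            fit_lognormal_from_ci(0, 1)
        with pytest.raises(ParameterError):
            fit_lognormal_from_ci(0.9, 0.5)

    def test_ci_recovered_from_draws(self):
        dist = fit_lognormal_from_ci(0.421, 0.852)
        draws = dist.sample(np.random.default_rng(42), size=200_000)
        assert np.quantile(draws, 0.025) == pytest.approx(0.421, rel=0.02)
        assert np.quantile(draws, 0.975) == pytest.approx(0.852, rel=0.02)


class TestFitBeta:
    def test_stable_utility_mean(self):
        dist = fit_beta_from_range(0.795, 0.716, 0.875)
        draws = dist.sample(np.random.default_rng(1), size=10_000)
        assert float(np.mean(draws)) == pytest.approx(0.795, abs=0.005)

    def test_degenerate(self):
        dist = fit_beta_from_range(0.5, 0.5, 0.5)
        assert dist.family == "point"

    def test_domain(self):
        dist = fit_beta_from_range(0.61, 0.549, 0.671)
        draws = dist.sample(np.random.default_rng(2), size=10_000)
        assert np.all((draws > 0) & (draws < 1))

    def test_infeasible_variance(self):
        with pytest.raises(ParameterError, match="infeasible"):
            fit_beta_from_sd(0.5, 0.51)

    def test_mean_out_of_range(self):
        with pytest.raises(ParameterError):
            fit_beta_from_range(1.2, 1.0, 1.4)


class TestFitGamma:
    def test_cost_shape(self):
        dist = fit_gamma(2395.13, 0.2)
        assert dist.params["shape"] == pytest.approx(25.0)
        assert dist.mean == pytest.approx(2395.13, abs=1e-9)

    def test_exponential(self):
        dist = fit_gamma(1.0, 1.0)
        assert dist.params["shape"] == pytest.approx(1.0)
        assert dist.mean == pytest.approx(1.0)

    def test_degenerate_limit(self):
        dist = fit_gamma(42.0, 0.001)
        draws = dist.sample(np.random.default_rng(3), size=1000)
        assert np.all(np.abs(draws - 42.0) < 1.0)

    def test_errors(self):
        with pytest.raises(ParameterError):
            fit_gamma(-1, 0.2)
        with pytest.raises(ParameterError):
            fit_gamma(1, 0)


class TestParameterPaths:
    def test_resolve_known_paths(self, params):
        assert resolve_parameter(params, "economics.discount_rate") == 0.045
        assert resolve_parameter(params, "tcs.total") == 251.25
        assert resolve_parameter(params, "rr.READMIT_COPD") == 0.599
        assert resolve_parameter(params, "utility.STABLE") == 0.795
        assert resolve_parameter(params, "cost.60s.READMIT_COPD.total") == 2395.13
        assert resolve_parameter(params, "prob.80s.READMIT_OTHER") == pytest.approx(410 / 1701)

    def test_unknown_path_rejected(self, params):
        for path in ("nurse.salary", "rr.BOGUS", "cost.50s.STABLE.total", "utility"):
            with pytest.raises(ParameterError, match="path"):
                resolve_parameter(params, path)
        with pytest.raises(ParameterError, match="path"):
            set_parameter(params, "nurse.salary", 1.0)

    def test_set_round_trip(self, params):
        for path, value in [
            ("economics.discount_rate", 0.09),
            ("tcs.total", 300.0),
            ("rr.READMIT_OTHER", 0.648),
            ("utility.READMIT_RESP", 0.468),
            ("cost.70s.READMIT_RESP.total", 4000.0),
        ]:
            modified = set_parameter(params, path, value)
            assert resolve_parameter(modified, path) == pytest.approx(value)
            # base set untouched
            assert resolve_parameter(params, path) != pytest.approx(value)

    def test_set_probability_renormalizes(self, params):
        modified = set_parameter(params, "prob.60s.READMIT_OTHER", 0.25)
        dist = modified.distributions["60s"]
        assert dist.prob(S.READMIT_OTHER) == pytest.approx(0.25)
        assert sum(dist.prob(s) for s in ALIVE_STATES) == pytest.approx(1.0, abs=1e-12)


class TestOneWayDsa:
    def test_degenerate_spec_zero_swing_last(self, params):
        base_tcs = params.tcs_costs.total
        specs = [
            DsaSpec("tcs.total", base_tcs, base_tcs),
            DsaSpec("rr.READMIT_OTHER", 0.648, 0.792),
        ]
        entries = one_way_dsa(params, specs, "60s")
        assert entries[-1].path == "tcs.total"
        assert entries[-1].swing == pytest.approx(0.0, abs=1e-9)

    def test_tcs_cost_swing_is_linear(self, params):
        tcs = params.tcs_costs.total
        specs = [DsaSpec("tcs.total", 0.75 * tcs, 1.25 * tcs)]
        (entry,) = one_way_dsa(params, specs, "60s")
        # bounds round to cents (188.44 / 314.06), so the swing is exactly 125.62
        assert entry.swing == pytest.approx(125.62, abs=1e-6)

    def test_sorted_descending(self, params):
        entries = one_way_dsa(params, default_dsa_specs(params, "60s"), "60s")
        swings = [e.swing for e in entries]
        assert swings == sorted(swings, reverse=True)

    def test_other_disease_parameters_rank_high(self, params):
        entries = one_way_dsa(params, default_dsa_specs(params, "60s"), "60s")
        top5 = {e.path for e in entries[:5]}
        assert any("READMIT_OTHER" in p for p in top5)

    def test_invalid_spec(self):
        with pytest.raises(ParameterError):
            DsaSpec("tcs.total", 10.0, 5.0)

    def test_tornado_frame(self, params):
        specs = [DsaSpec("rr.READMIT_COPD", 0.539, 0.659)]
        df = tornado_frame(one_way_dsa(params, specs, "70s"))
        assert list(df.columns) == ["parameter", "low_outcome", "high_outcome", "swing"]
        assert len(df) == 1


def point_registry(params, cohort):
    """Degenerate PSA registry: every distribution is a point mass at base."""
    registry = psa_distributions(params, cohort)
    return {
        path: PsaDistribution(
            family="point", params={"value": resolve_parameter(params, path)}, target=path
        )
        for path in registry
    }


class TestRunPsa:
    def test_degenerate_collapses_to_baseline(self, params):
        registry = point_registry(params, "60s")
        res = run_psa(params, 1, seed=0, cohort="60s", registry=registry)
        tcs = run_arm(params, Arm.TCS, "60s")
        usual = run_arm(params, Arm.USUAL_CARE, "60s")
        ce_base = incremental_result(tcs, usual, "60s")
        assert res.delta_costs[0] == pytest.approx(ce_base.delta_cost, abs=1e-9)
        assert res.delta_effects[0] == pytest.approx(ce_base.delta_effect, abs=1e-9)

    def test_reproducible(self, params):
        a = run_psa(params, 50, seed=123, cohort="70s")
        b = run_psa(params, 50, seed=123, cohort="70s")
        np.testing.assert_array_equal(a.delta_costs, b.delta_costs)
        np.testing.assert_array_equal(a.delta_effects, b.delta_effects)

    def test_seed_matters(self, params):
        a = run_psa(params, 50, seed=123, cohort="70s")
        b = run_psa(params, 50, seed=124, cohort="70s")
        assert not np.array_equal(a.delta_costs, b.delta_costs)

    def test_invalid_iterations(self, params):
        with pytest.raises(ParameterError):
            run_psa(params, 0, seed=1, cohort="60s")

    def test_sampled_means_match_specified(self, params):
        registry = psa_distributions(params, "60s")
        n = 10_000
        for i, (path, dist) in enumerate(sorted(registry.items())):
            if dist.family == "point":
                continue
            rng = np.random.default_rng((9, i))
            draws = dist.sample(rng, size=n)
            se = float(np.std(draws)) / np.sqrt(n)
            assert abs(float(np.mean(draws)) - dist.mean) <= 3 * se + 1e-12, path

    def test_renormalized_probability_draws_valid(self, params):
        from tcscea.sensitivity import _sampled_params

        registry = psa_distributions(params, "80s")
        rng = np.random.default_rng(5)
        for _ in range(200):
            draws = {p: float(d.sample(rng)) for p, d in registry.items()}
            sampled = _sampled_params(params, "80s", draws)
            dist = sampled.distributions["80s"]
            probs = [dist.prob(s) for s in ALIVE_STATES]
            assert all(0 <= p <= 1 for p in probs)
            assert sum(probs) == pytest.approx(1.0, abs=1e-12)


class TestCeac:
    def test_all_dominant(self):
        res = PSAResult(
            delta_costs=np.array([-10.0, -5.0]),
            delta_effects=np.array([0.1, 0.2]),
            n_iter=2,
            seed=0,
            cohort="60s",
        )
        curve = ceac(res, [0, 10_000, 50_000])
        np.testing.assert_array_equal(curve.probabilities, 1.0)

    def test_wtp_zero_is_fraction_cheaper(self):
        res = PSAResult(
            delta_costs=np.array([-10.0, 5.0, -1.0, 2.0]),
            delta_effects=np.array([0.1, 0.1, -0.1, 0.2]),
            n_iter=4,
            seed=0,
            cohort="60s",
        )
        curve = ceac(res, [1e-9, 100.0])
        assert curve.probabilities[0] == pytest.approx(0.5)

    def test_tie_counts_as_not_cost_effective(self):
        res = PSAResult(
            delta_costs=np.array([-100.0, 100.0]),
            delta_effects=np.array([0.1, 0.1]),
            n_iter=2,
            seed=0,
            cohort="60s",
        )
        curve = ceac(res, [1000.0])
        assert curve.probabilities[0] == pytest.approx(0.5)

    def test_monotone_when_effects_nonnegative(self, params):
        res = run_psa(params, 100, seed=17, cohort="60s")
        keep = res.delta_effects >= 0
        res2 = PSAResult(
            delta_costs=res.delta_costs[keep],
            delta_effects=res.delta_effects[keep],
            n_iter=int(keep.sum()),
            seed=17,
            cohort="60s",
        )
        curve = ceac(res2, np.arange(0, 50_001, 500.0))
        assert np.all(np.diff(curve.probabilities) >= -1e-12)

    def test_limit_is_fraction_positive_effect(self):
        # the zero-effect draw has positive cost, so it never becomes acceptable
        res = PSAResult(
            delta_costs=np.array([5.0, -5.0, 5.0, 5.0]),
            delta_effects=np.array([0.2, -0.1, 0.0, 0.3]),
            n_iter=4,
            seed=0,
            cohort="60s",
        )
        curve = ceac(res, [1e12])
        assert curve.probabilities[0] == pytest.approx(0.5)

    def test_empty_inputs(self):
        res = PSAResult(
            delta_costs=np.array([1.0]),
            delta_effects=np.array([1.0]),
            n_iter=1,
            seed=0,
            cohort="60s",
        )
        with pytest.raises(ParameterError):
            ceac(res, [])

    def test_descending_grid_rejected(self):
        with pytest.raises(ParameterError):
            CEACurve(wtp_grid=np.array([2.0, 1.0]), probabilities=np.array([0.5, 0.5]))


class TestPlots:
    def test_plot_smoke(self, params, tmp_path):
        entries = one_way_dsa(
            params, [DsaSpec("rr.READMIT_COPD", 0.539, 0.659)], "60s"
        )
        plot_tornado(entries, 1000.0, tmp_path / "tornado.png")
        res = run_psa(params, 20, seed=2, cohort="60s")
        plot_ce_plane({"60s": res}, 23050, tmp_path / "plane.png")
        curve = ceac(res, np.arange(0, 50_001, 1000.0))
        plot_ceac({"60s": curve}, 23050, tmp_path / "ceac.png")
        for name in ("tornado.png", "plane.png", "ceac.png"):
            assert (tmp_path / name).stat().st_size > 0
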