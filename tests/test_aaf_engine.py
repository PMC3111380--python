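"""Attributable-fraction arithmetic, quadrature and scenario machinery."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import injury_aaf as ia
from injury_aaf.aaf_engine import (
    ScenarioConfig,
    _excess_at,
    aaf_average,
    aaf_binge,
    aaf_categorical,
    aggregate_aaf,
    combine_aaf,
    rr_average_adjusted,
    rr_binge_adjusted,
    run_scenario,
    wholly_attributable,
)
from injury_aaf.consumption import PointMassConsumption, fit_gamma
from injury_aaf.risk_model import MVA, NON_MVA


def simulated_aaf(prevalences, rrs, n_days, rng):
    """Expected-deaths bookkeeping over simulated person-days.

    Persons are assigned to exposure groups multinomially; each
    contributes deaths proportional to its group RR.  The attributable
    fraction is the excess over the all-reference counterfactual.
    """
    counts = rng.multinomial(n_days, prevalences)
    deaths = float(np.dot(counts, rrs))
    counterfactual = float(counts.sum())  # RR 1 for everyone
    return (deaths - counterfactual) / deaths


class TestCategoricalAAF:
    def test_two_group_hand_value(self):
        assert aaf_categorical((0.5, 0.5), (1.0, 2.0)) == pytest.approx(1 / 3)

    def test_null_risks_give_zero(self):
        assert aaf_categorical((0.2, 0.8), (1.0, 1.0)) == 0.0

    def test_three_group_hand_value(self):
        # 0.2 * 0.1169 / (0.2 * 0.1169 + 1)
        assert aaf_categorical((0.3, 0.5, 0.2), (1.0, 1.0, 1.1169)) == pytest.approx(
            0.0228458, abs=1e-6
        )

    @pytest.mark.parametrize(
        "p,r",
        [((0.5, 0.6), (1.0, 2.0)), ((0.5, 0.5), (1.0,)), ((-0.1, 1.1), (1.0, 2.0)),
         ((0.5, 0.5), (1.0, -2.0))],
    )
    def test_invalid_inputs_rejected(self, p, r):
        with pytest.raises(ValueError):
            aaf_categorical(p, r)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(0, 10_000))
    def test_agrees_with_person_day_simulation(self, seed):
        """Formula matches brute-force expected-deaths bookkeeping at 10^6 draws."""
        rng = np.random.default_rng(seed)
        k = rng.integers(2, 5)
        p = rng.dirichlet(np.ones(k))
        rr = np.concatenate([[1.0], 1.0 + 2.0 * rng.random(k - 1)])
        analytic = aaf_categorical(p, rr)
        simulated = simulated_aaf(p, rr, 1_000_000, rng)
        assert simulated == pytest.approx(analytic, abs=1e-3)


class TestAdjustedRR:
    def test_binge_mixture_hand_value(self):
        # 5 drinks -> 5.5 h risk period -> p_day 0.229167; 52 occasions/yr
        adj = rr_binge_adjusted(4.58, 5.5 / 24.0, 52.0 / 365.0)
        assert adj == pytest.approx(1.1169, abs=1e-4)

    def test_never_exposed_is_null(self):
        assert rr_binge_adjusted(4.58, 0.22917, 0.0) == 1.0

    def test_always_exposed_is_crude(self):
        assert rr_binge_adjusted(4.58, 1.0, 1.0) == pytest.approx(4.58)

    def test_average_mixture_hand_value(self):
        assert rr_average_adjusted(5.0, 0.125) == pytest.approx(1.5)

    def test_average_endpoints(self):
        assert rr_average_adjusted(5.0, 0.0) == 1.0
        assert rr_average_adjusted(5.0, 1.0) == pytest.approx(5.0)

    def test_sub_unit_crude_rr_rejected(self):
        with pytest.raises(ValueError, match="below 1"):
            rr_binge_adjusted(0.9, 0.5, 0.5)
        with pytest.raises(ValueError, match="below 1"):
            rr_average_adjusted(0.9, 0.5)


class TestBingeAAF:
    def test_zero_binge_prevalence_gives_zero(self, curves, metabolism, summary):
        s = replace(summary, binge_prevalence=0.0)
        assert aaf_binge(s, curves[MVA], metabolism, ScenarioConfig()) == 0.0

    def test_matches_categorical_composition(self, curves, metabolism, summary):
        scenario = ScenarioConfig()
        dose = scenario.binge_dose_for(summary)  # men, main analysis: 5 drinks
        assert dose == pytest.approx(68.0)
        adj = rr_binge_adjusted(
            ia.rr_crude(curves[MVA], dose),
            ia.p_day_at_risk(metabolism, dose),
            ia.p_days_at_risk(summary.binge_occasions_per_year),
        )
        expected = aaf_categorical(
            (summary.p_abstainer_former, summary.p_current_nonbinge, summary.binge_prevalence),
            (1.0, 1.0, adj),
        )
        assert aaf_binge(summary, curves[MVA], metabolism, scenario) == pytest.approx(expected)

    def test_monotone_in_binge_dose_below_cap(self, curves, metabolism, summary):
        doses = [40.0, 60.0, 80.0, 100.0]
        vals = []
        for d in doses:
            s = replace(summary, binge_dose=d)
            vals.append(aaf_binge(s, curves[MVA], metabolism, ScenarioConfig(scenario="SA_III")))
        assert vals == sorted(vals)
        assert vals[0] < vals[-1]


class TestAverageAAF:
    def test_no_current_drinkers_gives_zero(self, curves, metabolism, summary):
        s = replace(summary, p_abstainer_former=1.0, p_current=0.0, binge_prevalence=0.0)
        dist = fit_gamma(20.0, 20.0)
        assert aaf_average(s, dist, curves[NON_MVA], metabolism) == 0.0

    def test_point_mass_reproduces_categorical(self, curves, metabolism, summary):
        x0 = 30.0
        adj = rr_average_adjusted(
            ia.rr_crude(curves[NON_MVA], x0), ia.p_day_at_risk(metabolism, x0)
        )
        expected = aaf_categorical(
            (summary.p_abstainer_former, summary.p_current), (1.0, adj)
        )
        got = aaf_average(summary, PointMassConsumption(x0), curves[NON_MVA], metabolism)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_quadrature_agrees_with_fine_riemann(self, curves, metabolism, summary):
        cfg = ScenarioConfig()
        dist = fit_gamma(27.9, 35.1)  # shape 0.63, scale 44.2
        s = replace(summary, p_abstainer_former=0.2, p_current=0.8, binge_prevalence=0.1)
        impl = aaf_average(s, dist, curves[NON_MVA], metabolism, grid=cfg.grid())
        step = cfg.grid_step / 10.0
        xm = np.arange(cfg.grid_low, cfg.grid_high, step) + step / 2.0
        a = s.p_current * float(np.sum(dist.pdf(xm) * _excess_at(xm, curves[NON_MVA], metabolism))) * step
        assert impl == pytest.approx(a / (a + 1.0), abs=1e-6)

    def test_monotone_in_mean_consumption(self, curves, metabolism, summary):
        vals = []
        for mean in (10.0, 20.0, 40.0):
            dist = fit_gamma(mean, 1.171 * mean)
            vals.append(aaf_average(summary, dist, curves[NON_MVA], metabolism))
        assert vals == sorted(vals)
        assert vals[0] < vals[-1]


class TestCombineAggregate:
    def test_combination_and_death_conversion(self):
        est = combine_aaf(0.02, 0.10, 200.0)
        assert est.aaf_total == pytest.approx(0.12)
        assert est.attributable_deaths == pytest.approx(24.0)

    def test_null_components(self):
        est = combine_aaf(0.0, 0.0, 57.0)
        assert est.aaf_total == 0.0
        assert est.attributable_deaths == 0.0

    def test_clipped_at_one(self):
        assert combine_aaf(0.7, 0.6, 10.0).aaf_total == 1.0

    def test_negative_deaths_rejected(self):
        with pytest.raises(ValueError):
            combine_aaf(0.1, 0.1, -5.0)

    def test_wholly_attributable_codes(self):
        assert wholly_attributable("X45") == 1.0
        assert wholly_attributable("X65") == 1.0
        with pytest.raises(ValueError, match="general"):
            wholly_attributable("W00")

    def test_death_weighted_aggregation(self):
        assert aggregate_aaf([0.2, 0.4], [100.0, 300.0]) == pytest.approx(0.35)
        assert aggregate_aaf([0.3], [50.0]) == pytest.approx(0.3)
        assert aggregate_aaf([0.2, 0.2], [10.0, 90.0]) == pytest.approx(0.2)

    def test_zero_total_deaths_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            aggregate_aaf([0.2, 0.4], [0.0, 0.0])


class TestRunScenario:
    def test_binge_dose_rules(self, summary):
        woman = replace(summary, sex="W")
        for scen, (dm, dw) in (("main", (68.0, 54.4)), ("SA_I", (81.6, 68.0)),
                               ("SA_II", (95.2, 81.6))):
            cfg = ScenarioConfig(scenario=scen)
            assert cfg.binge_dose_for(summary) == pytest.approx(dm)
            assert cfg.binge_dose_for(woman) == pytest.approx(dw)

    def test_sa3_requires_group_doses(self, summary):
        cfg = ScenarioConfig(scenario="SA_III")
        with pytest.raises(ValueError, match="binge_dose"):
            cfg.binge_dose_for(replace(summary, binge_dose=None))
        assert cfg.binge_dose_for(replace(summary, binge_dose=90.0)) == 90.0

    def test_scenario_monotonicity_for_mva(self, gamma_truth):
        bundle, cfg = ia.make_bundle(gamma_truth)
        totals = {}
        for scen in ("main", "SA_I", "SA_II"):
            ests = run_scenario(bundle, replace(cfg, scenario=scen))
            totals[scen] = [e.aaf_total for e in ests if e.injury_class == MVA]
        assert all(a <= b for a, b in zip(totals["main"], totals["SA_I"]))
        assert all(a <= b for a, b in zip(totals["SA_I"], totals["SA_II"]))

    def test_bookkeeping_identity(self, gamma_truth):
        bundle, cfg = ia.make_bundle(gamma_truth)
        for e in run_scenario(bundle, cfg):
            assert e.attributable_deaths == pytest.approx(e.aaf_total * e.deaths)

    def test_no_binge_anywhere_zeroes_the_binge_component(self, point_truth):
        truth = replace(
            point_truth,
            groups=tuple(replace(g, binge_prevalence=0.0) for g in point_truth.groups),
        )
        bundle, cfg = ia.make_bundle(truth)
        assert all(e.aaf_binge == 0.0 for e in run_scenario(bundle, cfg))

    def test_missing_stratum_reported(self, gamma_truth):
        bundle, cfg = ia.make_bundle(gamma_truth)
        extra = bundle.mortality.copy()
        extra.loc[len(extra)] = ["Falls", "60-69", "M", 10.0]
        with pytest.raises(ValueError, match="60-69"):
            run_scenario(replace(bundle, mortality=extra), cfg)
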