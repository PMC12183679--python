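"""Reactor physics: elementary relations, solver cross-validation, and
conservation/monotonicity properties."""

import numpy as np
import pytest
from dataclasses import replace
from hypothesis import given, settings, strategies as st

from flowopt.reactor import (
    ConditionBounds,
    KineticParameters,
    NumericsConfig,
    ReactionConditions,
    ReactorModel,
    analytic_isothermal_outlet,
    bimolecular_conversion,
    feed_concentrations,
    flow_from_residence_time,
    rate_constant,
    reaction_rate,
    residence_time_from_flow,
    simulate,
    steady_state_outlet,
)


class TestElementaryRelations:
    @pytest.mark.parametrize(
        "res_t, volume, expected",
        [(8.0, 1.32e-6, 0.165), (0.5, 1.32e-6, 2.64)],
    )
    def test_flow_from_residence_time(self, res_t, volume, expected):
        assert flow_from_residence_time(res_t, volume) == pytest.approx(expected)

    def test_flow_round_trip(self):
        q = flow_from_residence_time(3.7, 1.32e-6)
        assert residence_time_from_flow(q, 1.32e-6) == pytest.approx(3.7)

    @pytest.mark.parametrize("bad", [0.0, -1.0])
    def test_flow_rejects_nonpositive(self, bad):
        with pytest.raises(ValueError):
            flow_from_residence_time(bad, 1.32e-6)

    @pytest.mark.parametrize(
        "er, expected",
        [
            (1.0, (2.0, 2.0)),
            (1.1, (2.0952, 1.9048)),
            (0.1, (0.3636, 3.6364)),
        ],
    )
    def test_feed_concentrations(self, er, expected):
        c1f, c2f = feed_concentrations(er, 4.0, 4.0)
        assert c1f == pytest.approx(expected[0], abs=1e-4)
        assert c2f == pytest.approx(expected[1], abs=1e-4)
        # equal stocks split the total concentration
        assert c1f + c2f == pytest.approx(4.0)

    def test_feed_concentrations_rejects_nonpositive_ratio(self):
        with pytest.raises(ValueError):
            feed_concentrations(0.0, 4.0, 4.0)

    def test_rate_constant_at_reference_is_kref(self, kin):
        assert rate_constant(kin.tref, kin) == pytest.approx(0.413)

    def test_rate_constant_at_330K(self, kin):
        assert rate_constant(330.0, kin) == pytest.approx(0.956, abs=2e-3)

    def test_rate_constant_increasing_in_temperature(self, kin):
        temps = np.linspace(278, 330, 20)
        ks = rate_constant(temps, kin)
        assert np.all(np.diff(ks) > 0)

    def test_vanishing_activation_energy_gives_flat_k(self):
        kin = KineticParameters(ea=1e-9, kref=0.413)
        assert rate_constant(278.0, kin) == pytest.approx(0.413)
        assert rate_constant(330.0, kin) == pytest.approx(0.413)

    @pytest.mark.parametrize(
        "k, c1, c2, expected", [(0.5, 2.0, 2.0, 2.0), (0.7, 0.0, 3.0, 0.0), (0.0, 2.0, 2.0, 0.0)]
    )
    def test_reaction_rate(self, k, c1, c2, expected):
        assert reaction_rate(k, c1, c2) == pytest.approx(expected)

    def test_reaction_rate_rejects_negative_concentration(self):
        with pytest.raises(ValueError):
            reaction_rate(0.5, -0.1, 2.0)


class TestClosedForm:
    def test_full_conversion_asymptote(self):
        cond = ReactionConditions(8.0, 1.0, 330.0)
        assert analytic_isothermal_outlet(cond, k=1e6) == pytest.approx(2.0, abs=1e-4)

    def test_unequal_feed_hand_value(self):
        cond = ReactionConditions(3.8, 1.1, 320.0)
        assert analytic_isothermal_outlet(cond, k=0.782) == pytest.approx(1.70, abs=5e-3)

    def test_zero_contact_time_gives_zero(self):
        assert bimolecular_conversion(2.0, 2.0, 0.0, 5.0) == 0.0

    def test_equal_and_unequal_branches_continuous(self):
        # approaching equal feeds, the general form converges to the equal form
        x_eq = bimolecular_conversion(2.0, 2.0, 0.5, 4.0)
        x_near = bimolecular_conversion(2.0 + 1e-8, 2.0, 0.5, 4.0)
        assert x_near == pytest.approx(x_eq, rel=1e-6)


class TestSolvers:
    def test_transient_matches_closed_form(self, iso_model, kin):
        cond = ReactionConditions(8.0, 1.0, 330.0)
        res = simulate(cond, iso_model)
        expected = analytic_isothermal_outlet(cond, rate_constant(330.0, kin))
        assert expected == pytest.approx(1.877, abs=1e-3)
        assert res.converged
        assert res.outlet_c3 == pytest.approx(expected, rel=1e-3)

    def test_steady_state_route_matches_transient(self, iso_model):
        cond = ReactionConditions(8.0, 1.0, 330.0)
        c3_ss = steady_state_outlet(cond, iso_model)[2]
        c3_tr = simulate(cond, iso_model).outlet_c3
        assert abs(c3_ss - c3_tr) / c3_ss < 5e-3

    def test_vanishing_residence_time_gives_zero_conversion(self, iso_model):
        wide = replace(iso_model, bounds=ConditionBounds(res_t=(1e-4, 8.0)))
        c3 = steady_state_outlet(ReactionConditions(1e-3, 1.0, 330.0), wide)[2]
        assert c3 < 5e-3

    def test_stoichiometric_conservation_along_profile(self, iso_model):
        cond = ReactionConditions(5.0, 1.3, 315.0)
        res = simulate(cond, iso_model)
        c1f, c2f = iso_model.feed_concentrations(cond.er)
        p = res.profile
        assert np.max(np.abs((c1f - p.c1) - p.c3)) < 1e-6
        assert np.max(np.abs((c2f - p.c2) - p.c3)) < 1e-6

    def test_monotone_in_residence_time_and_temperature(self, iso_model):
        c3_rt = [
            steady_state_outlet(ReactionConditions(rt, 1.0, 310.0), iso_model)[2]
            for rt in np.linspace(0.5, 8, 6)
        ]
        assert np.all(np.diff(c3_rt) > 0)
        c3_t = [
            steady_state_outlet(ReactionConditions(4.0, 1.0, t), iso_model)[2]
            for t in np.linspace(278, 330, 6)
        ]
        assert np.all(np.diff(c3_t) > 0)

    def test_grid_refinement_stable(self, iso_model):
        cond = ReactionConditions(8.0, 1.0, 330.0)
        c3_n = simulate(cond, iso_model, NumericsConfig(n_nodes=400)).outlet_c3
        c3_2n = simulate(cond, iso_model, NumericsConfig(n_nodes=800)).outlet_c3
        assert abs(c3_2n - c3_n) / c3_n < 5e-3

    def test_out_of_bounds_conditions_rejected(self, iso_model):
        with pytest.raises(ValueError):
            steady_state_outlet(ReactionConditions(9.0, 1.0, 330.0), iso_model)

    def test_energy_coupling_slightly_exothermic(self, model):
        cond = ReactionConditions(4.0, 1.0, 310.0)
        c1, c2, c3, temp = steady_state_outlet(cond, model)
        # reaction releases heat; the strong jacket pins T just above the set point
        assert temp > cond.temp
        assert temp - cond.temp < 1.0

    def test_isothermal_profile_is_flat(self, iso_model):
        res = simulate(ReactionConditions(4.0, 1.0, 310.0), iso_model)
        assert np.all(res.profile.temp == 310.0)

    def test_feed_temperature_arrhenius_mode(self, model):
        # literal mode evaluates kinetics at Tf; with the jacket pinning T,
        # both modes agree closely but not identically
        lit = replace(model, arrhenius_mode="feed-temperature")
        cond = ReactionConditions(6.0, 1.0, 325.0)
        c3_local = steady_state_outlet(cond, model)[2]
        c3_feed = steady_state_outlet(cond, lit)[2]
        assert c3_feed == pytest.approx(c3_local, rel=1e-3)
        assert c3_feed != c3_local


class TestProperties:
    @settings(max_examples=25, deadline=None)
    @given(
        rt=st.floats(0.5, 8.0),
        er=st.floats(0.1, 2.0),
        temp=st.floats(278.0, 330.0),
    )
    def test_outlet_bounded_by_limiting_feed(self, rt, er, temp):
        iso = ReactorModel().isothermal()
        cond = ReactionConditions(rt, er, temp)
        c1, c2, c3, _ = steady_state_outlet(cond, iso)
        c1f, c2f = iso.feed_concentrations(er)
        assert -1e-9 <= c3 <= min(c1f, c2f) + 1e-6
        assert (c1f - c1) == pytest.approx(c3, abs=1e-6)
        assert (c2f - c2) == pytest.approx(c3, abs=1e-6)

    def test_model_validation(self):
        with pytest.raises(ValueError):
            ReactorModel(volume=-1.0)
        with pytest.raises(ValueError):
            KineticParameters(ea=-5.0)
        with pytest.raises(ValueError):
            KineticParameters(tref=500.0)
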