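"""Asthma medication model: event accounting, persistence fixed points,
closed-form limits, drift, mortality, and monotonicity."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from carecase.asthma import (AsthmaParams, EVENTS, build_asthma_model,
                             compare_med_use_scenarios, initial_distribution,
                             persistence_for_rate, run_asthma_scenario)
from carecase.engine import ModelValidationError, run_cohort, run_microsim, validate_model

NO_EVENTS = dict(p_exac_no_er={"with_med": 0.0, "without_med": 0.0},
                 p_exac_er={"with_med": 0.0, "without_med": 0.0},
                 p_exac_admit={"with_med": 0.0, "without_med": 0.0})


def med_use_fraction(trace, month: int) -> float:
    """Medication-use fraction among the living at a given month."""
    occ = trace.occupancy_frame()
    on = occ.iloc[month][[c for c in occ.columns if c.startswith("on_")]].sum()
    alive = 1.0 - occ.iloc[month]["dead"]
    return float(on / alive)


class TestConstruction:
    def test_built_model_validates(self, asthma_params):
        model, _ = build_asthma_model(asthma_params, "adult", 0.80)
        report = validate_model(model, initial=initial_distribution(0.80))
        assert report.ok, report.violations

    def test_initial_med_use_equals_scenario_rate(self, asthma_params):
        out = run_asthma_scenario(asthma_params, 0.73, 6, "adult")
        # month-1 occupancy keeps the assigned medication split (less deaths)
        assert med_use_fraction(out.trace, 1) == pytest.approx(0.73, abs=1e-3)

    def test_unknown_population_rejected(self, asthma_params):
        with pytest.raises(ModelValidationError, match="population"):
            build_asthma_model(asthma_params, "teen")

    def test_occupancy_conserved_every_cycle(self, asthma_outputs):
        for out in asthma_outputs.values():
            assert np.allclose(out.trace.occupancy.sum(axis=1), 1.0, atol=1e-9)


class TestClosedForms:
    def test_no_event_work_days(self):
        """With exacerbations and deaths switched off an adult attends every
        available day: 60 x 21.67 = 1300.2."""
        params = AsthmaParams(**NO_EVENTS, p_death_other_monthly=0.0)
        out = run_asthma_scenario(params, 0.80, 60, "adult")
        assert out.attended_days == pytest.approx(1300.2, abs=1e-9)
        assert out.missed_days == pytest.approx(0.0, abs=1e-12)

    def test_no_event_qalys_at_fixed_mix(self):
        """Without events and with frozen medication status, QALYs reduce to
        60 x (r*u_on + (1-r)*u_off)."""
        frozen = {"on": {e: 1.0 for e in EVENTS}, "off": {e: 0.0 for e in EVENTS}}
        params = AsthmaParams(**NO_EVENTS, p_death_other_monthly=0.0,
                              persistence=frozen, persistence_presets={0.8: frozen})
        r = 0.8
        out = run_asthma_scenario(params, r, 60, "adult")
        expected = 60 * (r * 0.0748 + (1 - r) * 0.0756)
        assert out.qalys == pytest.approx(expected, abs=1e-9)

    def test_single_month_expected_missed_days_full_adherence(self, asthma_params):
        """One month, everyone medicated: .27*3 + .0382*4 + .0035*7 = .9873
        expected missed days (scaled by one month of other-cause survival)."""
        out = run_asthma_scenario(asthma_params, 1.0, 1, "adult")
        hand = (0.27 * 3 + 0.0382 * 4 + 0.0035 * 7) * (1 - 0.0001)
        assert out.missed_days == pytest.approx(hand, abs=1e-6)
        assert out.missed_days == pytest.approx(0.987, abs=2e-3)


class TestPersistence:
    @pytest.mark.parametrize("rate, expected_fp", [(0.70, 0.708), (0.80, 0.806), (0.90, 0.903)])
    def test_preset_fixed_points_track_scenario_rates(self, asthma_params, rate, expected_fp):
        table = persistence_for_rate(asthma_params, rate)
        ev_on = asthma_params.event_probabilities("on")
        ev_off = asthma_params.event_probabilities("off")
        stay = sum(ev_on[e] * table["on"][e] for e in EVENTS)
        gain = sum(ev_off[e] * table["off"][e] for e in EVENTS)
        fp = gain / (gain + 1 - stay)
        assert fp == pytest.approx(expected_fp, abs=2e-3)

    @given(rate=st.floats(0.35, 0.93))
    def test_solved_tables_have_fixed_point_at_rate(self, rate):
        params = AsthmaParams(persistence_presets={})
        table = persistence_for_rate(params, rate)
        ev_on = params.event_probabilities("on")
        ev_off = params.event_probabilities("off")
        stay = sum(ev_on[e] * table["on"][e] for e in EVENTS)
        gain = sum(ev_off[e] * table["off"][e] for e in EVENTS)
        assert gain / (gain + 1 - stay) == pytest.approx(rate, abs=1e-9)

    def test_infeasible_rate_raises(self):
        params = AsthmaParams(persistence_presets={})
        with pytest.raises(ModelValidationError, match="persistence"):
            persistence_for_rate(params, 0.999)

    def test_med_use_drifts_gently_upward(self, asthma_outputs):
        """The cohort medication-use fraction rises gradually from its
        starting rate over the 60 months."""
        for rate, out in asthma_outputs.items():
            m1 = med_use_fraction(out.trace, 1)
            m60 = med_use_fraction(out.trace, 60)
            assert m60 >= m1 - 1e-9, f"rate {rate}: {m1:.5f} -> {m60:.5f}"
            assert abs(m60 - rate) < 0.02, "drift should stay gentle"


class TestScenarioOutputs:
    def test_mortality_negligible_over_five_years(self, asthma_outputs):
        for out in asthma_outputs.values():
            assert out.deaths < 0.01

    def test_monotone_in_medication_use(self, asthma_outputs):
        rates = sorted(asthma_outputs)
        for a, b in zip(rates, rates[1:]):
            assert asthma_outputs[b].attended_days >= asthma_outputs[a].attended_days
            assert asthma_outputs[b].qalys >= asthma_outputs[a].qalys
            assert asthma_outputs[b].direct_cost_events <= asthma_outputs[a].direct_cost_events

    def test_identical_scenarios_give_zero_deltas(self, asthma_params):
        delta = compare_med_use_scenarios(asthma_params, 0.80, 0.80, 24, "adult")
        for name, value in delta.as_dict().items():
            assert value == pytest.approx(0.0, abs=1e-12), name

    def test_direct_cost_decomposition(self, asthma_base_delta):
        d = asthma_base_delta
        assert d.direct_cost_total == pytest.approx(
            d.direct_cost_events + d.direct_cost_medication, abs=1e-9)
        assert d.direct_cost_events < 0 < d.direct_cost_medication

    def test_child_days_use_school_scale(self, asthma_params):
        child = run_asthma_scenario(asthma_params, 0.80, 12, "child")
        adult = run_asthma_scenario(asthma_params, 0.80, 12, "adult")
        assert child.attended_days < adult.attended_days
        assert child.attended_days <= 12 * 15.0
        # same exacerbation process, same missed days
        assert child.missed_days == pytest.approx(adult.missed_days, abs=1e-9)

    def test_parent_workday_ratio_scales_indirect_cost(self, asthma_params):
        half = asthma_params.model_copy(update={"parent_workday_ratio": 0.5})
        full = run_asthma_scenario(asthma_params, 0.80, 12, "child")
        scaled = run_asthma_scenario(half, 0.80, 12, "child")
        assert scaled.indirect_cost == pytest.approx(0.5 * full.indirect_cost, rel=1e-9)

    def test_strict_horizon_flag(self, asthma_params):
        with pytest.raises(ModelValidationError, match="horizon"):
            run_asthma_scenario(asthma_params, 0.8, 13, "adult", strict_horizon=True)

    def test_utility_scale_identity(self, asthma_params):
        """Monthly no-exacerbation utilities equal the daily utilities on a
        month = 30/365-year scale, within 1%."""
        month_fraction = 30 / 365
        assert asthma_params.utilities_monthly["none"]["with_med"] / 0.91 == \
            pytest.approx(month_fraction, rel=0.01)
        assert asthma_params.utilities_monthly["none"]["without_med"] / 0.92 == \
            pytest.approx(month_fraction, rel=0.01)


def test_cohort_matches_microsim(asthma_params):
    """Micro-simulation oracle at the base 80% scenario (200k individuals)."""
    model, rewards = build_asthma_model(asthma_params, "adult", 0.80)
    trace = run_cohort(model, rewards, initial_distribution(0.80))
    sim = run_microsim(model, rewards, initial_distribution(0.80), 200_000, seed=20260102)
    for ch, z in sim.z_scores(trace.per_person).items():
        assert abs(z) < 3.0, f"channel {ch}: z={z:.2f}"
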