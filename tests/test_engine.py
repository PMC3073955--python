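"""Unit and property tests for the Markov cohort engine and its
micro-simulation oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from carecase.engine import (ModelValidationError, RewardSchedule, TransitionModel,
                             normalize_distribution, run_cohort, run_microsim,
                             validate_model)

#: sum_{t=1..5} 0.99^t — survival accrued at each cycle end under a 1%
#: per-cycle death hazard (geometric closed form)
GEOMETRIC_5Y = sum(0.99 ** t for t in range(1, 6))  # = 4.851985059900001


def two_state(p_die: float, n_cycles: int = 5) -> TransitionModel:
    return TransitionModel(
        states=("alive", "dead"), absorbing=frozenset({"dead"}),
        transition=lambda t, s: {"alive": 1 - p_die, "dead": p_die} if s == "alive" else {"dead": 1.0},
        n_cycles=n_cycles)


def survival_rewards(death_fraction: float = 0.0) -> RewardSchedule:
    return RewardSchedule(
        channels=("survival",),
        state_rewards=lambda t, s: {"survival": 1.0} if s == "alive" else {},
        death_cycle_fraction=death_fraction, utility_channel="survival")


class TestValidation:
    def test_well_formed_model_passes(self):
        report = validate_model(two_state(0.5))
        assert report.ok and report.violations == ()

    def test_row_sum_violation_names_state(self):
        bad = TransitionModel(
            states=("a", "b"), absorbing=frozenset(),
            transition=lambda t, s: {"a": 0.5, "b": 0.49} if s == "a" else {"b": 1.0},
            n_cycles=2)
        report = validate_model(bad)
        assert not report.ok
        assert any("row-sum" in v and "'a'" in v for v in report.violations)
        with pytest.raises(ModelValidationError):
            report.raise_if_failed()

    def test_leaky_absorbing_state_fails(self):
        bad = TransitionModel(
            states=("alive", "dead"), absorbing=frozenset({"dead"}),
            transition=lambda t, s: ({"alive": 0.99, "dead": 0.01} if s == "alive"
                                     else {"dead": 0.99, "alive": 0.01}),
            n_cycles=2)
        report = validate_model(bad)
        assert any("absorbing" in v for v in report.violations)

    def test_negative_probability_reported(self):
        bad = TransitionModel(
            states=("a", "b"), absorbing=frozenset(),
            transition=lambda t, s: {"a": 1.1, "b": -0.1} if s == "a" else {"b": 1.0},
            n_cycles=1)
        assert any("negative" in v for v in validate_model(bad).violations)

    def test_unreachable_state_flagged_with_initial(self):
        model = TransitionModel(
            states=("a", "b", "c"), absorbing=frozenset(),
            transition=lambda t, s: {"a": 1.0} if s != "c" else {"c": 1.0},
            n_cycles=2)
        report = validate_model(model, initial={"a": 1.0})
        assert any("unreachable" in v and "'c'" in v for v in report.violations)

    def test_duplicate_state_names_rejected(self):
        with pytest.raises(ModelValidationError):
            TransitionModel(states=("a", "a"), absorbing=frozenset(),
                            transition=lambda t, s: {"a": 1.0}, n_cycles=1)

    def test_config_distribution_tolerance(self):
        # small drift is rescaled, gross drift is an error
        v = normalize_distribution({"x": 0.5000001, "y": 0.5})
        assert v.sum() == pytest.approx(1.0, abs=1e-15)
        with pytest.raises(ModelValidationError):
            normalize_distribution({"x": 0.6, "y": 0.5})


class TestCohort:
    def test_absorbing_live_state_accrues_full_horizon(self):
        model = TransitionModel(states=("alive",), absorbing=frozenset({"alive"}),
                                transition=lambda t, s: {"alive": 1.0}, n_cycles=5)
        rewards = RewardSchedule(channels=("utility",),
                                 state_rewards=lambda t, s: {"utility": 1.0})
        trace = run_cohort(model, rewards, {"alive": 1.0})
        assert trace.per_person["utility"] == pytest.approx(5.0)

    def test_geometric_survival_closed_form(self):
        trace = run_cohort(two_state(0.01), survival_rewards(), {"alive": 1.0})
        assert trace.per_person["survival"] == pytest.approx(GEOMETRIC_5Y, abs=1e-12)

    def test_death_cycle_fraction_credits_part_cycle(self):
        # one cycle, certain death: utility = fraction of the source state's reward
        trace = run_cohort(two_state(1.0, n_cycles=1), survival_rewards(0.5), {"alive": 1.0})
        assert trace.per_person["survival"] == pytest.approx(0.5)

    def test_occupancy_rows_conserve_mass(self):
        trace = run_cohort(two_state(0.3), survival_rewards(), {"alive": 1.0})
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_initial_distribution_rejected(self):
        with pytest.raises(ModelValidationError, match="initial"):
            run_cohort(two_state(0.1), survival_rewards(), {"alive": 0.9})
        with pytest.raises(ModelValidationError, match="unknown"):
            run_cohort(two_state(0.1), survival_rewards(), {"elsewhere": 1.0})

    def test_discounting_shrinks_totals(self):
        undiscounted = run_cohort(two_state(0.01), survival_rewards(), {"alive": 1.0})
        discounted = run_cohort(two_state(0.01), survival_rewards(), {"alive": 1.0},
                                discount_rate=0.03)
        assert discounted.per_person["survival"] < undiscounted.per_person["survival"]

    def test_trace_csv_round_trip(self, tmp_path):
        import pandas as pd
        trace = run_cohort(two_state(0.2), survival_rewards(), {"alive": 1.0})
        path = tmp_path / "trace.csv"
        trace.to_csv(path)
        df = pd.read_csv(path, index_col=0)
        assert list(df.columns) == ["alive", "dead", "cum_survival"]
        assert df.shape[0] == 6
        assert df["cum_survival"].iloc[-1] == pytest.approx(trace.per_person["survival"])


def three_state_chain(seed: int, n_cycles: int = 4):
    rng = np.random.default_rng(seed)
    P = rng.dirichlet(np.ones(3), size=(n_cycles, 3))
    model = TransitionModel(
        states=("a", "b", "c"), absorbing=frozenset(),
        transition=lambda t, s: dict(zip(("a", "b", "c"), P[t, ("a", "b", "c").index(s)])),
        n_cycles=n_cycles)
    rs = rng.uniform(0, 2, size=(n_cycles, 3, 2))
    rewards = RewardSchedule(
        channels=("x", "y"),
        state_rewards=lambda t, s: {"x": rs[t, ("a", "b", "c").index(s), 0],
                                    "y": rs[t, ("a", "b", "c").index(s), 1]},
        death_cycle_fraction=0.0)
    return model, rewards


class TestMicrosim:
    def test_cohort_matches_microsim_within_3se(self):
        model, rewards = three_state_chain(seed=7)
        trace = run_cohort(model, rewards, {"a": 1.0})
        sim = run_microsim(model, rewards, {"a": 1.0}, 200_000, seed=11)
        for ch, z in sim.z_scores(trace.per_person).items():
            assert abs(z) < 3.0, f"channel {ch}: z={z:.2f}"

    def test_same_seed_reproduces_identical_result(self):
        model, rewards = three_state_chain(seed=3)
        a = run_microsim(model, rewards, {"a": 1.0}, 5_000, seed=42)
        b = run_microsim(model, rewards, {"a": 1.0}, 5_000, seed=42)
        assert a == b

    def test_deterministic_chain_equals_cohort_exactly(self):
        model = TransitionModel(
            states=("a", "b"), absorbing=frozenset({"b"}),
            transition=lambda t, s: {"b": 1.0},
            n_cycles=3)
        rewards = RewardSchedule(channels=("x",),
                                 state_rewards=lambda t, s: {"x": 2.0 if s == "b" else 0.0},
                                 death_cycle_fraction=0.0)
        trace = run_cohort(model, rewards, {"a": 1.0})
        sim = run_microsim(model, rewards, {"a": 1.0}, 100, seed=0)
        assert sim.means["x"] == pytest.approx(trace.per_person["x"])
        assert sim.standard_errors["x"] == 0.0

    def test_standard_error_is_sd_over_sqrt_n(self):
        model, rewards = three_state_chain(seed=5)
        sim = run_microsim(model, rewards, {"a": 1.0}, 2_000, seed=1)
        assert all(se >= 0 for se in sim.standard_errors.values())
        assert sum(sim.terminal_counts.values()) == 2_000

    def test_requires_positive_population(self):
        model, rewards = three_state_chain(seed=1)
        with pytest.raises(ModelValidationError):
            run_microsim(model, rewards, {"a": 1.0}, 0, seed=1)


@given(p=st.floats(0.0, 1.0), scale=st.floats(0.1, 10.0))
def test_channel_linearity(p, scale):
    """Scaling one channel's rewards scales its total and leaves others alone."""
    model = two_state(p)
    base = RewardSchedule(
        channels=("u", "v"),
        state_rewards=lambda t, s: {"u": 1.0, "v": 2.0} if s == "alive" else {},
        death_cycle_fraction=0.0)
    scaled = RewardSchedule(
        channels=("u", "v"),
        state_rewards=lambda t, s: {"u": scale, "v": 2.0} if s == "alive" else {},
        death_cycle_fraction=0.0)
    t0 = run_cohort(model, base, {"alive": 1.0}).per_person
    t1 = run_cohort(model, scaled, {"alive": 1.0}).per_person
    assert t1["u"] == pytest.approx(scale * t0["u"], rel=1e-12, abs=1e-12)
    assert t1["v"] == pytest.approx(t0["v"], rel=1e-12, abs=1e-12)


@given(p=st.floats(0.0, 1.0), q=st.floats(0.0, 1.0))
def test_mass_conservation_random_two_state(p, q):
    model = TransitionModel(
        states=("a", "b"), absorbing=frozenset(),
        transition=lambda t, s: ({"a": 1 - p, "b": p} if s == "a" else {"a": q, "b": 1 - q}),
        n_cycles=6)
    trace = run_cohort(model, survival_rewards(0.0), {"a": 0.5, "b": 0.5})
    assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-9)


@given(p=st.floats(0.0, 0.5))
def test_cumulative_totals_nondecreasing_for_nonnegative_rewards(p):
    trace = run_cohort(two_state(p), survival_rewards(), {"alive": 1.0})
    assert np.all(np.diff(trace.cumulative[:, 0]) >= -1e-12)
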