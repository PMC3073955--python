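"""Monthly-cycle asthma controller-medication model.

Simulates a cohort of people with persistent asthma — employed adults, or
children/adolescents whose missed school days become a parent's missed work
days — over 12 to 60 monthly cycles.  Each month a person either uses or does
not use appropriate controller medication; conditional on medication status
they experience at most one of three mutually exclusive exacerbation
categories (office-visit level, ER/urgent-care level, hospital admission) or
no exacerbation.  Next month's medication status follows a persistence law
conditioned on this month's medication status and event category, producing
the observed month-to-month switching between use and non-use while holding
the cohort-level use rate near its scenario value.

States are ``(medication status, event category this month)`` plus an
absorbing dead state.  Asthma deaths occur only out of the ER and admission
branches; a small other-cause monthly mortality applies to everyone.  The
month of death accrues half of the pre-death monthly utility (15 days at the
usual daily utility, zero thereafter).
"""

from __future__ import annotations

from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field, field_validator

from .economics import EconomicAssumptions
from .engine import (CohortTrace, ModelValidationError, RewardSchedule,
                     TransitionModel, run_cohort)

__all__ = [
    "EVENTS", "MED_STATUSES", "AsthmaParams", "AsthmaOutputs", "AsthmaDelta",
    "persistence_for_rate", "build_asthma_model",
    "run_asthma_scenario", "compare_med_use_scenarios",
    "ALLOWED_HORIZONS",
]

#: event categories within a month, mutually exclusive
EVENTS = ("none", "exac", "er", "admit")
MED_STATUSES = ("on", "off")
ALLOWED_HORIZONS = (12, 24, 36, 48, 60)

PersistenceTable = dict[str, dict[str, float]]

# Probability of using medication next month, by (current status, event this
# month).  The published sets were chosen so the cohort-level use rate stays
# essentially constant at the scenario rate over the whole simulation; each
# scenario rate therefore carries its own preset.
_BASE_PERSISTENCE: PersistenceTable = {
    "on": {"none": 0.96, "exac": 0.96, "er": 0.99, "admit": 0.99},
    "off": {"none": 0.01, "exac": 0.25, "er": 0.30, "admit": 0.30},
}
_PERSISTENCE_PRESETS: dict[float, PersistenceTable] = {
    0.80: _BASE_PERSISTENCE,
    0.70: {
        "on": {"none": 0.95, "exac": 0.97, "er": 0.99, "admit": 0.99},
        "off": {"none": 0.01, "exac": 0.15, "er": 0.25, "admit": 0.25},
    },
    0.90: {
        "on": {"none": 0.965, "exac": 0.99, "er": 0.99, "admit": 0.99},
        "off": {"none": 0.01, "exac": 0.40, "er": 0.45, "admit": 0.45},
    },
}


def _event_table(name: str):
    def check(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != {"with_med", "without_med"}:
            raise ValueError(f"{name} must have keys with_med/without_med")
        for k, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}[{k}] = {p} outside [0, 1]")
        return v
    return check


class AsthmaParams(BaseModel):
    """Input parameters of the asthma medication model (monthly cycles)."""

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    med_use_rate: float = Field(default=0.80, ge=0, le=1)
    p_exac_no_er: dict[str, float] = Field(
        default_factory=lambda: {"with_med": 0.27, "without_med": 0.53})
    p_exac_er: dict[str, float] = Field(
        default_factory=lambda: {"with_med": 0.0382, "without_med": 0.0756})
    p_exac_admit: dict[str, float] = Field(
        default_factory=lambda: {"with_med": 0.0035, "without_med": 0.0069})
    persistence: PersistenceTable = Field(
        default_factory=lambda: {m: dict(v) for m, v in _BASE_PERSISTENCE.items()})
    #: per-scenario persistence presets (keyed by medication-use rate); rates
    #: without a preset are solved for (see persistence_for_rate)
    persistence_presets: dict[float, PersistenceTable] = Field(
        default_factory=lambda: {r: {m: dict(v) for m, v in t.items()}
                                 for r, t in _PERSISTENCE_PRESETS.items()})
    p_death_er: float = Field(default=0.0002, ge=0, le=1)
    p_death_admit: float = Field(default=0.0014, ge=0, le=1)
    p_death_other_monthly: float = Field(default=0.0001, ge=0, le=1)
    #: monthly utility by event category, with / without medication
    utilities_monthly: dict[str, dict[str, float]] = Field(
        default_factory=lambda: {
            "none": {"with_med": 0.0748, "without_med": 0.0756},
            "exac": {"with_med": 0.0706, "without_med": 0.0712},
            "er": {"with_med": 0.0698, "without_med": 0.0704},
            "admit": {"with_med": 0.0649, "without_med": 0.0654},
        })
    #: daily utilities the monthly values derive from (documentation and the
    #: month = 30/365-year scale identity; not consumed by the transition law)
    daily_utilities: dict[str, float] = Field(
        default_factory=lambda: {
            "normal_no_med": 0.92, "normal_med": 0.91, "exac_day": 0.72,
            "er_extra_decrement": 0.05, "admit_extra_decrement": 0.10,
            "med_disutility": 0.01,
        })
    days_available_per_month: dict[str, float] = Field(
        default_factory=lambda: {"adult": 21.67, "child": 15.0})
    days_missed: dict[str, float] = Field(
        default_factory=lambda: {"exac": 3.0, "er": 4.0, "admit": 7.0})
    costs: dict[str, float] = Field(
        default_factory=lambda: {"office_visit": 155.44, "er": 1080.0,
                                 "admission": 13512.0, "med_monthly": 112.0})
    horizon_months: int = Field(default=60, ge=1)
    parent_workday_ratio: float = Field(default=1.0, ge=0,
                                        description="parent work days lost per child school day lost")
    death_cycle_fraction: float = Field(default=0.5, ge=0, le=1)
    discount_rate: float = Field(default=0.0, ge=0)

    _v_exac = field_validator("p_exac_no_er")(classmethod(_event_table("p_exac_no_er")))
    _v_er = field_validator("p_exac_er")(classmethod(_event_table("p_exac_er")))
    _v_admit = field_validator("p_exac_admit")(classmethod(_event_table("p_exac_admit")))

    @field_validator("persistence")
    @classmethod
    def _v_persistence(cls, v: PersistenceTable) -> PersistenceTable:
        if set(v) != set(MED_STATUSES):
            raise ValueError("persistence must have keys on/off")
        for m, table in v.items():
            if set(table) != set(EVENTS):
                raise ValueError(f"persistence[{m}] must have keys {EVENTS}")
            for e, p in table.items():
                if not 0.0 <= p <= 1.0:
                    raise ValueError(f"persistence[{m}][{e}] = {p} outside [0, 1]")
        return v

    @field_validator("days_missed")
    @classmethod
    def _v_days(cls, v: dict[str, float]) -> dict[str, float]:
        for e, d in v.items():
            if d < 0:
                raise ValueError(f"days_missed[{e}] must be >= 0")
        return v

    def event_probabilities(self, med: str) -> dict[str, float]:
        """Monthly event-category distribution given medication status."""
        key = "with_med" if med == "on" else "without_med"
        p = {"exac": self.p_exac_no_er[key], "er": self.p_exac_er[key],
             "admit": self.p_exac_admit[key]}
        rest = 1.0 - sum(p.values())
        if rest < 0:
            raise ModelValidationError(
                f"event probabilities for {med!r} sum to more than 1")
        p["none"] = rest
        return p

    def utility(self, med: str, event: str) -> float:
        key = "with_med" if med == "on" else "without_med"
        return self.utilities_monthly[event][key]


def persistence_for_rate(params: AsthmaParams, rate: float) -> PersistenceTable:
    """Persistence table whose cohort fixed point tracks ``rate``.

    Published presets exist for 70/80/90%.  For other rates the table keeps
    the base with-medication persistence and rescales the restart
    probabilities after exacerbation-level events so the lumped two-state
    medication-use chain has its fixed point at ``rate``:
    ``r* = G / (G + 1 - S)`` with ``S`` the expected stay-on and ``G`` the
    expected restart probability under each status's event mix.
    """
    if not 0.0 <= rate <= 1.0:
        raise ModelValidationError(f"medication-use rate {rate} outside [0, 1]")
    if rate in (0.0, 1.0):
        # degenerate scenarios: no finite fixed-point rescaling exists; the
        # base persistence applies and the resulting drift is reported as-is
        return {m: dict(v) for m, v in params.persistence.items()}
    key = round(rate, 6)
    for preset_rate, table in params.persistence_presets.items():
        if abs(preset_rate - key) < 1e-9:
            return {m: dict(v) for m, v in table.items()}
    base = params.persistence
    ev_on = params.event_probabilities("on")
    ev_off = params.event_probabilities("off")
    stay = sum(ev_on[e] * base["on"][e] for e in EVENTS)
    g_target = rate * (1.0 - stay) / (1.0 - rate)
    g_none = ev_off["none"] * base["off"]["none"]
    g_rest = sum(ev_off[e] * base["off"][e] for e in EVENTS if e != "none")
    if g_rest <= 0:
        raise ModelValidationError("cannot rescale restart probabilities: all zero")
    k = (g_target - g_none) / g_rest
    table = {"on": dict(base["on"]),
             "off": {e: (base["off"][e] if e == "none" else base["off"][e] * k)
                     for e in EVENTS}}
    for e, p in table["off"].items():
        if not 0.0 <= p <= 1.0:
            raise ModelValidationError(
                f"no feasible persistence table for rate {rate}: restart[{e}] = {p:.4f}")
    return table


CHANNELS = ("utility", "days_attended", "days_missed", "cost_events",
            "cost_medication", "indirect_cost", "deaths")


def build_asthma_model(params: AsthmaParams,
                       population: str = "adult",
                       med_use_rate: float | None = None,
                       assumptions: EconomicAssumptions | None = None,
                       ) -> tuple[TransitionModel, RewardSchedule]:
    """Construct the monthly transition law and rewards for one scenario.

    In the first month medication status is the assigned initial status; from
    month two onward it follows the persistence law for the scenario rate.
    Event probabilities within a month depend only on that month's medication
    status.  For children, days are school days and the indirect cost applies
    ``parent_workday_ratio`` parent work days per school day lost.
    """
    if population not in ("adult", "child"):
        raise ModelValidationError(f"population must be adult or child, got {population!r}")
    a = assumptions or EconomicAssumptions()
    rate = params.med_use_rate if med_use_rate is None else med_use_rate
    persistence = persistence_for_rate(params, rate)
    T = params.horizon_months
    p_other = params.p_death_other_monthly
    death_by_event = {"none": 0.0, "exac": 0.0,
                      "er": params.p_death_er, "admit": params.p_death_admit}
    event_cost = {"none": 0.0, "exac": params.costs["office_visit"],
                  "er": params.costs["er"], "admit": params.costs["admission"]}
    med_cost = params.costs["med_monthly"]
    avail = params.days_available_per_month[population]
    day_factor = params.parent_workday_ratio if population == "child" else 1.0
    daily_wage = a.hours_per_day * a.hourly_wage
    ev = {m: params.event_probabilities(m) for m in MED_STATUSES}

    states = tuple(f"{m}_{e}" for m in MED_STATUSES for e in EVENTS) + ("dead",)

    def transition(t: int, state: str) -> dict[str, float]:
        if state == "dead":
            return {"dead": 1.0}
        med, event = state.split("_", 1)
        if t == 0:
            next_on = 1.0 if med == "on" else 0.0
        else:
            next_on = persistence[med][event]
        row: dict[str, float] = {"dead": p_other}
        alive = 1.0 - p_other
        for m_next, p_m in (("on", next_on), ("off", 1.0 - next_on)):
            if p_m == 0.0:
                continue
            for e_next, p_e in ev[m_next].items():
                flow = alive * p_m * p_e
                d = death_by_event[e_next]
                row["dead"] = row.get("dead", 0.0) + flow * d
                dest = f"{m_next}_{e_next}"
                row[dest] = row.get(dest, 0.0) + flow * (1.0 - d)
        return row

    def transition_rewards(t: int, src: str, dest: str) -> dict[str, float]:
        # the month of death still carries that month's event cost, missed
        # days and medication cost, as one-off rewards on the death flow
        if dest != "dead" or src == "dead":
            return {}
        med, event = src.split("_", 1)
        if t == 0:
            next_on = 1.0 if med == "on" else 0.0
        else:
            next_on = persistence[med][event]
        alive = 1.0 - p_other
        total = {"cost_events": 0.0, "cost_medication": 0.0,
                 "days_missed": 0.0, "indirect_cost": 0.0, "deaths": 0.0}
        death_flow = p_other
        for m_next, p_m in (("on", next_on), ("off", 1.0 - next_on)):
            for e_next in ("er", "admit"):
                flow = alive * p_m * ev[m_next][e_next] * death_by_event[e_next]
                death_flow += flow
                total["cost_events"] += flow * event_cost[e_next]
                if m_next == "on":
                    total["cost_medication"] += flow * med_cost
                missed = params.days_missed[e_next]
                total["days_missed"] += flow * missed
                total["indirect_cost"] += flow * missed * day_factor * daily_wage
        if death_flow <= 0:
            return {}
        out = {ch: v / death_flow for ch, v in total.items() if v != 0.0}
        out["deaths"] = 1.0
        return out

    def state_rewards(t: int, state: str) -> dict[str, float]:
        if state == "dead":
            return {}
        med, event = state.split("_", 1)
        missed = params.days_missed.get(event, 0.0)
        return {
            "utility": params.utility(med, event),
            "days_attended": avail - missed,
            "days_missed": missed,
            "cost_events": event_cost[event],
            "cost_medication": med_cost if med == "on" else 0.0,
            "indirect_cost": missed * day_factor * daily_wage,
        }

    model = TransitionModel(states=states, absorbing=frozenset({"dead"}),
                            transition=transition, n_cycles=T,
                            cycle_length_label="month")
    rewards = RewardSchedule(channels=CHANNELS, state_rewards=state_rewards,
                             transition_rewards=transition_rewards,
                             death_cycle_fraction=params.death_cycle_fraction,
                             utility_channel="utility")
    return model, rewards


def initial_distribution(rate: float) -> dict[str, float]:
    """Everyone starts alive, exacerbation-free, with med use at the scenario rate."""
    return {"on_none": rate, "off_none": 1.0 - rate}


@dataclass(frozen=True)
class AsthmaOutputs:
    """Per-person expectations over the model horizon."""

    med_use_rate: float
    population: str
    horizon_months: int
    qalys: float
    attended_days: float
    missed_days: float
    direct_cost_events: float
    direct_cost_medication: float
    direct_cost_total: float
    indirect_cost: float
    deaths: float
    trace: CohortTrace

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "med_use_rate", "horizon_months", "qalys", "attended_days",
            "missed_days", "direct_cost_events", "direct_cost_medication",
            "direct_cost_total", "indirect_cost", "deaths")}


def run_asthma_scenario(params: AsthmaParams,
                        med_use_rate: float,
                        horizon_months: int = 60,
                        population: str = "adult",
                        assumptions: EconomicAssumptions | None = None,
                        strict_horizon: bool = False) -> AsthmaOutputs:
    """Run one medication-use scenario and return per-person expectations.

    ``horizon_months`` is normally one of 12/24/36/48/60; other positive
    horizons are allowed unless ``strict_horizon`` is set.
    """
    if strict_horizon and horizon_months not in ALLOWED_HORIZONS:
        raise ModelValidationError(
            f"horizon_months {horizon_months} not in {ALLOWED_HORIZONS}")
    if horizon_months < 1:
        raise ModelValidationError("horizon_months must be >= 1")
    run_params = params.model_copy(update={"horizon_months": horizon_months})
    model, rewards = build_asthma_model(run_params, population=population,
                                        med_use_rate=med_use_rate,
                                        assumptions=assumptions)
    trace = run_cohort(model, rewards, initial_distribution(med_use_rate),
                       discount_rate=params.discount_rate)
    pp = trace.per_person
    return AsthmaOutputs(
        med_use_rate=med_use_rate, population=population,
        horizon_months=horizon_months, qalys=pp["utility"],
        attended_days=pp["days_attended"], missed_days=pp["days_missed"],
        direct_cost_events=pp["cost_events"],
        direct_cost_medication=pp["cost_medication"],
        direct_cost_total=pp["cost_events"] + pp["cost_medication"],
        indirect_cost=pp["indirect_cost"], deaths=pp["deaths"], trace=trace)


@dataclass(frozen=True)
class AsthmaDelta:
    """Scenario deltas (high medication-use rate minus low)."""

    low: AsthmaOutputs
    high: AsthmaOutputs

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self.high, k) - getattr(self.low, k)
                for k in self.low.as_dict() if k not in ("med_use_rate", "horizon_months")}

    @property
    def qalys(self) -> float:
        return self.high.qalys - self.low.qalys

    @property
    def attended_days(self) -> float:
        return self.high.attended_days - self.low.attended_days

    @property
    def direct_cost_events(self) -> float:
        return self.high.direct_cost_events - self.low.direct_cost_events

    @property
    def direct_cost_medication(self) -> float:
        return self.high.direct_cost_medication - self.low.direct_cost_medication

    @property
    def direct_cost_total(self) -> float:
        return self.high.direct_cost_total - self.low.direct_cost_total

    @property
    def indirect_cost(self) -> float:
        return self.high.indirect_cost - self.low.indirect_cost

    @property
    def missed_days(self) -> float:
        return self.high.missed_days - self.low.missed_days


def compare_med_use_scenarios(params: AsthmaParams,
                              low_rate: float, high_rate: float,
                              horizon_months: int = 60,
                              population: str = "adult",
                              assumptions: EconomicAssumptions | None = None,
                              ) -> AsthmaDelta:
    """Deltas per person between two medication-use scenarios (high - low).

    The direct-cost delta decomposes into event-cost savings
    (``direct_cost_events``) and added medication cost
    (``direct_cost_medication``).
    """
    if not low_rate <= high_rate:
        raise ModelValidationError("low_rate must not exceed high_rate")
    low = run_asthma_scenario(params, low_rate, horizon_months, population, assumptions)
    high = run_asthma_scenario(params, high_rate, horizon_months, population, assumptions)
    return AsthmaDelta(low=low, high=high)
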