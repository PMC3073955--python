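"""Five-year annual-cycle breast-cancer screening model.

Simulates a fixed cohort of employed African-American women aged 50-65 under
configurable two-year (HEDIS-style) mammography rates.  Women are assigned a
persistent screening pattern — annual, biennial, sporadic (one mammogram in
five years) or none — and may develop breast cancer each year.  The stage
distribution at diagnosis depends on whether a mammogram occurred that year
(the stage-shift mechanism through which screening acts); stage then drives
remission, recurrence, progression and cancer death, along with utilities,
employment probabilities, treatment costs and missed work days.

The model is a discrete-time Markov cohort model over states::

    well_<pattern> x 4   cancer-free, screening per pattern
    remission_I..IV      in remission after treatment, by stage at diagnosis
    progressive          progressive / recurrent disease
    dead                 absorbing

Diagnosis, initial treatment, and the year-of-diagnosis outcome (remission,
progression, or cancer death) all resolve within a single annual cycle;
year-of-diagnosis utilities, costs, employment and absenteeism are carried as
one-off transition rewards.  In-situ diagnoses are treated within the year
and return to the well state.  Absenteeism days are weighted by the
employment probability of the state in which they occur — the employer incurs
absence costs only for women still in the workforce; workforce exits are
costed separately through the turnover channel.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field, field_validator, model_validator

from .economics import EconomicAssumptions, annual_turnover_cost
from .engine import (CohortTrace, ModelValidationError, RewardSchedule,
                     TransitionModel, normalize_distribution, run_cohort)

__all__ = [
    "STAGES", "INVASIVE_STAGES", "PATTERNS",
    "StageDistribution", "ScreeningPatternMix", "MammographyParams",
    "MammographyOutputs", "MammographyDelta",
    "pattern_mix_for_hedis", "build_mammography_model",
    "run_mammography_scenario", "compare_hedis_scenarios",
    "MAMMOGRAPHY_VARIANTS",
]

STAGES = ("in_situ", "I", "II", "III", "IV")
INVASIVE_STAGES = ("I", "II", "III", "IV")
PATTERNS = ("annual", "biennial", "sporadic", "none")

#: model variants: base, stage-distribution sensitivity corners I-IV
#: (reconstructed from the published ranges), and the false-positive variants
MAMMOGRAPHY_VARIANTS = ("base", "I", "II", "III", "IV", "fp_cost", "fp_cost_rescreen")

# Corner stage-at-diagnosis distributions spanning the published sensitivity
# ranges for screened diagnoses (in situ .04-.21, I .32-.57, II .16-.43,
# III .04-.13, IV .02-.08).
PESSIMISTIC_SCREENED = {"in_situ": 0.04, "I": 0.32, "II": 0.43, "III": 0.13, "IV": 0.08}
OPTIMISTIC_SCREENED = {"in_situ": 0.21, "I": 0.57, "II": 0.16, "III": 0.04, "IV": 0.02}

# Sensitivity variants I-IV interpolate the screened stage distributions
# between the pessimistic and optimistic corners of the published ranges,
# so the sequence I -> IV is monotone from least to greatest screening benefit.
_VARIANT_WEIGHTS = {"I": 0.0, "II": 1.0 / 3.0, "III": 2.0 / 3.0, "IV": 1.0}


def variant_screened_distribution(weight: float) -> dict[str, float]:
    """Screened stage distribution at interpolation ``weight`` in [0, 1]."""
    return {s: (1.0 - weight) * PESSIMISTIC_SCREENED[s] + weight * OPTIMISTIC_SCREENED[s]
            for s in STAGES}


class StageDistribution(BaseModel):
    """A probability distribution over stage at diagnosis."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    probabilities: dict[str, float]
    provenance_label: str = ""

    @model_validator(mode="after")
    def _check(self) -> "StageDistribution":
        if set(self.probabilities) != set(STAGES):
            raise ValueError(f"stage distribution must have keys {STAGES}")
        for s, p in self.probabilities.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"stage {s}: probability {p} outside [0, 1]")
        total = sum(self.probabilities.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"stage distribution sums to {total:.12f}, not 1")
        return self

    def __getitem__(self, stage: str) -> float:
        return self.probabilities[stage]


class ScreeningPatternMix(BaseModel):
    """Proportions of women on each multi-year screening pattern.

    The two-year (HEDIS) mammography rate relates to the pattern proportions
    through ``annual + biennial + 0.4 * sporadic`` — a sporadic screener (one
    mammogram in five years) has probability 2/5 of falling inside the
    two-year window.  Published mixes are rounded to three decimals, so the
    identity is enforced to 3e-3.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    hedis_rate: float = Field(ge=0.0, le=1.0)
    annual: float = Field(ge=0.0, le=1.0)
    biennial: float = Field(ge=0.0, le=1.0)
    sporadic: float = Field(ge=0.0, le=1.0)
    none: float = Field(ge=0.0, le=1.0)

    @model_validator(mode="after")
    def _check(self) -> "ScreeningPatternMix":
        total = self.annual + self.biennial + self.sporadic + self.none
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"pattern proportions sum to {total:.12f}, not 1")
        err = self.hedis_identity_error()
        if err > 3e-3:
            raise ValueError(
                f"annual + biennial + 0.4*sporadic = {self.hedis_rate - err:.4f} "
                f"does not reproduce the HEDIS rate {self.hedis_rate}")
        return self

    def hedis_identity_error(self) -> float:
        return abs(self.annual + self.biennial + 0.4 * self.sporadic - self.hedis_rate)

    def proportion(self, pattern: str) -> float:
        return getattr(self, pattern)


#: published pattern mixes for the two headline HEDIS scenarios
_TABULATED_MIXES = {
    0.70: dict(annual=0.197, biennial=0.395, sporadic=0.270, none=0.138),
    0.80: dict(annual=0.242, biennial=0.483, sporadic=0.182, none=0.093),
}
#: sporadic:none ratio implied by the 70% mix, reused for other rates
_SPORADIC_TO_NONE = 0.270 / 0.138


def pattern_mix_for_hedis(hedis_rate: float) -> ScreeningPatternMix:
    """Screening-pattern mix consistent with a two-year mammography rate.

    For the tabulated rates 0.70 and 0.80 the published mixes are returned
    exactly.  For other rates the mix solves the constraint system
    {sum = 1; biennial = 2*annual; annual + biennial + 0.4*sporadic = rate;
    sporadic:none = 0.270:0.138}, reflecting the observation that twice as
    many screened women follow biennial as annual patterns.
    """
    if not 0.0 <= hedis_rate <= 1.0:
        raise ModelValidationError(f"hedis_rate {hedis_rate} outside [0, 1]")
    key = round(hedis_rate, 6)
    if key in _TABULATED_MIXES:
        return ScreeningPatternMix(hedis_rate=key, **_TABULATED_MIXES[key])
    rho = _SPORADIC_TO_NONE
    none = (1.0 - hedis_rate) / (1.0 + 0.6 * rho)
    sporadic = rho * none
    annual = (1.0 - none * (1.0 + rho)) / 3.0
    biennial = 2.0 * annual
    if annual < -1e-12:
        raise ModelValidationError(
            f"no feasible nonnegative pattern mix for HEDIS rate {hedis_rate}: "
            "binding constraint annual >= 0 (rate too low for the fixed "
            "sporadic:none ratio)")
    annual = max(annual, 0.0)
    return ScreeningPatternMix(hedis_rate=hedis_rate, annual=annual,
                               biennial=biennial, sporadic=sporadic, none=none)


def _prob_dict(name: str, keys: tuple[str, ...]):
    def check(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(keys):
            raise ValueError(f"{name} must have keys {keys}")
        for k, p in v.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}[{k}] = {p} outside [0, 1]")
        return v
    return check


class MammographyParams(BaseModel):
    """Every input parameter of the breast-cancer screening model.

    Defaults are the published base case for African-American women aged
    50-65; all fields can be overridden from a configuration file.  Stage
    distributions: screened annual/biennial diagnoses use the
    Jacobellis-Cutter distribution, screened sporadic diagnoses the Yood
    (managed-care) distribution, and diagnoses in unscreened years the
    clinical-detection distribution.
    """

    model_config = ConfigDict(extra="forbid", validate_assignment=True)

    # --- transition probabilities -------------------------------------------------
    annual_incidence_base: float = Field(default=0.003, ge=0, le=1)
    #: cancers found per woman-cycle: the annual/biennial/sporadic entries are
    #: per-mammogram detection probabilities applied in screened cycles; the
    #: "none" entry is the clinical-detection probability applied in *any*
    #: cycle without a mammogram, whatever the woman's pattern
    incidence_by_pattern: dict[str, float] = Field(
        default_factory=lambda: {"annual": 0.003, "biennial": 0.003,
                                 "sporadic": 0.005, "none": 0.008})
    stage_dist_screened: dict[str, StageDistribution] = Field(
        default_factory=lambda: {
            "annual": StageDistribution(
                probabilities={"in_situ": 0.13, "I": 0.41, "II": 0.37, "III": 0.07, "IV": 0.02},
                provenance_label="screened annual (Jacobellis-Cutter)"),
            "biennial": StageDistribution(
                probabilities={"in_situ": 0.13, "I": 0.41, "II": 0.37, "III": 0.07, "IV": 0.02},
                provenance_label="screened biennial (Jacobellis-Cutter)"),
            "sporadic": StageDistribution(
                probabilities={"in_situ": 0.17, "I": 0.29, "II": 0.40, "III": 0.09, "IV": 0.05},
                provenance_label="screened sporadic (Yood)"),
        })
    stage_dist_unscreened: StageDistribution = Field(
        default_factory=lambda: StageDistribution(
            probabilities={"in_situ": 0.04, "I": 0.32, "II": 0.43, "III": 0.13, "IV": 0.08},
            provenance_label="unscreened / clinical detection"))
    remission_in_diagnosis_year_by_stage: dict[str, float] = Field(
        default_factory=lambda: {"I": 0.975, "II": 0.94, "III": 0.81, "IV": 0.66})
    continued_remission_by_stage: dict[str, float] = Field(
        default_factory=lambda: {"I": 0.975, "II": 0.94, "III": 0.81, "IV": 0.66})
    #: per-stage annual cancer death rates imposed on the remission dynamics
    #: via the recurrence->death branch (see ``death_given_recurrence``)
    annual_cancer_death_rate_by_stage: dict[str, float] = Field(
        default_factory=lambda: {"I": 0.0075, "II": 0.03, "III": 0.126, "IV": 0.264})
    death_given_progression: float = Field(default=0.79, ge=0, le=1)
    other_cause_death_annual: float = Field(default=0.01, ge=0, le=1)

    # --- utilities ---------------------------------------------------------------
    utility_well: float = Field(default=1.0, ge=0, le=1)
    utility_newly_diagnosed_by_stage: dict[str, float] = Field(
        default_factory=lambda: {"I": 0.90, "II": 0.85, "III": 0.81, "IV": 0.81})
    treatment_disutility_by_stage: dict[str, float] = Field(
        default_factory=lambda: {"I": -0.10, "II": -0.20, "III": -0.25, "IV": -0.25})
    utility_progressive: float = Field(default=0.40, ge=0, le=1)

    # --- employment --------------------------------------------------------------
    employment_prob_well: float = Field(default=1.0, ge=0, le=1)
    employment_treatment_year_by_stage: dict[str, float] = Field(
        default_factory=lambda: {"in_situ": 0.86, "I": 0.70, "II": 0.60, "III": 0.50, "IV": 0.40})
    employment_remission_by_stage: dict[str, float] = Field(
        default_factory=lambda: {"I": 0.94, "II": 0.88, "III": 0.81, "IV": 0.75})
    employment_progressive: float = Field(default=0.56, ge=0, le=1)

    # --- costs -------------------------------------------------------------------
    treatment_cost_by_stage: dict[str, float] = Field(
        default_factory=lambda: {"I": 22488.0, "II": 27213.0, "III": 29220.0, "IV": 31476.0})
    cost_recurrent: float = Field(default=33000.0, ge=0)
    cost_in_situ_treatment: float = Field(default=0.0, ge=0)
    cost_mammogram: float = Field(default=81.86, ge=0)
    cost_false_positive_followup: float = Field(default=533.0, ge=0)
    false_positive_rate: float = Field(default=0.10, ge=0, le=1)
    false_positive_rescreen_boost: float = Field(default=0.10, ge=0)

    # --- absenteeism -------------------------------------------------------------
    days_missed_treatment_year_mean: float = Field(default=44.5, ge=0)
    # Per-stage treatment-year missed days; chosen so the expectation under
    # the base-case stage-at-diagnosis mix is ~44.5 days, rising with stage.
    days_missed_by_stage: dict[str, float] = Field(
        default_factory=lambda: {"in_situ": 11.0, "I": 34.0, "II": 46.0, "III": 69.0, "IV": 92.0})
    days_missed_progressive_year: float = Field(default=92.0, ge=0)

    # --- run controls ------------------------------------------------------------
    horizon_years: int = Field(default=5, ge=1)
    death_cycle_fraction: float = Field(default=0.5, ge=0, le=1)
    discount_rate: float = Field(default=0.0, ge=0)

    _v_inc = field_validator("incidence_by_pattern")(classmethod(_prob_dict("incidence_by_pattern", PATTERNS)))
    _v_rem = field_validator("remission_in_diagnosis_year_by_stage", "continued_remission_by_stage",
                             "annual_cancer_death_rate_by_stage", "utility_newly_diagnosed_by_stage",
                             "employment_remission_by_stage")(
        classmethod(_prob_dict("stage-probability table", INVASIVE_STAGES)))
    _v_etx = field_validator("employment_treatment_year_by_stage")(
        classmethod(_prob_dict("employment_treatment_year_by_stage", STAGES)))

    @field_validator("stage_dist_screened")
    @classmethod
    def _v_screened(cls, v: dict[str, StageDistribution]) -> dict[str, StageDistribution]:
        required = {"annual", "biennial", "sporadic"}
        if set(v) != required:
            raise ValueError(f"stage_dist_screened must have keys {sorted(required)}")
        return v

    @field_validator("treatment_cost_by_stage", "days_missed_by_stage")
    @classmethod
    def _v_nonneg(cls, v: dict[str, float]) -> dict[str, float]:
        for k, c in v.items():
            if c < 0:
                raise ValueError(f"cost/days for {k} must be >= 0, got {c}")
        return v

    def death_given_recurrence(self, stage: str) -> float:
        """Probability a recurrence in a cycle ends in cancer death that cycle.

        Derived so that the annual cancer death rate from remission states
        reproduces the published per-stage calibration exactly:
        ``rate_s = (1 - continued_remission_s) * death_given_recurrence_s``.
        The flat death-given-progression probability applies to the
        progressive-disease state instead.
        """
        c = self.continued_remission_by_stage[stage]
        if c >= 1.0:
            return 0.0
        return min(1.0, self.annual_cancer_death_rate_by_stage[stage] / (1.0 - c))

    @field_validator("treatment_disutility_by_stage")
    @classmethod
    def _v_disutil(cls, v: dict[str, float]) -> dict[str, float]:
        if set(v) != set(INVASIVE_STAGES):
            raise ValueError(f"treatment_disutility_by_stage must have keys {INVASIVE_STAGES}")
        for k, d in v.items():
            if not -1.0 <= d <= 0.0:
                raise ValueError(f"treatment disutility for stage {k} must lie in [-1, 0], got {d}")
        return v


CHANNELS = ("survival", "utility", "employment", "days_missed", "indirect_cost",
            "cost_screening", "cost_fp", "cost_treatment", "exits")


def _screening_schedule(params: MammographyParams, variant: str) -> dict[str, list[float]]:
    """Effective per-cycle mammography probability per pattern.

    Annual screens every cycle; biennial in cycles 1, 3, 5; sporadic women
    screen exactly once in five years, implemented as 1/5 of the sporadic
    group per cycle; none never screen.  Under the rescreen-boost variant a
    woman's per-cycle screening probability is raised by 10% (relative,
    capped at 1) once she has experienced a false-positive mammogram; the
    cohort implementation tracks the prior-false-positive fraction of each
    still-well pattern group.
    """
    T = params.horizon_years
    base = {
        "annual": [1.0] * T,
        "biennial": [1.0 if t % 2 == 0 else 0.0 for t in range(T)],
        "sporadic": [1.0 / 5.0] * T,
        "none": [0.0] * T,
    }
    if variant != "fp_cost_rescreen":
        return base
    boosted: dict[str, list[float]] = {}
    factor = 1.0 + params.false_positive_rescreen_boost
    for p in PATTERNS:
        q = params.incidence_by_pattern[p]
        f = 0.0  # fraction of the still-well group with a prior false positive
        eff = []
        for t in range(T):
            sp0 = base[p][t]
            sp = sp0 * (1.0 - f) + min(1.0, sp0 * factor) * f
            eff.append(sp)
            f = f + (1.0 - f) * sp * (1.0 - q) * params.false_positive_rate
        boosted[p] = eff
    return boosted


def _variant_distributions(params: MammographyParams, variant: str
                           ) -> tuple[dict[str, float], dict[str, float], dict[str, float]]:
    """(annual/biennial, sporadic, unscreened) stage distributions for a variant."""
    if variant in _VARIANT_WEIGHTS:
        ab = variant_screened_distribution(_VARIANT_WEIGHTS[variant])
        sp = dict(ab)
    else:
        ab = dict(params.stage_dist_screened["annual"].probabilities)
        sp = dict(params.stage_dist_screened["sporadic"].probabilities)
    return ab, sp, dict(params.stage_dist_unscreened.probabilities)


def build_mammography_model(params: MammographyParams,
                            mix: ScreeningPatternMix,
                            variant: str = "base",
                            assumptions: EconomicAssumptions | None = None,
                            ) -> tuple[TransitionModel, RewardSchedule]:
    """Construct the transition law and reward schedule for one scenario.

    ``variant``: ``base``; ``I``-``IV`` replace the screened stage
    distributions with sensitivity-range corner combinations (I most
    pessimistic, IV most optimistic); ``fp_cost`` adds false-positive
    follow-up costs; ``fp_cost_rescreen`` additionally boosts screening after
    a false positive.
    """
    if variant not in MAMMOGRAPHY_VARIANTS:
        raise ModelValidationError(
            f"unknown variant {variant!r}; expected one of {MAMMOGRAPHY_VARIANTS}")
    a = assumptions or EconomicAssumptions()
    fp_on = variant in ("fp_cost", "fp_cost_rescreen")
    dist_ab, dist_sp, dist_un = _variant_distributions(params, variant)
    schedule = _screening_schedule(params, variant)

    states = tuple(f"well_{p}" for p in PATTERNS) + \
        tuple(f"remission_{s}" for s in INVASIVE_STAGES) + ("progressive", "dead")
    T = params.horizon_years
    p_oc = params.other_cause_death_annual
    alive = 1.0 - p_oc
    d79 = params.death_given_progression
    daily = a.hours_per_day * a.hourly_wage
    d_prog = params.days_missed_progressive_year

    trans: dict[tuple[int, str], dict[str, float]] = {}
    trews: dict[tuple[int, str, str], dict[str, float]] = {}

    def add_reward(t: int, src: str, dest: str, ch: str, per_unit: float) -> None:
        if per_unit != 0.0:
            trews.setdefault((t, src, dest), defaultdict(float))[ch] += per_unit

    q_unscreened = params.incidence_by_pattern["none"]
    for p in PATTERNS:
        w = f"well_{p}"
        q_scr = params.incidence_by_pattern[p]
        screened = dist_ab if p in ("annual", "biennial") else dist_sp
        for t in range(T):
            sp = schedule[p][t]
            # cancers found this cycle: per-mammogram detection in screened
            # cycles, clinical detection in unscreened cycles, each with its
            # own stage-at-diagnosis distribution (the stage-shift mechanism)
            inc_s = alive * sp * q_scr
            inc_u = alive * (1.0 - sp) * q_unscreened
            stage_flow = {s: inc_s * screened[s] + inc_u * dist_un[s] for s in STAGES}
            q_total_flow = inc_s + inc_u
            flow_is = stage_flow["in_situ"]
            flow_ww = (alive - q_total_flow) + flow_is
            row: dict[str, float] = {w: flow_ww}
            # non-remission in the diagnosis year resolves within the cycle:
            # death with probability death_given_progression, else progressive
            prog_flow = 0.0
            dead_flow = p_oc
            prog_tot: dict[str, float] = defaultdict(float)
            dead_tot: dict[str, float] = defaultdict(float)
            for s in INVASIVE_STAGES:
                dx = stage_flow[s]
                r_s = params.remission_in_diagnosis_year_by_stage[s]
                row[f"remission_{s}"] = dx * r_s
                e_tx = params.employment_treatment_year_by_stage[s]
                # absenteeism accrues only while employed; workforce exits are
                # costed separately through the turnover channel
                eff_days = params.days_missed_by_stage[s] * e_tx
                one_off = {
                    "utility": params.treatment_disutility_by_stage[s],
                    "cost_treatment": params.treatment_cost_by_stage[s],
                    "days_missed": eff_days,
                    "indirect_cost": eff_days * daily,
                }
                if dx * r_s > 0:
                    dest = f"remission_{s}"
                    for ch, v in one_off.items():
                        add_reward(t, w, dest, ch, v)
                    add_reward(t, w, dest, "employment",
                               e_tx - params.employment_remission_by_stage[s])
                    add_reward(t, w, dest, "exits", 1.0 - e_tx)
                nonrem = dx * (1.0 - r_s)
                wgt_prog = nonrem * (1.0 - d79)
                wgt_dead = nonrem * d79
                prog_flow += wgt_prog
                dead_flow += wgt_dead
                if wgt_prog > 0:
                    for ch, v in one_off.items():
                        prog_tot[ch] += wgt_prog * v
                    prog_tot["employment"] += wgt_prog * (e_tx - params.employment_progressive)
                    prog_tot["exits"] += wgt_prog * (1.0 - e_tx)
                if wgt_dead > 0:
                    for ch, v in one_off.items():
                        dead_tot[ch] += wgt_dead * v
                    dead_tot["exits"] += wgt_dead * (1.0 - e_tx)
            row["dead"] = dead_flow
            if prog_flow > 0:
                row["progressive"] = prog_flow
                for ch, v in prog_tot.items():
                    add_reward(t, w, "progressive", ch, v / prog_flow)
            for ch, v in dead_tot.items():
                add_reward(t, w, "dead", ch, v / dead_flow)
            # mammogram cost rides on every surviving outflow of the well state
            if sp > 0:
                for dest in row:
                    if dest != "dead":
                        add_reward(t, w, dest, "cost_screening", sp * params.cost_mammogram)
            # false-positive follow-up (variants only): screened, cancer-free women
            if fp_on and sp > 0 and flow_ww > 0:
                total_fp = alive * sp * (1.0 - q_scr) * params.false_positive_rate \
                    * params.cost_false_positive_followup
                add_reward(t, w, w, "cost_fp", total_fp / flow_ww)
            # in-situ diagnoses share the well->well flow; expectation-weight their one-offs
            if flow_is > 0 and flow_ww > 0:
                share = flow_is / flow_ww
                e_is = params.employment_treatment_year_by_stage["in_situ"]
                eff_days_is = params.days_missed_by_stage["in_situ"] * e_is
                add_reward(t, w, w, "cost_treatment", share * params.cost_in_situ_treatment)
                add_reward(t, w, w, "days_missed", share * eff_days_is)
                add_reward(t, w, w, "indirect_cost", share * eff_days_is * daily)
                add_reward(t, w, w, "employment", share * (e_is - params.employment_prob_well))
                add_reward(t, w, w, "exits", share * (1.0 - e_is))
            trans[(t, w)] = row

    for s in INVASIVE_STAGES:
        st = f"remission_{s}"
        c_s = params.continued_remission_by_stage[s]
        rec = alive * (1.0 - c_s)
        d_s = params.death_given_recurrence(s)
        death_flow = p_oc + rec * d_s
        cancer_share = (rec * d_s) / death_flow if death_flow > 0 else 0.0
        row = {st: alive * c_s, "progressive": rec * (1.0 - d_s), "dead": death_flow}
        eff_days_prog = d_prog * params.employment_progressive
        for t in range(T):
            trans[(t, st)] = dict(row)
            add_reward(t, st, "dead", "cost_treatment", cancer_share * params.cost_recurrent)
            add_reward(t, st, "dead", "days_missed", cancer_share * eff_days_prog)
            add_reward(t, st, "dead", "indirect_cost", cancer_share * eff_days_prog * daily)
            add_reward(t, st, "dead", "exits",
                       cancer_share * (1.0 - params.employment_progressive))
            if rec * (1.0 - d_s) > 0:
                add_reward(t, st, "progressive", "exits", 1.0 - params.employment_progressive)

    death_flow = p_oc + alive * d79
    cancer_share = alive * d79 / death_flow
    eff_days_prog = d_prog * params.employment_progressive
    for t in range(T):
        trans[(t, "progressive")] = {"progressive": alive * (1.0 - d79), "dead": death_flow}
        add_reward(t, "progressive", "dead", "cost_treatment", cancer_share * params.cost_recurrent)
        add_reward(t, "progressive", "dead", "days_missed", cancer_share * eff_days_prog)
        add_reward(t, "progressive", "dead", "indirect_cost", cancer_share * eff_days_prog * daily)
        trans[(t, "dead")] = {"dead": 1.0}

    state_rewards: dict[str, dict[str, float]] = {}
    for p in PATTERNS:
        state_rewards[f"well_{p}"] = {
            "survival": 1.0, "utility": params.utility_well,
            "employment": params.employment_prob_well,
        }
    for s in INVASIVE_STAGES:
        state_rewards[f"remission_{s}"] = {
            "survival": 1.0,
            "utility": params.utility_newly_diagnosed_by_stage[s],
            "employment": params.employment_remission_by_stage[s],
        }
    eff_days_prog = d_prog * params.employment_progressive
    state_rewards["progressive"] = {
        "survival": 1.0, "utility": params.utility_progressive,
        "employment": params.employment_progressive,
        "days_missed": eff_days_prog, "indirect_cost": eff_days_prog * daily,
        "cost_treatment": params.cost_recurrent,
    }
    state_rewards["dead"] = {}

    trews_plain = {k: dict(v) for k, v in trews.items()}

    model = TransitionModel(
        states=states, absorbing=frozenset({"dead"}),
        transition=lambda t, s: trans[(t, s)],
        n_cycles=T, cycle_length_label="year")
    rewards = RewardSchedule(
        channels=CHANNELS,
        state_rewards=lambda t, s: state_rewards[s],
        transition_rewards=lambda t, s, d: trews_plain.get((t, s, d), {}),
        death_cycle_fraction=params.death_cycle_fraction,
        utility_channel="utility")
    return model, rewards


def initial_distribution(mix: ScreeningPatternMix) -> dict[str, float]:
    """All women start alive and cancer-free, split across pattern groups."""
    raw = {f"well_{p}": mix.proportion(p) for p in PATTERNS}
    values = normalize_distribution(raw, "screening pattern mix")
    return {k: float(v) for k, v in zip(raw, values)}


@dataclass(frozen=True)
class MammographyOutputs:
    """Per-person expectations over the model horizon (0-5 year scales)."""

    hedis_rate: float
    variant: str
    life_expectancy: float
    qalys: float
    employment_years: float
    missed_days: float
    missed_work_cost: float
    medical_cost: float
    cost_screening: float
    cost_false_positive: float
    cost_treatment: float
    workforce_exits: float
    turnover_cost: float
    trace: CohortTrace

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "hedis_rate", "life_expectancy", "qalys", "employment_years",
            "missed_days", "missed_work_cost", "medical_cost", "cost_screening",
            "cost_false_positive", "cost_treatment", "workforce_exits", "turnover_cost")}


def run_mammography_scenario(params: MammographyParams,
                             hedis_rate: float,
                             variant: str = "base",
                             assumptions: EconomicAssumptions | None = None,
                             ) -> MammographyOutputs:
    """Run one HEDIS-rate scenario and return per-person expectations."""
    a = assumptions or EconomicAssumptions()
    mix = pattern_mix_for_hedis(hedis_rate)
    model, rewards = build_mammography_model(params, mix, variant=variant, assumptions=a)
    trace = run_cohort(model, rewards, initial_distribution(mix),
                       discount_rate=params.discount_rate)
    pp = trace.per_person
    return MammographyOutputs(
        hedis_rate=hedis_rate, variant=variant,
        life_expectancy=pp["survival"], qalys=pp["utility"],
        employment_years=pp["employment"], missed_days=pp["days_missed"],
        missed_work_cost=pp["indirect_cost"],
        medical_cost=pp["cost_screening"] + pp["cost_fp"] + pp["cost_treatment"],
        cost_screening=pp["cost_screening"], cost_false_positive=pp["cost_fp"],
        cost_treatment=pp["cost_treatment"], workforce_exits=pp["exits"],
        turnover_cost=pp["exits"] * annual_turnover_cost(a, rounded=False),
        trace=trace)


@dataclass(frozen=True)
class MammographyDelta:
    """Channel-by-channel deltas: high-rate scenario minus low-rate scenario."""

    low: MammographyOutputs
    high: MammographyOutputs

    def __getattr__(self, name: str) -> float:
        low, high = object.__getattribute__(self, "low"), object.__getattribute__(self, "high")
        if hasattr(low, name) and name != "trace":
            return getattr(high, name) - getattr(low, name)
        raise AttributeError(name)

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self.high, k) - getattr(self.low, k)
                for k in self.low.as_dict() if k != "hedis_rate"}


def compare_hedis_scenarios(params: MammographyParams,
                            low_rate: float, high_rate: float,
                            variant: str = "base",
                            assumptions: EconomicAssumptions | None = None,
                            ) -> MammographyDelta:
    """Deltas of all outputs between two HEDIS-rate scenarios (high - low)."""
    if not low_rate <= high_rate:
        raise ModelValidationError("low_rate must not exceed high_rate")
    low = run_mammography_scenario(params, low_rate, variant, assumptions)
    high = run_mammography_scenario(params, high_rate, variant, assumptions)
    return MammographyDelta(low=low, high=high)
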