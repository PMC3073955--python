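"""Employer-facing economics: absenteeism, turnover, business-case rows.

Converts model-channel outputs (missed work days, workforce exits, medical
costs) into money from the employer perspective.  Sign convention throughout:
deltas are (improved scenario − baseline), so savings print as negative
numbers; helpers can flip the sign for prose-style "savings of $X" figures.

Full precision is retained internally; rounding is applied only when
formatting reports.
"""

from __future__ import annotations

from dataclasses import dataclass

from pydantic import BaseModel, ConfigDict, Field

__all__ = [
    "EconomicAssumptions",
    "BusinessCaseRow",
    "absenteeism_cost",
    "annual_turnover_cost",
    "business_case_row",
    "scale_to_population",
]


class EconomicAssumptions(BaseModel):
    """Wage and turnover assumptions shared by both clinical models.

    Defaults: average hourly wage $21.31 (US Department of Labor, May 2007),
    8-hour days, 2080-hour work years, and a replacement (turnover) cost of
    33% of the new hire's annual salary.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    hourly_wage: float = Field(default=21.31, gt=0, description="currency per hour")
    hours_per_day: float = Field(default=8.0, gt=0)
    hours_per_year: float = Field(default=2080.0, gt=0)
    turnover_fraction: float = Field(default=0.33, ge=0, le=1,
                                     description="fraction of annual salary to replace an employee")
    currency_rounding: int = Field(default=2, ge=0, description="decimal places in reports")

    @property
    def daily_wage(self) -> float:
        return self.hours_per_day * self.hourly_wage


def absenteeism_cost(days: float, assumptions: EconomicAssumptions | None = None) -> float:
    """Cost to the employer of ``days`` missed work days: days x hours/day x wage."""
    if days < 0:
        raise ValueError(f"days must be >= 0, got {days}")
    a = assumptions or EconomicAssumptions()
    return days * a.hours_per_day * a.hourly_wage


def annual_turnover_cost(assumptions: EconomicAssumptions | None = None,
                         rounded: bool = True) -> float:
    """Cost of replacing one employee: turnover fraction x wage x hours/year.

    With the default assumptions (0.33 x $21.31/h x 2080 h) this is $14,627
    when rounded to whole currency for reporting.
    """
    a = assumptions or EconomicAssumptions()
    cost = a.turnover_fraction * a.hourly_wage * a.hours_per_year
    return float(round(cost)) if rounded else cost


@dataclass(frozen=True)
class BusinessCaseRow:
    """One row of the cross-domain employer business-case comparison.

    ``total_delta = direct_delta + indirect_delta`` (within rounding).  For
    rows that also carry a with-turnover variant of the indirect cost, the
    optional ``*_with_turnover`` fields are populated and
    ``turnover_included`` is set.
    """

    label: str
    direct_delta: float
    days_delta: float
    indirect_delta: float
    total_delta: float
    indirect_delta_with_turnover: float | None = None
    total_delta_with_turnover: float | None = None

    @property
    def turnover_included(self) -> bool:
        return self.indirect_delta_with_turnover is not None

    def as_dict(self) -> dict[str, float | str | None]:
        return {
            "label": self.label,
            "direct_delta": self.direct_delta,
            "days_delta": self.days_delta,
            "indirect_delta": self.indirect_delta,
            "total_delta": self.total_delta,
            "indirect_delta_with_turnover": self.indirect_delta_with_turnover,
            "total_delta_with_turnover": self.total_delta_with_turnover,
        }


def business_case_row(label: str,
                      direct_delta: float,
                      days_delta: float,
                      indirect_delta: float,
                      indirect_delta_with_turnover: float | None = None) -> BusinessCaseRow:
    """Assemble a business-case row; the total is always computed, never entered."""
    total = direct_delta + indirect_delta
    total_wt = (direct_delta + indirect_delta_with_turnover
                if indirect_delta_with_turnover is not None else None)
    return BusinessCaseRow(label=label, direct_delta=direct_delta, days_delta=days_delta,
                           indirect_delta=indirect_delta, total_delta=total,
                           indirect_delta_with_turnover=indirect_delta_with_turnover,
                           total_delta_with_turnover=total_wt)


def scale_to_population(per_person_delta: float, n: float,
                        rounding: str = "none") -> float:
    """Scale a per-person delta to a population of ``n``.

    ``rounding``: ``"none"`` (full precision), ``"integer"`` (nearest whole
    unit — e.g. whole QALYs or life-years in a population projection), or
    ``"nearest_50"`` (round currency to the nearest $50 for headline figures).
    """
    if n < 0:
        raise ValueError("population size must be >= 0")
    value = per_person_delta * n
    if rounding == "none":
        return value
    if rounding == "integer":
        return float(round(value))
    if rounding == "nearest_50":
        return float(round(value / 50.0) * 50)
    raise ValueError(f"unknown rounding mode {rounding!r}")
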