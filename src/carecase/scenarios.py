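"""Named experiments: sensitivity tables, false-positive variants, and the
cross-domain employer business-case comparison.

These drive the package's three headline reports:

* the mammography output table (five outputs x {low rate, high rate, Diff}
  across the base model and stage-distribution sensitivity variants I-IV);
* the asthma medication-use sweep (QALYs, adult work days, child school days
  at 60/70/80/90% use);
* the business-case comparison table (per-person deltas in direct medical
  cost, days off work, indirect cost and total, for the mammography and
  asthma interventions).

Diff rows are always recomputed from the two scenario runs, never entered by
hand.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from . import __version__ as _version
from .asthma import AsthmaDelta, AsthmaParams, compare_med_use_scenarios, run_asthma_scenario
from .economics import (BusinessCaseRow, EconomicAssumptions, business_case_row)
from .engine import ModelValidationError
from .mammography import (MammographyDelta, MammographyParams, _VARIANT_WEIGHTS,
                          compare_hedis_scenarios, variant_screened_distribution)

__all__ = [
    "SensitivityVariant", "ComparisonReport",
    "run_stage_sensitivity", "run_false_positive_variant",
    "run_asthma_sweep", "build_comparison_table", "write_results_bundle",
]

#: the five mammography outputs reported per scenario, in table order
MAMMOGRAPHY_OUTPUT_FIELDS = (
    "life_expectancy", "qalys", "employment_years", "missed_work_cost", "medical_cost")


@dataclass(frozen=True)
class SensitivityVariant:
    """A stage-distribution sensitivity variant of the screening model.

    Variants I-IV interpolate the screened stage-at-diagnosis distributions
    between the pessimistic and optimistic corners of the published ranges
    (I = most pessimistic, IV = most optimistic); they are reconstructions —
    the original variant definitions were not published in full.
    """

    id: str
    weight: float | None = None  # None => base distributions

    @property
    def screened_distribution(self) -> dict[str, float] | None:
        if self.weight is None:
            return None
        return variant_screened_distribution(self.weight)

    @classmethod
    def named(cls, variant_id: str) -> "SensitivityVariant":
        if variant_id == "base":
            return cls(id="base", weight=None)
        if variant_id in _VARIANT_WEIGHTS:
            return cls(id=variant_id, weight=_VARIANT_WEIGHTS[variant_id])
        raise ModelValidationError(f"unknown sensitivity variant {variant_id!r}")


def run_stage_sensitivity(params: MammographyParams,
                          variants: Sequence[str] = ("base", "I", "II", "III", "IV"),
                          hedis_pair: tuple[float, float] = (0.70, 0.80),
                          assumptions: EconomicAssumptions | None = None,
                          ) -> pd.DataFrame:
    """Five outputs x {low, high, Diff} for each sensitivity variant.

    Returns a DataFrame indexed by (output, row) with one column per variant;
    ``row`` is the low rate, the high rate, or ``"Diff"`` (high - low,
    recomputed).
    """
    low_rate, high_rate = hedis_pair
    if not low_rate < high_rate:
        raise ModelValidationError("hedis_pair must be (low, high) with low < high")
    for v in variants:
        SensitivityVariant.named(v)  # validates ids up front
    rows: dict[str, dict[tuple[str, str], float]] = {}
    labels = (f"{low_rate:.0%}", f"{high_rate:.0%}", "Diff")
    for v in variants:
        delta = compare_hedis_scenarios(params, low_rate, high_rate, variant=v,
                                        assumptions=assumptions)
        col: dict[tuple[str, str], float] = {}
        for out in MAMMOGRAPHY_OUTPUT_FIELDS:
            col[(out, labels[0])] = getattr(delta.low, out)
            col[(out, labels[1])] = getattr(delta.high, out)
            col[(out, labels[2])] = getattr(delta.high, out) - getattr(delta.low, out)
        rows[v] = col
    index = pd.MultiIndex.from_product([MAMMOGRAPHY_OUTPUT_FIELDS, labels],
                                       names=["output", "scenario"])
    return pd.DataFrame({v: pd.Series(rows[v]) for v in variants}).reindex(index)


def run_false_positive_variant(params: MammographyParams,
                               include_rescreen_boost: bool = False,
                               hedis_pair: tuple[float, float] = (0.70, 0.80),
                               assumptions: EconomicAssumptions | None = None,
                               ) -> dict[str, float]:
    """Business-case totals with false-positive follow-up costs included.

    Each mammogram in a cancer-free woman triggers follow-up cost with the
    configured false-positive probability; the rescreen variant additionally
    raises subsequent screening probability after a false positive.  Returns
    the scenario medical-cost levels, the direct-cost saving (the headline
    comparison when false positives are counted), and the combined
    direct+indirect saving.
    """
    variant = "fp_cost_rescreen" if include_rescreen_boost else "fp_cost"
    delta = compare_hedis_scenarios(params, *hedis_pair, variant=variant,
                                    assumptions=assumptions)
    direct_diff = delta.medical_cost
    indirect_diff = delta.missed_work_cost
    return {
        "variant": variant,
        "medical_cost_low": delta.low.medical_cost,
        "medical_cost_high": delta.high.medical_cost,
        "false_positive_cost_low": delta.low.cost_false_positive,
        "false_positive_cost_high": delta.high.cost_false_positive,
        "direct_cost_diff": direct_diff,
        "direct_cost_saving": -direct_diff,
        "indirect_cost_diff": indirect_diff,
        "total_diff": direct_diff + indirect_diff,
        "total_saving": -(direct_diff + indirect_diff),
    }


def run_asthma_sweep(params: AsthmaParams,
                     rates: Sequence[float] = (0.60, 0.70, 0.80, 0.90),
                     horizon_months: int = 60,
                     assumptions: EconomicAssumptions | None = None,
                     ) -> pd.DataFrame:
    """Cumulative QALYs, adult work days and child school days by use rate."""
    cols = {}
    for r in rates:
        adult = run_asthma_scenario(params, r, horizon_months, "adult", assumptions)
        child = run_asthma_scenario(params, r, horizon_months, "child", assumptions)
        cols[f"{r:.0%}"] = {
            "cumulative_qalys": adult.qalys,
            "cumulative_work_days_adults": adult.attended_days,
            "cumulative_school_days_children": child.attended_days,
            "direct_cost_events_adults": adult.direct_cost_events,
            "direct_cost_medication_adults": adult.direct_cost_medication,
            "cumulative_deaths": adult.deaths,
        }
    return pd.DataFrame(cols)


@dataclass(frozen=True)
class ComparisonReport:
    """The cross-domain business-case table plus run metadata."""

    rows: tuple[BusinessCaseRow, ...]
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.as_dict() for r in self.rows]).set_index("label")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)

    def to_markdown(self) -> str:
        df = self.to_frame()
        return df.to_markdown(floatfmt=",.2f")


def build_comparison_table(mammography_delta: MammographyDelta,
                           asthma_delta_10: AsthmaDelta,
                           asthma_delta_20: AsthmaDelta,
                           assumptions: EconomicAssumptions | None = None,
                           ) -> ComparisonReport:
    """Assemble the three-row employer business-case comparison.

    Deltas are (improved scenario - baseline): savings are negative.  The
    mammography row carries both the no-turnover and with-turnover indirect
    cost; the asthma rows follow the published convention of reporting
    exacerbation-related cost savings in the direct column (the offsetting
    medication cost appears in the metadata as the net direct saving).
    """
    a = assumptions or EconomicAssumptions()
    for name, row in (("mammography", mammography_delta),
                      ("asthma 10%", asthma_delta_10),
                      ("asthma 20%", asthma_delta_20)):
        if row is None:
            raise ModelValidationError(f"missing input row: {name}")
    m = mammography_delta
    mam_row = business_case_row(
        label=(f"mammography {m.low.hedis_rate:.0%} -> {m.high.hedis_rate:.0%}"),
        direct_delta=m.medical_cost,
        days_delta=m.missed_days,
        indirect_delta=m.missed_work_cost,
        indirect_delta_with_turnover=m.missed_work_cost + m.turnover_cost)
    rows = [mam_row]
    for d in (asthma_delta_10, asthma_delta_20):
        rows.append(business_case_row(
            label=(f"asthma medications {d.low.med_use_rate:.0%} -> "
                   f"{d.high.med_use_rate:.0%} ({d.low.population}s)"),
            direct_delta=d.direct_cost_events,
            days_delta=d.missed_days,
            indirect_delta=d.indirect_cost))
    metadata = {
        "package_version": _version,
        "assumptions": a.model_dump(),
        "asthma_net_direct_delta_10": asthma_delta_10.direct_cost_total,
        "asthma_net_direct_delta_20": asthma_delta_20.direct_cost_total,
        "mammography_variant": m.low.variant,
        "horizons": {"mammography_years": 5,
                     "asthma_months": asthma_delta_10.low.horizon_months},
    }
    return ComparisonReport(rows=tuple(rows), metadata=metadata)


def write_results_bundle(path, tables: Mapping[str, pd.DataFrame | dict],
                         metadata: Mapping | None = None) -> None:
    """Write a JSON results bundle with full-precision values and metadata."""
    payload: dict = {"package_version": _version, "metadata": dict(metadata or {})}
    for name, obj in tables.items():
        if isinstance(obj, pd.DataFrame):
            df = obj.copy()
            if isinstance(df.index, pd.MultiIndex):
                df.index = [" / ".join(map(str, ix)) for ix in df.index]
            payload[name] = json.loads(df.to_json(orient="index"))
        else:
            payload[name] = obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
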