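"""ICERs with dominance handling, subgroup aggregation and scenario grids.

The incremental comparison is always "increase the catheterization rate"
(cath arm) versus "maintain the current rate" (no-cath arm), expressed per
additional catheterization performed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from . import assemble
from .assemble import (ACS_SPECIFIC_RATIOS, NONACS_SPECIFIC_RATIOS,
                       MortalityLibrary, ParameterSet, build_parameter_set,
                       family_results, marginal_aggregate)
from .tables import ParameterTables

DAYS_PER_YEAR = 365

#: Scenario families reported side by side in the sensitivity grid.
FAMILIES = {
    "acs_yusuf": (True, "yusuf"),
    "acs_frisc2": (True, "frisc2"),
    "nonacs": (False, "yusuf"),
}


@dataclass(frozen=True)
class CEResult:
    """Incremental cost-effectiveness of one comparison."""

    label: str
    delta_cost: float
    delta_qaly: float
    status: str          # "icer" | "dominated" | "dominant"
    icer: float          # CAD per QALY; nan unless status == "icer"

    @property
    def healthy_days(self) -> int:
        """Healthy-day equivalent of the QALY gain (365 days/year)."""
        return round(self.delta_qaly * DAYS_PER_YEAR)


def icer(cath: tuple[float, float], nocath: tuple[float, float],
         label: str = "") -> CEResult:
    """Classify and (where defined) compute the ICER between two arms.

    ``cath`` and ``nocath`` are (total cost, total QALY) pairs.  Dominated:
    costs more, no more effective; dominant: costs no more, at least as
    effective; otherwise the ratio ΔC/ΔE.
    """
    dc = float(cath[0]) - float(nocath[0])
    de = float(cath[1]) - float(nocath[1])
    if not (math.isfinite(dc) and math.isfinite(de)):
        raise ValueError("non-finite incremental totals")
    return from_deltas(dc, de, label)


def from_deltas(dc: float, de: float, label: str = "") -> CEResult:
    both_zero = dc == 0.0 and de == 0.0
    if not both_zero and dc >= 0.0 and de <= 0.0:
        return CEResult(label, dc, de, "dominated", float("nan"))
    if not both_zero and dc <= 0.0 and de >= 0.0:
        return CEResult(label, dc, de, "dominant", float("nan"))
    ratio = dc / de if de != 0.0 else float("nan")
    return CEResult(label, dc, de, "icer", ratio)


def aggregate_overall(results: dict, weights: dict,
                      label: str = "overall") -> CEResult:
    """Weighted average of subgroup (ΔC, ΔE) pairs, then the ICER of the
    aggregate.  ``results`` values may be CEResult or (ΔC, ΔE) tuples."""
    if set(results) != set(weights):
        raise ValueError(f"label sets differ: {sorted(results)} vs "
                         f"{sorted(weights)}")
    if any(w < 0 for w in weights.values()) or sum(weights.values()) <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    total = sum(weights.values())
    dc = de = 0.0
    for key, value in results.items():
        if isinstance(value, CEResult):
            value = (value.delta_cost, value.delta_qaly)
        dc += weights[key] * value[0]
        de += weights[key] * value[1]
    return from_deltas(dc / total, de / total, label)


# ---------------------------------------------------------------------------
# deterministic scenario grid

@dataclass(frozen=True)
class ScenarioSpec:
    """One row of the sensitivity grid: named parameter overrides, the
    families it applies to, and an optional subgroup restriction for the
    reported aggregate (e.g. the male-yield rows report the male ICER)."""

    name: str
    overrides: dict = field(default_factory=dict)
    families: tuple = tuple(FAMILIES)
    report_sex: str | None = None


def apply_scenario(params: ParameterSet, overrides: dict) -> ParameterSet:
    """Return a copy of ``params`` with the scenario overrides applied."""
    p = params.copy()
    known = {"high_risk_ratio", "rr_multiplier", "extend_rr_to", "use_saq",
             "proc_cost_factor", "annual_cost_factor", "discount_rate",
             "utility_duration_years", "normal_fraction"}
    unknown = set(overrides) - known
    if unknown:
        raise ValueError(f"unknown scenario overrides: {sorted(unknown)}")
    if "high_risk_ratio" in overrides:
        p.high_risk_ratio.update(overrides["high_risk_ratio"])
    if "extend_rr_to" in overrides:
        p.rr_schedules = {a: s.extended_first_window(
            overrides["extend_rr_to"]) for a, s in p.rr_schedules.items()}
    if "rr_multiplier" in overrides:
        p.rr_schedules = {a: s.multiplied(overrides["rr_multiplier"])
                          for a, s in p.rr_schedules.items()}
    if "use_saq" in overrides:
        p.use_saq = bool(overrides["use_saq"])
    if "proc_cost_factor" in overrides:
        f = overrides["proc_cost_factor"]
        p.proc_costs = {k: v * f for k, v in p.proc_costs.items()}
    if "annual_cost_factor" in overrides:
        f = overrides["annual_cost_factor"]
        p.annual_costs = {k: v * f for k, v in p.annual_costs.items()}
    if "discount_rate" in overrides:
        p.discount_rate = overrides["discount_rate"]
    if "normal_fraction" in overrides:
        p.normal_fraction = overrides["normal_fraction"]
    if "utility_duration_years" in overrides:
        p.utility_duration_years = overrides["utility_duration_years"]
    return p


def default_scenarios() -> list[ScenarioSpec]:
    """The deterministic sensitivity grid: indication-specific yields,
    sex-specific yield ranges, RR +/-25%, the 10-year constant-benefit
    variant, SAQ utilities, procedure/care cost factors and alternative
    discount rates."""
    acs_only = ("acs_yusuf", "acs_frisc2")
    return [
        ScenarioSpec("base"),
        ScenarioSpec("acs_specific_yield",
                     {"high_risk_ratio": ACS_SPECIFIC_RATIOS},
                     families=acs_only),
        ScenarioSpec("nonacs_specific_yield",
                     {"high_risk_ratio": NONACS_SPECIFIC_RATIOS},
                     families=("nonacs",)),
        ScenarioSpec("male_yield_4to1", {"high_risk_ratio": {"male": 4.0}},
                     report_sex="male"),
        ScenarioSpec("male_yield_2to1", {"high_risk_ratio": {"male": 2.0}},
                     report_sex="male"),
        ScenarioSpec("female_yield_7to1",
                     {"high_risk_ratio": {"female": 7.0}},
                     report_sex="female"),
        ScenarioSpec("female_yield_3to1",
                     {"high_risk_ratio": {"female": 3.0}},
                     report_sex="female"),
        ScenarioSpec("rr_increase_25pct", {"rr_multiplier": 1.25}),
        ScenarioSpec("rr_decrease_25pct", {"rr_multiplier": 0.75}),
        ScenarioSpec("rr_constant_10yr", {"extend_rr_to": 10.0}),
        ScenarioSpec("saq_utilities", {"use_saq": True}),
        ScenarioSpec("proc_cost_up_50pct", {"proc_cost_factor": 1.5}),
        ScenarioSpec("proc_cost_down_25pct", {"proc_cost_factor": 0.75}),
        ScenarioSpec("care_cost_up_50pct", {"annual_cost_factor": 1.5}),
        ScenarioSpec("care_cost_down_25pct", {"annual_cost_factor": 0.75}),
        ScenarioSpec("no_discounting", {"discount_rate": 0.0}),
        ScenarioSpec("discount_3pct", {"discount_rate": 0.03}),
        ScenarioSpec("discount_6pct", {"discount_rate": 0.06}),
    ]


def run_scenarios(tables: ParameterTables, library: MortalityLibrary,
                  specs: list[ScenarioSpec] | None = None,
                  base_options: dict | None = None) -> pd.DataFrame:
    """Evaluate the scenario grid for every family; one row per
    (scenario, family) with the reported aggregate and its ICER."""
    specs = specs if specs is not None else default_scenarios()
    base_options = base_options or {}
    base = {fam: build_parameter_set(tables, rr_scenario=rr, **base_options)
            for fam, (_, rr) in FAMILIES.items()}
    rows = []
    for spec in specs:
        for fam in spec.families:
            acs, _ = FAMILIES[fam]
            try:
                params = apply_scenario(base[fam], spec.overrides)
                res = family_results(params, library, acs)
                if spec.report_sex is None:
                    dc, de = res["aggregate"]
                else:
                    dc, de = marginal_aggregate(
                        res["cells"], params.subgroup_weights,
                        lambda k: k[0] == spec.report_sex)
            except Exception as exc:
                raise RuntimeError(
                    f"scenario {spec.name!r} failed for family "
                    f"{fam!r}") from exc
            ce = from_deltas(dc, de, f"{spec.name}/{fam}")
            rows.append({"scenario": spec.name, "family": fam,
                         "report_sex": spec.report_sex or "all",
                         "delta_cost": ce.delta_cost,
                         "delta_qaly": ce.delta_qaly,
                         "status": ce.status, "icer": ce.icer})
    return pd.DataFrame(rows)


def base_case_table(tables: ParameterTables, library: MortalityLibrary,
                    base_options: dict | None = None) -> pd.DataFrame:
    """Base-case ΔC/ΔE/ICER by family with sex and age-band sub-aggregates,
    plus the overall row mixing ACS and non-ACS by the configured share."""
    base_options = base_options or {}
    rows = []
    family_aggs = {}
    for fam, (acs, rr) in FAMILIES.items():
        params = build_parameter_set(tables, rr_scenario=rr, **base_options)
        res = family_results(params, library, acs)
        family_aggs[fam] = res["aggregate"]
        ce = from_deltas(*res["aggregate"], fam)
        rows.append({"strategy": fam, "subgroup": "all",
                     "delta_cost": ce.delta_cost,
                     "delta_qaly": ce.delta_qaly, "status": ce.status,
                     "icer": ce.icer})
        w = params.subgroup_weights
        for label, pred in (
                [(sex, (lambda k, s=sex: k[0] == s)) for sex in ("male",
                                                                 "female")]
                + [(band, (lambda k, b=band: k[1] == b))
                   for band in ("lt65", "65_75", "gt75")]):
            dc, de = marginal_aggregate(res["cells"], w, pred)
            ce = from_deltas(dc, de, f"{fam}/{label}")
            rows.append({"strategy": fam, "subgroup": label,
                         "delta_cost": ce.delta_cost,
                         "delta_qaly": ce.delta_qaly, "status": ce.status,
                         "icer": ce.icer})
        if fam == "acs_yusuf":
            acs_share = params.acs_fraction
    overall = aggregate_overall(
        {"acs": family_aggs["acs_yusuf"], "nonacs": family_aggs["nonacs"]},
        {"acs": acs_share, "nonacs": 1.0 - acs_share})
    rows.insert(0, {"strategy": "overall", "subgroup": "all",
                    "delta_cost": overall.delta_cost,
                    "delta_qaly": overall.delta_qaly,
                    "status": overall.status, "icer": overall.icer})
    return pd.DataFrame(rows)
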