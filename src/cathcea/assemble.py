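"""Assembly of model inputs from parameter tables and registry survival.

``ParameterSet`` holds every tunable scenario-level parameter (yield ratios,
relative risks, utilities, costs, discounting); ``MortalityLibrary`` holds
the registry-derived annual mortality curves extended to the lifetime
horizon.  ``subgroup_inputs`` combines the two into the
:class:`~cathcea.markov_engine.ModelInputs` for one stratification cell, and
``family_results`` runs a whole scenario family (ACS-Yusuf, ACS-FRISC-II or
non-ACS) across its sex/age cells.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import tables as _tables
from .keys import (AGE_BANDS, DISEASE_ANATOMIES, HIGH_RISK_ANATOMIES, SEXES,
                   START_AGES, Subgroup)
from .markov_engine import ModelInputs, incremental
from .survival_model import (AnnualMortality, LifeTable, annual_probs,
                             extrapolate, km_estimate,
                             medical_management_mortality,
                             population_mortality, schedule_from_table3)
from .yield_model import (AnatomyMix, lm_split_from_prevalence,
                          marginal_anatomy_mix)

#: Base-case catheterizations per high-risk case detected, by sex.
BASE_HIGH_RISK_RATIOS = {"male": 3.0, "female": 5.0}
#: Indication-specific yield ratios explored in sensitivity analysis.
ACS_SPECIFIC_RATIOS = {"male": 2.6, "female": 3.4}
NONACS_SPECIFIC_RATIOS = {"male": 2.5, "female": 5.0}

#: Normal-coronary share of the non-high-risk remainder of the marginal
#: catheterization (not published; explicit model parameter).
DEFAULT_NORMAL_FRACTION = 0.15

HORIZON_AGE = 100


@dataclass
class ParameterSet:
    """Scenario-level parameters; the object the PSA perturbs."""

    rr_scenario: str                      # "yusuf" | "frisc2"
    rr_schedules: dict                    # anatomy -> RelativeRiskSchedule
    high_risk_ratio: dict                 # sex -> catheterizations per case
    lm_split: dict                        # (sex, band) -> left-main share
    normal_fraction: float
    utilities: dict                       # (sex, band, anatomy, mgmt) -> u
    utility_se: dict                      # same keys -> SE (SD/sqrt(n))
    undetected_decrement: float
    use_saq: bool
    saq_utilities: dict                   # anatomy -> (rev, med)
    annual_costs: dict                    # (anatomy, tx, band, year) -> CAD
    proc_costs: dict                      # cath/cabg/pci -> CAD
    p_cath_death: dict                    # (sex, band) -> probability
    p_revasc: dict                        # (sex, band, anatomy) -> prob
    cabg_share: dict                      # (sex, band, anatomy) -> share
    discount_rate: float
    acs_fraction: float
    subgroup_weights: dict                # (sex, band) -> count
    start_ages: dict = field(default_factory=lambda: dict(START_AGES))
    half_cycle: bool = False
    utility_duration_years: int | None = None

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)


def build_parameter_set(tables: _tables.ParameterTables,
                        rr_scenario: str = "yusuf",
                        high_risk_ratio: dict | None = None,
                        normal_fraction: float = DEFAULT_NORMAL_FRACTION,
                        discount_rate: float = _tables.DISCOUNT_RATE,
                        acs_fraction: float = 0.5,
                        use_saq: bool = False) -> ParameterSet:
    """Base-case parameter set from the published tables."""
    t1, t2, t3 = tables.table1, tables.table2, tables.table3
    schedules = {a: schedule_from_table3(t3, rr_scenario, a)
                 for a in DISEASE_ANATOMIES}
    utilities, utility_se = {}, {}
    p_cath, p_rev, cabg = {}, {}, {}
    lm_split = {}
    for _, row in t1.iterrows():
        key = (row["sex"], row["age_band"])
        p_cath[key] = row["p_cath_death_pct"] / 100.0
        p_rev[key + (row["anatomy"],)] = row["p_revasc_pct"] / 100.0
        cabg[key + (row["anatomy"],)] = row["p_cabg_pct"] / 100.0
        se_n = max(float(row["n_utility"]), 1.0)
        for mgmt, mean_col, sd_col in (
                ("revascularized", "u_revasc_mean", "u_revasc_sd"),
                ("medical", "u_medical_mean", "u_medical_sd")):
            utilities[key + (row["anatomy"], mgmt)] = float(row[mean_col])
            utility_se[key + (row["anatomy"], mgmt)] = \
                float(row[sd_col]) / np.sqrt(se_n)
    for sex in SEXES:
        for band in AGE_BANDS:
            lm_split[(sex, band)] = lm_split_from_prevalence(t1, sex, band)
    annual_costs = {
        (r.anatomy, r.treatment, r.age_band, int(r.year)): float(r.mean)
        for r in t2.itertuples()}
    return ParameterSet(
        rr_scenario=rr_scenario,
        rr_schedules=schedules,
        high_risk_ratio=dict(high_risk_ratio or BASE_HIGH_RISK_RATIOS),
        lm_split=lm_split,
        normal_fraction=normal_fraction,
        utilities=utilities,
        utility_se=utility_se,
        undetected_decrement=_tables.UNDETECTED_UTILITY_DECREMENT,
        use_saq=use_saq,
        saq_utilities=dict(_tables.SAQ_UTILITIES),
        annual_costs=annual_costs,
        proc_costs=dict(_tables.PROCEDURE_COSTS),
        p_cath_death=p_cath,
        p_revasc=p_rev,
        cabg_share=cabg,
        discount_rate=discount_rate,
        acs_fraction=acs_fraction,
        subgroup_weights=_tables.subgroup_counts(t1),
    )


@dataclass
class MortalityLibrary:
    """Registry mortality curves extended to the lifetime horizon.

    ``curves`` maps (acs, sex, band, anatomy, management) to an
    :class:`AnnualMortality` running from cycle 1 to age ``horizon_age``;
    ``population`` maps (sex, band) likewise.
    """

    curves: dict
    population: dict
    life_table: LifeTable
    start_ages: dict
    horizon_age: int = HORIZON_AGE

    def horizon(self, band: str) -> int:
        return self.horizon_age - self.start_ages[band]


def build_mortality_library(patients: pd.DataFrame,
                            life_table: LifeTable | pd.DataFrame,
                            start_ages: dict | None = None,
                            horizon_age: int = HORIZON_AGE,
                            observed_years: int = 10) -> MortalityLibrary:
    """Kaplan-Meier per cell, discretized and life-table extrapolated."""
    if isinstance(life_table, pd.DataFrame):
        life_table = LifeTable(life_table)
    start_ages = dict(start_ages or START_AGES)
    curves, population = {}, {}
    for sex in SEXES:
        for band in AGE_BANDS:
            start = start_ages[band]
            horizon = horizon_age - start
            population[(sex, band)] = population_mortality(
                life_table, start, sex, horizon)
            for acs in (False, True):
                for anatomy in DISEASE_ANATOMIES:
                    for mgmt in ("revascularized", "medical"):
                        cell = {"acs": acs, "sex": sex, "age_band": band,
                                "anatomy": anatomy, "management": mgmt}
                        km = km_estimate(patients, cell,
                                         years=observed_years)
                        mort = annual_probs(km)
                        mort = extrapolate(mort, life_table, start, sex,
                                           horizon,
                                           observed_years=observed_years)
                        curves[(acs, sex, band, anatomy, mgmt)] = mort
    return MortalityLibrary(curves, population, life_table, start_ages,
                            horizon_age)


def anatomy_mix_for(params: ParameterSet, sex: str,
                    age_band: str) -> AnatomyMix:
    return marginal_anatomy_mix(params.high_risk_ratio[sex],
                                params.lm_split[(sex, age_band)],
                                params.normal_fraction)


def subgroup_inputs(params: ParameterSet, library: MortalityLibrary,
                    acs: bool, sex: str, age_band: str) -> ModelInputs:
    """Assemble :class:`ModelInputs` for one stratification cell."""
    horizon = library.horizon(age_band)
    u_rev, u_med, u_undet = {}, {}, {}
    for a in DISEASE_ANATOMIES:
        if params.use_saq:
            u_rev[a], u_med[a] = params.saq_utilities[a]
            u_undet[a] = (u_med[a] if a in HIGH_RISK_ANATOMIES else u_rev[a])
        else:
            u_rev[a] = params.utilities[(sex, age_band, a, "revascularized")]
            u_med[a] = params.utilities[(sex, age_band, a, "medical")]
            u_undet[a] = (max(u_rev[a] - params.undetected_decrement, 0.0)
                          if a in HIGH_RISK_ANATOMIES else u_rev[a])
    q_rev, q_med, q_cf = {}, {}, {}
    for a in DISEASE_ANATOMIES:
        q_rev[a] = library.curves[(acs, sex, age_band, a, "revascularized")]
        q_med[a] = library.curves[(acs, sex, age_band, a, "medical")]
        q_cf[a] = medical_management_mortality(q_rev[a],
                                               params.rr_schedules[a])
    return ModelInputs(
        mix=anatomy_mix_for(params, sex, age_band),
        p_cath_death=params.p_cath_death[(sex, age_band)],
        p_revasc={a: params.p_revasc[(sex, age_band, a)]
                  for a in DISEASE_ANATOMIES},
        cabg_share={a: params.cabg_share[(sex, age_band, a)]
                    for a in DISEASE_ANATOMIES},
        proc_costs=dict(params.proc_costs),
        annual_costs={(a, tx, y): params.annual_costs[(a, tx, age_band, y)]
                      for a in DISEASE_ANATOMIES
                      for tx in ("cabg", "pci", "medical")
                      for y in (1, 2, 3)},
        u_rev=u_rev, u_med=u_med, u_undetected=u_undet,
        u_normal=0.85,
        q_rev=q_rev, q_med_observed=q_med, q_med_counterfactual=q_cf,
        q_population=library.population[(sex, age_band)],
        discount_rate=params.discount_rate,
        horizon=horizon,
        half_cycle=params.half_cycle,
        utility_duration_years=params.utility_duration_years,
        label=Subgroup(acs, sex, age_band).label(),
    )


def family_results(params: ParameterSet, library: MortalityLibrary,
                   acs: bool) -> dict:
    """Incremental (cost, QALY) per (sex, age band) cell of one scenario
    family, plus the family aggregate under the cohort-count weights."""
    cells = {}
    for sex in SEXES:
        for band in AGE_BANDS:
            inputs = subgroup_inputs(params, library, acs, sex, band)
            res = incremental(inputs)
            cells[(sex, band)] = (res["delta_cost"], res["delta_qaly"])
    weights = params.subgroup_weights
    total_w = sum(weights.values())
    dc = sum(weights[k] * cells[k][0] for k in cells) / total_w
    de = sum(weights[k] * cells[k][1] for k in cells) / total_w
    return {"cells": cells, "aggregate": (dc, de)}


def marginal_aggregate(cells: dict, weights: dict,
                       select) -> tuple[float, float]:
    """Weighted (cost, QALY) aggregate over the cells picked by ``select``
    (a predicate on the (sex, band) key)."""
    keys = [k for k in cells if select(k)]
    w = sum(weights[k] for k in keys)
    dc = sum(weights[k] * cells[k][0] for k in keys) / w
    de = sum(weights[k] * cells[k][1] for k in keys) / w
    return dc, de
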