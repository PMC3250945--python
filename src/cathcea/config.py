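"""Synthetic-registry configuration.

The generator emulates a provincial catheterization registry: patient-level
survival by indication/sex/age/anatomy/treatment, regional catheterization
and detection rates, EQ-5D survey records, annual cost records and a
Gompertz national life table.  Published registry survival exists only as
curves, so the generating hazards are explicit, documented free parameters:
the defaults below are piecewise-exponential annual hazards chosen so that
revascularized left-main/3-vessel patients have better 10-year survival than
medically managed ones (the qualitative ordering seen in such registries)
while 1-2-vessel survival is nearly treatment-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import tables as _tables
from .keys import (AGE_BANDS, ANATOMIES, DISEASE_ANATOMIES, MANAGEMENTS,
                   SEXES, START_AGES)

#: Piecewise annual hazards per (anatomy, management): (breakpoints, rates);
#: rates[i] applies on [breaks[i], breaks[i+1]); the last rate extends to inf.
BASE_HAZARDS: dict[tuple[str, str], tuple[tuple[float, ...], tuple[float, ...]]] = {
    ("left_main", "revascularized"): ((0.0, 5.0), (0.035, 0.045)),
    ("left_main", "medical"): ((0.0, 5.0), (0.075, 0.080)),
    ("three_vessel", "revascularized"): ((0.0, 5.0), (0.032, 0.042)),
    ("three_vessel", "medical"): ((0.0, 5.0), (0.055, 0.060)),
    ("one_two_vessel", "revascularized"): ((0.0, 5.0), (0.022, 0.032)),
    ("one_two_vessel", "medical"): ((0.0, 5.0), (0.025, 0.034)),
    ("normal", "medical"): ((0.0, 5.0), (0.008, 0.012)),
}

#: Multiplicative hazard modifiers for the stratification cells.
ACS_HAZARD_MULTIPLIER = 1.35
SEX_HAZARD_MULTIPLIER = {"male": 1.0, "female": 0.85}
AGE_HAZARD_MULTIPLIER = {"lt65": 1.0, "65_75": 1.9, "gt75": 3.4}

#: Gompertz life-table parameters m(age) = a * exp(b * age), per sex.
LIFE_TABLE_PARAMS = {"male": (2.0e-5, 0.100), "female": (1.1e-5, 0.103)}


@dataclass
class YieldLineConfig:
    """Generative model for regional detection rates (per 100,000 adults).

    detection = intercept + slope * cath_rate + region_effect + noise.
    Default slopes encode the observed yields: ~1 high-risk case per 3
    catheterizations in males, per 5 in females.
    """

    slopes: dict[str, float] = field(default_factory=lambda: {
        "high_risk_male": 1.0 / 3.0, "high_risk_female": 1.0 / 5.0})
    intercepts: dict[str, float] = field(default_factory=lambda: {
        "high_risk_male": 0.0, "high_risk_female": 0.0})
    region_effect_sd: float = 5.0
    residual_sd: float = 5.0
    cath_rate_range: tuple[float, float] = (347.0, 542.0)
    adult_population_range: tuple[int, int] = (120_000, 600_000)


@dataclass
class SynthConfig:
    """Complete parameter set for one synthetic registry draw."""

    n_patients: int = 50_000
    n_regions: int = 9
    years: int = 10
    seed: int = 0
    acs_fraction: float = 0.5
    #: (sex, age band) -> cohort fraction.
    subgroup_weights: dict = field(default_factory=dict)
    #: (sex, age band) -> {anatomy: probability}; sums to 1 per cell.
    anatomy_prevalence: dict = field(default_factory=dict)
    #: (sex, age band, anatomy) -> (p_revascularize, cabg_share).
    treatment_probs: dict = field(default_factory=dict)
    #: (acs, sex, age band, anatomy, management) -> (breakpoints, rates).
    hazard_params: dict = field(default_factory=dict)
    yield_line: YieldLineConfig = field(default_factory=YieldLineConfig)
    #: (anatomy, treatment, age band, year) -> (mean cost, gamma shape).
    cost_params: dict = field(default_factory=dict)
    #: (sex, age band, anatomy, management) -> (mean utility, SD).
    utility_params: dict = field(default_factory=dict)
    #: sex -> (Gompertz a, Gompertz b).
    life_table_params: dict = field(
        default_factory=lambda: dict(LIFE_TABLE_PARAMS))
    life_table_ages: tuple[int, int] = (20, 105)
    registry_normal_fraction: float = 0.0
    surveys_per_cell: int = 200
    cost_records_per_cell: int = 200
    start_ages: dict = field(default_factory=lambda: dict(START_AGES))

    def validate(self) -> None:
        if self.n_regions < 2:
            raise ValueError("n_regions must be >= 2")
        if not 0.0 <= self.acs_fraction <= 1.0:
            raise ValueError("acs_fraction must lie in [0, 1]")
        if not 0.0 <= self.registry_normal_fraction < 1.0:
            raise ValueError("registry_normal_fraction must lie in [0, 1)")
        for cell, prevs in self.anatomy_prevalence.items():
            total = sum(prevs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"anatomy prevalences for {cell} sum to "
                                 f"{total}, expected 1")
            if any(p < 0 or p > 1 for p in prevs.values()):
                raise ValueError(f"anatomy prevalence outside [0,1] in {cell}")
        for cell, (p_rev, cabg) in self.treatment_probs.items():
            if not (0 <= p_rev <= 1 and 0 <= cabg <= 1):
                raise ValueError(f"treatment probabilities outside [0,1] "
                                 f"for {cell}")
        for cell, (breaks, rates) in self.hazard_params.items():
            if any(r < 0 for r in rates):
                raise ValueError(f"negative hazard for {cell}")
            if len(breaks) != len(rates) or breaks[0] != 0:
                raise ValueError(f"malformed hazard spec for {cell}")
        for sex, (a, b) in self.life_table_params.items():
            if a <= 0 or b < 0:
                raise ValueError(f"Gompertz parameters must satisfy a>0, "
                                 f"b>=0 for {sex}")
        for cell, (mean, sd) in self.utility_params.items():
            if sd < 0:
                raise ValueError(f"negative utility SD for {cell}")
        for cell, (mean, shape) in self.cost_params.items():
            if mean <= 0 or shape <= 0:
                raise ValueError(f"non-positive cost mean/shape for {cell}")


def _hazard_for(acs: bool, sex: str, age_band: str, anatomy: str,
                management: str) -> tuple[tuple[float, ...], tuple[float, ...]]:
    breaks, rates = BASE_HAZARDS[(anatomy, management)]
    mult = ((ACS_HAZARD_MULTIPLIER if acs else 1.0)
            * SEX_HAZARD_MULTIPLIER[sex] * AGE_HAZARD_MULTIPLIER[age_band])
    return breaks, tuple(r * mult for r in rates)


def default_config(tables: "_tables.ParameterTables | None" = None,
                   **overrides) -> SynthConfig:
    """Build the default configuration from the published parameter tables.

    Anatomy prevalences, treatment probabilities and utility means/SDs come
    from table 1 (disease prevalences normalized per cell, optionally
    rescaled by a registry normal-coronary fraction); cost means from
    table 2 (gamma shape 1.5 by default); subgroup weights from the table 1
    cohort counts.
    """
    tables = tables or _tables.load_tables()
    t1, t2 = tables.table1, tables.table2
    cfg = SynthConfig(**overrides)

    counts = _tables.subgroup_counts(t1)
    total = sum(counts.values())
    cfg.subgroup_weights = {k: v / total for k, v in counts.items()}

    nf = cfg.registry_normal_fraction
    for (sex, band), grp in t1.groupby(["sex", "age_band"]):
        prevs = dict(zip(grp["anatomy"], grp["prevalence_pct"]))
        s = sum(prevs.values())
        cell = {a: (1.0 - nf) * prevs[a] / s for a in DISEASE_ANATOMIES}
        cell["normal"] = nf
        cfg.anatomy_prevalence[(sex, band)] = cell
        for _, row in grp.iterrows():
            cfg.treatment_probs[(sex, band, row["anatomy"])] = (
                row["p_revasc_pct"] / 100.0, row["p_cabg_pct"] / 100.0)
            cfg.utility_params[(sex, band, row["anatomy"],
                                "revascularized")] = (
                row["u_revasc_mean"], row["u_revasc_sd"])
            cfg.utility_params[(sex, band, row["anatomy"], "medical")] = (
                row["u_medical_mean"], row["u_medical_sd"])
        cfg.treatment_probs[(sex, band, "normal")] = (0.0, 0.0)

    for _, row in t2.iterrows():
        cfg.cost_params[(row["anatomy"], row["treatment"], row["age_band"],
                         int(row["year"]))] = (float(row["mean"]), 1.5)

    for acs in (False, True):
        for sex in SEXES:
            for band in AGE_BANDS:
                for anatomy in ANATOMIES:
                    for mgmt in MANAGEMENTS:
                        if anatomy == "normal" and mgmt == "revascularized":
                            continue
                        cfg.hazard_params[(acs, sex, band, anatomy, mgmt)] = \
                            _hazard_for(acs, sex, band, anatomy, mgmt)
    cfg.validate()
    return cfg


def piecewise_cumulative_hazard(breaks, rates, t: np.ndarray) -> np.ndarray:
    """Cumulative hazard H(t) of a piecewise-exponential spec at times t."""
    t = np.asarray(t, dtype=float)
    breaks = np.asarray(breaks, dtype=float)
    rates = np.asarray(rates, dtype=float)
    edges = np.append(breaks, np.inf)
    H = np.zeros_like(t)
    for i, r in enumerate(rates):
        lo, hi = edges[i], edges[i + 1]
        H += r * np.clip(t - lo, 0.0, hi - lo)
    return H
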