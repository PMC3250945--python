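"""Registry survival to annual transition probabilities.

Kaplan-Meier estimation per stratification cell, discretization to annual
death probabilities q_t, the odds-ratio to relative-risk conversion,
window-RR imputation on the cumulative-hazard scale, relative-risk
counterfactual construction for undetected high-risk patients, life-table
extrapolation past the observed follow-up, and population mortality for
normal-coronary patients.

All relative risks act on the hazard scale, h_med(t) = RR(t) * h_rev(t),
which keeps annual probabilities in [0, 1].
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter


# ---------------------------------------------------------------------------
# life table

class LifeTable:
    """Annual population mortality probability m(age, sex)."""

    def __init__(self, frame: pd.DataFrame):
        required = {"age", "sex", "m"}
        if not required.issubset(frame.columns):
            raise ValueError(f"life table needs columns {sorted(required)}")
        if ((frame["m"] <= 0) | (frame["m"] >= 1)).any():
            raise ValueError("life-table m must lie strictly in (0, 1)")
        self._frame = frame
        self._lookup = {(r.sex, int(r.age)): float(r.m)
                        for r in frame.itertuples()}
        self.min_age = int(frame["age"].min())
        self.max_age = int(frame["age"].max())

    def m(self, age: int, sex: str) -> float:
        try:
            return self._lookup[(sex, int(age))]
        except KeyError:
            raise ValueError(f"life table has no entry for age {age}, "
                             f"sex {sex!r} (range {self.min_age}-"
                             f"{self.max_age})") from None

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()


# ---------------------------------------------------------------------------
# Kaplan-Meier

@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival on an annual grid with Greenwood SEs."""

    subgroup: dict
    times: np.ndarray           # 0..years
    survival: np.ndarray        # S(t) at grid times
    greenwood_se: np.ndarray
    at_risk: np.ndarray
    n: int


def km_estimate(patients: pd.DataFrame, subgroup: dict,
                years: int | None = None) -> KMCurve:
    """Kaplan-Meier survival for one stratification cell.

    ``subgroup`` filters on any of acs/sex/age_band/anatomy/management
    (management "revascularized" matches CABG or PCI).  Ties are handled the
    standard way: deaths at t are processed before censorings at t.
    """
    df = patients
    for key, val in subgroup.items():
        if key == "management":
            if val == "revascularized":
                df = df[df["treatment"].isin(["cabg", "pci"])]
            else:
                df = df[df["treatment"] == "medical"]
        else:
            df = df[df[key] == val]
    if df.empty:
        raise ValueError(f"no patients in subgroup cell {subgroup}")
    if years is None:
        years = int(math.ceil(df["event_time"].max()))
    grid = np.arange(0, years + 1, dtype=float)

    kmf = KaplanMeierFitter()
    kmf.fit(df["event_time"], event_observed=df["event"])
    S = kmf.survival_function_at_times(grid).to_numpy()

    # Greenwood variance: Var(S(t)) = S(t)^2 * sum_{t_i <= t} d_i/(n_i (n_i - d_i))
    tab = kmf.event_table
    d = tab["observed"].to_numpy(float)
    n_at = tab["at_risk"].to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n_at - d > 0, d / (n_at * (n_at - d)), 0.0)
    cum = np.cumsum(terms)
    idx = np.searchsorted(tab.index.to_numpy(float), grid, side="right") - 1
    cum_at_grid = np.where(idx >= 0, cum[np.clip(idx, 0, None)], 0.0)
    se = S * np.sqrt(cum_at_grid)

    at_risk = np.array([float((df["event_time"] >= t).sum()) for t in grid])
    return KMCurve(dict(subgroup), grid, S, se, at_risk, len(df))


# ---------------------------------------------------------------------------
# annual mortality

@dataclass(frozen=True)
class AnnualMortality:
    """Annual death probabilities q_t, t = 1..horizon, with source tags."""

    q: np.ndarray
    source: tuple  # one tag per cycle: observed|rr-adjusted|extrapolated|population
    subgroup: dict = field(default_factory=dict)

    def __post_init__(self):
        q = np.asarray(self.q, dtype=float)
        if ((q < 0) | (q > 1)).any():
            raise ValueError("annual death probabilities must lie in [0, 1]")
        if len(self.source) != len(q):
            raise ValueError("source tags must match the number of cycles")
        object.__setattr__(self, "q", q)

    @property
    def horizon(self) -> int:
        return len(self.q)

    def hazard(self) -> np.ndarray:
        """h_t = -ln(1 - q_t); infinite where q_t = 1."""
        with np.errstate(divide="ignore"):
            return -np.log1p(-self.q)

    def survival(self) -> np.ndarray:
        """S at integer years 0..horizon (S(0) = 1)."""
        return np.concatenate([[1.0], np.cumprod(1.0 - self.q)])

    def cumulative_hazard(self, t: int) -> float:
        return float(self.hazard()[:t].sum())


def annual_probs(curve: KMCurve, years: int | None = None,
                 source: str = "observed") -> AnnualMortality:
    """Discretize a survival curve: q_t = 1 - S(t)/S(t-1).

    Once S reaches 0 the state is absorbing and q_t = 1 thereafter.
    """
    S = np.asarray(curve.survival, dtype=float)
    if years is not None:
        S = S[:years + 1]
    q = np.empty(len(S) - 1)
    for t in range(1, len(S)):
        q[t - 1] = 1.0 if S[t - 1] <= 0 else 1.0 - S[t] / S[t - 1]
    q = np.clip(q, 0.0, 1.0)
    return AnnualMortality(q, tuple([source] * len(q)), dict(curve.subgroup))


# ---------------------------------------------------------------------------
# relative-risk machinery

def or_to_rr(odds_ratio: float, baseline_risk: float) -> float:
    """Convert an odds ratio to a relative risk at baseline risk p0:
    RR = OR / (1 - p0 + p0 * OR)."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0.0 < baseline_risk < 1.0:
        raise ValueError("baseline risk must lie strictly in (0, 1)")
    p0 = baseline_risk
    return odds_ratio / (1.0 - p0 + p0 * odds_ratio)


def impute_window_rr(rr_0_to_a: float, rr_0_to_b: float,
                     mortality_rev: AnnualMortality,
                     a: int, b: int) -> float:
    """Impute the (a, b] window RR from cumulative 0-a and 0-b RRs.

    Solved on the cumulative-hazard scale of the revascularized curve:
    RR_(a,b] = (RR_0b H(b) - RR_0a H(a)) / (H(b) - H(a)).
    """
    if not 0 < a < b <= mortality_rev.horizon:
        raise ValueError("need 0 < a < b <= horizon")
    if rr_0_to_a <= 0 or rr_0_to_b <= 0:
        raise ValueError("cumulative RRs must be positive")
    Ha = mortality_rev.cumulative_hazard(a)
    Hb = mortality_rev.cumulative_hazard(b)
    if Hb <= Ha:
        raise ValueError(f"no events in ({a}, {b}]: cumulative hazard flat")
    rr = (rr_0_to_b * Hb - rr_0_to_a * Ha) / (Hb - Ha)
    if rr <= 0:
        raise ValueError(f"imputed window RR non-positive ({rr:.4f}); "
                         "cumulative inputs are inconsistent")
    return rr


@dataclass(frozen=True)
class RRWindow:
    start: float
    end: float
    rr: float
    ci_low: float | None = None
    ci_high: float | None = None
    source: str = "estimated"


@dataclass(frozen=True)
class RelativeRiskSchedule:
    """Ordered, contiguous RR windows covering (0, inf)."""

    windows: tuple
    scenario: str = ""
    anatomy: str = "all"

    def __post_init__(self):
        ws = tuple(sorted(self.windows, key=lambda w: w.start))
        if not ws or ws[0].start != 0:
            raise ValueError("windows must start at 0")
        for prev, cur in zip(ws, ws[1:]):
            if cur.start != prev.end:
                raise ValueError("windows must be contiguous")
        if any(w.rr <= 0 for w in ws):
            raise ValueError("relative risks must be positive")
        object.__setattr__(self, "windows", ws)

    def rr_at(self, cycle: int) -> float:
        """RR applying to cycle t (the year spanning (t-1, t])."""
        for w in self.windows:
            if w.start < cycle <= w.end:
                return w.rr
        if cycle > self.windows[-1].end:
            return self.windows[-1].rr
        raise ValueError(f"cycle {cycle} not covered")

    def rr_vector(self, horizon: int) -> np.ndarray:
        return np.array([self.rr_at(t) for t in range(1, horizon + 1)])

    def multiplied(self, factor: float,
                   estimated_only: bool = True) -> "RelativeRiskSchedule":
        """Scale the RRs; by default only windows whose source is
        "estimated", leaving assumed RR = 1 windows untouched."""
        new = tuple(
            replace(w, rr=w.rr * factor)
            if (w.source == "estimated" or not estimated_only) else w
            for w in self.windows)
        return replace(self, windows=new)

    def inverted(self) -> "RelativeRiskSchedule":
        return replace(self, windows=tuple(
            replace(w, rr=1.0 / w.rr) for w in self.windows))

    def extended_first_window(self, through: float) -> "RelativeRiskSchedule":
        """Apply the first window's RR through year ``through`` (the
        constant-benefit scenario); later windows past it are kept."""
        first = self.windows[0]
        new = [replace(first, end=through)]
        for w in self.windows[1:]:
            if w.end <= through:
                continue
            new.append(replace(w, start=max(w.start, through)))
        return replace(self, windows=tuple(new))


def schedule_from_table3(table3: pd.DataFrame, scenario: str,
                         anatomy: str) -> RelativeRiskSchedule:
    """Build an RR schedule from the transcribed table; the FRISC-II
    scenario carries a single pooled schedule (anatomy rows tagged "all")."""
    rows = table3[table3["scenario"] == scenario]
    if rows.empty:
        raise ValueError(f"no RR rows for scenario {scenario!r}")
    tag = anatomy if (rows["anatomy"] == anatomy).any() else "all"
    rows = rows[rows["anatomy"] == tag]
    if rows.empty:
        raise ValueError(f"no RR rows for {scenario!r}/{anatomy!r}")
    windows = tuple(
        RRWindow(float(r.window_start), float(r.window_end), float(r.rr),
                 None if pd.isna(r.ci_low) else float(r.ci_low),
                 None if pd.isna(r.ci_high) else float(r.ci_high),
                 str(r.source))
        for r in rows.itertuples())
    return RelativeRiskSchedule(windows, scenario=scenario, anatomy=anatomy)


def medical_management_mortality(
        mortality_rev: AnnualMortality,
        schedule: RelativeRiskSchedule) -> AnnualMortality:
    """Counterfactual medical-management mortality from the revascularized
    curve: h_med(t) = RR(t) * h_rev(t), q = 1 - exp(-h_med)."""
    rr = schedule.rr_vector(mortality_rev.horizon)
    h = mortality_rev.hazard()
    absorbing = ~np.isfinite(h)
    if absorbing.any() and (rr[absorbing] < 1).any():
        warnings.warn("q_rev = 1 with RR < 1: medical arm kept absorbing",
                      stacklevel=2)
    with np.errstate(invalid="ignore"):
        q = np.where(absorbing, 1.0, -np.expm1(-rr * h))
    return AnnualMortality(np.clip(q, 0.0, 1.0),
                           tuple(["rr-adjusted"] * len(q)),
                           dict(mortality_rev.subgroup))


# ---------------------------------------------------------------------------
# extrapolation

def extrapolate(mortality: AnnualMortality, life_table: LifeTable,
                start_age: int, sex: str, horizon: int,
                observed_years: int = 10) -> AnnualMortality:
    """Extend a curve past the observed window with the population age
    increment: h(t) = h(T) * m(start_age + t) / m(start_age + T) for
    t > T, capped at q = 0.999."""
    if mortality.horizon < observed_years:
        raise ValueError(f"mortality must cover the observed "
                         f"{observed_years} years")
    if horizon <= mortality.horizon:
        return mortality
    if start_age + horizon > life_table.max_age:
        raise ValueError(f"start age {start_age} + horizon {horizon} "
                         f"exceeds life-table range (max "
                         f"{life_table.max_age})")
    h_ref = -math.log1p(-min(mortality.q[observed_years - 1], 0.999))
    m_ref = life_table.m(start_age + observed_years, sex)
    q_ext, tags = [], []
    for t in range(mortality.horizon + 1, horizon + 1):
        h = h_ref * life_table.m(start_age + t, sex) / m_ref
        q_ext.append(min(-math.expm1(-h), 0.999))
        tags.append("extrapolated")
    return AnnualMortality(np.concatenate([mortality.q, q_ext]),
                           tuple(mortality.source) + tuple(tags),
                           dict(mortality.subgroup))


def population_mortality(life_table: LifeTable, start_age: int, sex: str,
                         horizon: int) -> AnnualMortality:
    """Normal-coronary patients: q_t = m(start_age + t, sex)."""
    q = [life_table.m(start_age + t, sex) for t in range(1, horizon + 1)]
    return AnnualMortality(np.array(q), tuple(["population"] * horizon),
                           {"sex": sex, "start_age": start_age})
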