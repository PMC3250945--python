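"""Two-arm lifetime Markov cohort model for one marginal catheterization.

One additional potentially-eligible patient either undergoes catheterization
(cycle-0 procedural risk and cost, anatomy revealed, revascularization per
observed practice) or does not (same latent anatomy, all managed medically,
with undetected would-have-been-revascularized patients following the
relative-risk counterfactual mortality and carrying the undetected-disease
utility).  Cycles are annual; state occupancy is valued at cycle start (no
half-cycle correction by default); cycle-t increments are discounted by
(1 + r)^-t with cycle-0 procedure events undiscounted.

A seeded patient-level microsimulation (:func:`microsimulate`) provides an
independent oracle for the cohort trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .keys import DISEASE_ANATOMIES
from .survival_model import AnnualMortality
from .yield_model import AnatomyMix

_OCC_EPS = 1e-8


@dataclass
class ModelInputs:
    """Complete parameter set for one subgroup run (anatomy mix, procedural
    risk, practice patterns, costs, utilities and mortality curves)."""

    mix: AnatomyMix
    p_cath_death: float
    p_revasc: dict          # anatomy -> probability of revascularization
    cabg_share: dict        # anatomy -> CABG share among revascularized
    proc_costs: dict        # {"cath": .., "cabg": .., "pci": ..}
    annual_costs: dict      # (anatomy, treatment, year 1..3) -> CAD
    u_rev: dict             # anatomy -> utility, revascularized
    u_med: dict             # anatomy -> utility, medically managed
    u_undetected: dict      # anatomy -> utility, undetected would-be-revasc
    u_normal: float
    q_rev: dict             # anatomy -> AnnualMortality (observed, extended)
    q_med_observed: dict    # anatomy -> AnnualMortality
    q_med_counterfactual: dict  # anatomy -> AnnualMortality (rr-adjusted)
    q_population: AnnualMortality
    discount_rate: float = 0.05
    horizon: int = 40
    normal_annual_cost: float = 0.0
    half_cycle: bool = False
    utility_duration_years: int | None = None
    common_utility: float | None = None
    label: str = ""

    def validate(self) -> None:
        if not 0.0 <= self.p_cath_death <= 1.0:
            raise ValueError("p_cath_death must lie in [0, 1]")
        if self.discount_rate <= -1.0:
            raise ValueError("discount rate must exceed -1")
        for a in DISEASE_ANATOMIES:
            for d, nm in ((self.p_revasc, "p_revasc"),
                          (self.cabg_share, "cabg_share")):
                if not 0.0 <= d[a] <= 1.0:
                    raise ValueError(f"{nm}[{a}] outside [0, 1]")
            for u in (self.u_rev[a], self.u_med[a], self.u_undetected[a]):
                if not 0.0 <= u <= 1.0:
                    raise ValueError(f"utility for {a} outside [0, 1]")
        if any(c < 0 for c in self.proc_costs.values()):
            raise ValueError("procedure costs must be non-negative")
        if any(c < 0 for c in self.annual_costs.values()):
            raise ValueError("annual costs must be non-negative")
        for a in DISEASE_ANATOMIES:
            for curves in (self.q_rev, self.q_med_observed,
                           self.q_med_counterfactual):
                if a not in curves:
                    raise ValueError(f"missing mortality curve for {a}")
                if curves[a].horizon < self.horizon:
                    raise ValueError(
                        f"mortality curve for {a} covers "
                        f"{curves[a].horizon} < horizon {self.horizon}")
        if self.q_population.horizon < self.horizon:
            raise ValueError("population mortality shorter than horizon")


@dataclass(frozen=True)
class CohortTrace:
    """State occupancy and undiscounted increment streams for one arm."""

    strategy: str
    states: tuple                  # (anatomy, treatment) labels
    occupancy: np.ndarray          # (cycles+1, n_states)
    dead: np.ndarray               # (cycles+1,)
    cost_increments: np.ndarray    # undiscounted, per cycle
    qaly_increments: np.ndarray    # undiscounted, per cycle
    procedure_cost: float          # included in cost_increments[0]

    def __post_init__(self):
        total = self.occupancy.sum(axis=1) + self.dead
        if np.abs(total - 1.0).max() > 1e-10:
            raise ValueError("state occupancies do not sum to 1")
        if (np.diff(self.dead) < -1e-12).any():
            raise ValueError("dead occupancy must be non-decreasing")

    @property
    def cycles(self) -> int:
        return len(self.cost_increments)


def _state_table(inputs: ModelInputs, strategy: str):
    """Per-state initial mass, mortality curve, utility and annual costs."""
    mix = inputs.mix.as_dict()
    alive0 = (1.0 - inputs.p_cath_death) if strategy == "cath" else 1.0
    states, mass0, qs, us, costs, proc = [], [], [], [], [], []
    for a in DISEASE_ANATOMIES:
        p_rev, share = inputs.p_revasc[a], inputs.cabg_share[a]
        for tx, frac in (("cabg", p_rev * share),
                         ("pci", p_rev * (1.0 - share)),
                         ("medical", 1.0 - p_rev)):
            states.append((a, tx))
            mass0.append(alive0 * mix[a] * frac)
            year_costs = [inputs.annual_costs[(a, tx, y)] for y in (1, 2, 3)]
            costs.append(year_costs)
            if tx == "medical":
                qs.append(inputs.q_med_observed[a])
                us.append(inputs.u_med[a])
                proc.append(0.0)
            else:
                if strategy == "cath":
                    qs.append(inputs.q_rev[a])
                    us.append(inputs.u_rev[a])
                    proc.append(inputs.proc_costs[tx])
                else:
                    # undetected: would have been revascularized
                    qs.append(inputs.q_med_counterfactual[a])
                    us.append(inputs.u_undetected[a])
                    proc.append(0.0)
    states.append(("normal", "medical"))
    mass0.append(alive0 * mix["normal"])
    qs.append(inputs.q_population)
    us.append(inputs.u_normal)
    costs.append([inputs.normal_annual_cost] * 3)
    proc.append(0.0)

    q_matrix = np.stack([q.q[:inputs.horizon] for q in qs])  # (S, T)
    return (tuple(states), np.array(mass0), q_matrix, np.array(us),
            np.array(costs), np.array(proc))


def run_cohort(inputs: ModelInputs, strategy: str) -> CohortTrace:
    """Run one strategy arm ("cath" or "no-cath") to the horizon or until
    alive occupancy falls below 1e-8."""
    if strategy not in ("cath", "no-cath"):
        raise ValueError("strategy must be 'cath' or 'no-cath'")
    inputs.validate()
    states, mass0, q, u_state, year_costs, proc = _state_table(inputs,
                                                               strategy)
    T = inputs.horizon
    occ = np.zeros((T + 1, len(states)))
    occ[0] = mass0
    cost_inc = np.zeros(T)
    qaly_inc = np.zeros(T)
    proc_cost = 0.0
    if strategy == "cath":
        proc_cost = inputs.proc_costs["cath"] + float(mass0 @ proc)

    k_expiry = inputs.utility_duration_years
    u_common = (inputs.common_utility if inputs.common_utility is not None
                else inputs.u_normal)
    ran = 0
    for t in range(T):
        occ[t + 1] = occ[t] * (1.0 - q[:, t])
        basis = 0.5 * (occ[t] + occ[t + 1]) if inputs.half_cycle else occ[t]
        year = min(t + 1, 3)
        cost_inc[t] = float(basis @ year_costs[:, year - 1])
        u_t = u_state if (k_expiry is None or t + 1 <= k_expiry) \
            else np.full_like(u_state, u_common)
        qaly_inc[t] = float(basis @ u_t)
        ran = t + 1
        if occ[t + 1].sum() < _OCC_EPS:
            break
    occ = occ[:ran + 1]
    cost_inc = cost_inc[:ran]
    qaly_inc = qaly_inc[:ran]
    cost_inc[0] += proc_cost
    dead = 1.0 - occ.sum(axis=1)
    dead[np.abs(dead) < 1e-15] = 0.0
    return CohortTrace(strategy, states, occ, dead, cost_inc, qaly_inc,
                       proc_cost)


def accumulate(trace: CohortTrace,
               discount_rate: float) -> tuple[float, float]:
    """Total discounted (cost, QALY): cycle-t increments x (1+r)^-t; the
    cycle-0 procedure events carry factor 1 by construction."""
    if discount_rate <= -1.0:
        raise ValueError("discount rate must exceed -1")
    t = np.arange(trace.cycles)
    disc = (1.0 + discount_rate) ** (-t)
    return (float(trace.cost_increments @ disc),
            float(trace.qaly_increments @ disc))


def incremental(inputs: ModelInputs) -> dict:
    """Run both arms and return the incremental (cost, QALY) pair."""
    out = {}
    for strategy in ("cath", "no-cath"):
        trace = run_cohort(inputs, strategy)
        out[strategy] = accumulate(trace, inputs.discount_rate)
    c1, e1 = out["cath"]
    c0, e0 = out["no-cath"]
    out["delta_cost"] = c1 - c0
    out["delta_qaly"] = e1 - e0
    return out


# ---------------------------------------------------------------------------
# microsimulation oracle

def microsimulate(inputs: ModelInputs, strategy: str, n: int,
                  rng: np.random.Generator) -> dict:
    """Patient-level Monte Carlo version of :func:`run_cohort`.

    Each simulated patient draws a procedural outcome, an (anatomy,
    treatment) state, and a death cycle from the state's annual
    probabilities (inverse-CDF on the implied discrete lifetime law, the
    same distribution as sequential annual Bernoulli draws).  Returns mean
    discounted cost/QALY with Monte-Carlo standard errors.
    """
    inputs.validate()
    states, mass0, q, u_state, year_costs, proc = _state_table(inputs,
                                                               strategy)
    T = inputs.horizon
    r = inputs.discount_rate
    disc = (1.0 + r) ** (-np.arange(T))
    # per-state prefix sums over lived years 0..T
    k_expiry = inputs.utility_duration_years
    u_common = (inputs.common_utility if inputs.common_utility is not None
                else inputs.u_normal)
    cost_prefix = np.zeros((len(states), T + 1))
    qaly_prefix = np.zeros((len(states), T + 1))
    for s in range(len(states)):
        yearly_cost = np.array([year_costs[s, min(t, 2)] for t in range(T)])
        u_years = np.array([
            u_state[s] if (k_expiry is None or t + 1 <= k_expiry)
            else u_common for t in range(T)])
        cost_prefix[s, 1:] = np.cumsum(yearly_cost * disc)
        qaly_prefix[s, 1:] = np.cumsum(u_years * disc)

    # lifetime law per state: L = lived years in 1..T
    #   P(L = l) = prod_{j<l}(1-q_j) * q_l for l < T; survivors capped at T
    surv = np.cumprod(1.0 - q, axis=1)            # (S, T) survival past cycle
    pmf = np.zeros((len(states), T))
    pmf[:, 0] = q[:, 0]
    pmf[:, 1:] = surv[:, :-1] * q[:, 1:]
    pmf[:, T - 1] += surv[:, T - 1]               # survive the whole horizon
    cdf = np.cumsum(pmf, axis=1)

    p_proc_death = inputs.p_cath_death if strategy == "cath" else 0.0
    state_probs = np.concatenate([[p_proc_death], mass0])
    state_probs = state_probs / state_probs.sum()
    draws = rng.choice(len(state_probs), size=n, p=state_probs)
    u = rng.random(n)

    cost = np.zeros(n)
    qaly = np.zeros(n)
    cath_cost = inputs.proc_costs["cath"] if strategy == "cath" else 0.0
    cost += cath_cost
    for s in range(len(states)):
        m = draws == s + 1
        k = int(m.sum())
        if k == 0:
            continue
        lived = np.searchsorted(cdf[s], u[m] * cdf[s, -1], side="right") + 1
        lived = np.clip(lived, 1, T)
        cost[m] += proc[s] + cost_prefix[s, lived]
        qaly[m] += qaly_prefix[s, lived]
    return {
        "cost_mean": float(cost.mean()),
        "cost_se": float(cost.std(ddof=1) / np.sqrt(n)),
        "qaly_mean": float(qaly.mean()),
        "qaly_se": float(qaly.std(ddof=1) / np.sqrt(n)),
        "n": n,
    }
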