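"""Probabilistic sensitivity analysis.

Inputs are drawn independently per Monte-Carlo iteration: normal
distributions for relative risks, utilities and the high-risk yield
probability (truncated to their valid ranges), gamma distributions for all
cost estimates (method-of-moments from published means and 95% CIs).  Each
draw reruns both model arms; the (ΔC, ΔE) cloud is summarized as CE-plane
quadrant shares, a 95% confidence ellipse and cost-effectiveness
acceptability curves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assemble import MortalityLibrary, ParameterSet, family_results
from .keys import DISEASE_ANATOMIES, SEXES

_CHI2_2DF_95 = 5.991464547107979


# ---------------------------------------------------------------------------
# distributions

def gamma_from_mean_ci(mean: float, ci_low: float,
                       ci_high: float) -> tuple[float, float]:
    """Method-of-moments gamma (shape, scale) from a mean and 95% CI:
    SE = (ci_high - ci_low)/3.92, shape = mean^2/SE^2, scale = SE^2/mean."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if ci_high <= ci_low:
        raise ValueError("ci_high must exceed ci_low")
    se = (ci_high - ci_low) / 3.92
    if se <= 0:
        raise ValueError("non-positive SE")
    return mean * mean / (se * se), se * se / mean


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one parameter of the model."""

    path: tuple            # e.g. ("rr", "left_main", 0)
    family: str            # "normal" | "gamma"
    mean: float
    se: float
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if self.family not in ("normal", "gamma"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family == "gamma" and (self.mean <= 0 or self.se < 0):
            # se == 0 is the degenerate point mass used when a spread is
            # switched off
            raise ValueError("gamma requires positive mean and "
                             "non-negative SE")
        if self.lower > self.upper:
            raise ValueError("truncation bounds out of order")

    def draw(self, rng: np.random.Generator) -> float:
        if self.se == 0:
            return self.mean
        if self.family == "normal":
            x = rng.normal(self.mean, self.se)
        else:
            shape = self.mean ** 2 / self.se ** 2
            x = rng.gamma(shape, self.se ** 2 / self.mean)
        return float(np.clip(x, self.lower, self.upper))


def default_distribution_specs(params: ParameterSet,
                               table2: pd.DataFrame,
                               yield_cv: float = 0.10,
                               proc_cost_cv: float = 0.10) -> list[DistributionSpec]:
    """The sampled parameters of the base-case PSA.

    Relative risks take their SE from the published 95% CIs; utilities use
    SD/sqrt(n); annual costs convert mean/CI to gamma moments; procedure
    costs use a configurable coefficient of variation; the high-risk yield
    probability (1/ratio) gets SE = ``yield_cv`` x mean since no variance is
    published.
    """
    specs: list[DistributionSpec] = []
    for anatomy in DISEASE_ANATOMIES:
        sched = params.rr_schedules[anatomy]
        for i, w in enumerate(sched.windows):
            if w.ci_low is None or w.ci_high is None:
                continue
            se = (w.ci_high - w.ci_low) / 3.92
            specs.append(DistributionSpec(("rr", anatomy, i), "normal",
                                          w.rr, se, lower=0.01))
    for key, mean in params.utilities.items():
        specs.append(DistributionSpec(("utility",) + key, "normal", mean,
                                      params.utility_se[key], 0.0, 1.0))
    for sex in SEXES:
        p = 1.0 / params.high_risk_ratio[sex]
        specs.append(DistributionSpec(("yield_prob", sex), "normal", p,
                                      yield_cv * p, 1e-3, 1.0 - 1e-3))
    for r in table2.itertuples():
        se = (float(r.ci_high) - float(r.ci_low)) / 3.92
        se = max(se, 1e-9)
        specs.append(DistributionSpec(
            ("annual_cost", r.anatomy, r.treatment, r.age_band,
             int(r.year)), "gamma", float(r.mean), se))
    for name, cost in params.proc_costs.items():
        specs.append(DistributionSpec(("proc_cost", name), "gamma", cost,
                                      proc_cost_cv * cost))
    return specs


def _apply(params: ParameterSet, path: tuple, value: float) -> None:
    kind = path[0]
    if kind == "rr":
        _, anatomy, idx = path
        sched = params.rr_schedules[anatomy]
        windows = list(sched.windows)
        windows[idx] = type(windows[idx])(
            windows[idx].start, windows[idx].end, value,
            windows[idx].ci_low, windows[idx].ci_high, windows[idx].source)
        params.rr_schedules[anatomy] = type(sched)(
            tuple(windows), sched.scenario, sched.anatomy)
    elif kind == "utility":
        key = path[1:]
        if key not in params.utilities:
            raise KeyError(f"no utility parameter {key}")
        params.utilities[key] = value
    elif kind == "yield_prob":
        params.high_risk_ratio[path[1]] = 1.0 / value
    elif kind == "annual_cost":
        key = path[1:]
        if key not in params.annual_costs:
            raise KeyError(f"no annual cost parameter {key}")
        params.annual_costs[key] = value
    elif kind == "proc_cost":
        if path[1] not in params.proc_costs:
            raise KeyError(f"no procedure cost {path[1]!r}")
        params.proc_costs[path[1]] = value
    else:
        raise KeyError(f"unknown parameter path {path}")


def sample_inputs(base: ParameterSet, specs: list[DistributionSpec],
                  rng: np.random.Generator) -> ParameterSet:
    """One Monte-Carlo draw of the parameter set (independent draws,
    truncated to valid ranges, deterministic under a seeded rng)."""
    draw = base.copy()
    for spec in specs:
        _apply(draw, spec.path, spec.draw(rng))
    return draw


# ---------------------------------------------------------------------------
# the simulation itself

@dataclass(frozen=True)
class PSAResult:
    """Paired (ΔC, ΔE) draws for one scenario family."""

    draws: np.ndarray          # (n, 2): delta_cost, delta_qaly
    seed: int
    scenario: str = ""
    failures: tuple = field(default_factory=tuple)

    def __post_init__(self):
        d = np.asarray(self.draws, dtype=float)
        if d.ndim != 2 or d.shape[1] != 2 or d.shape[0] < 1:
            raise ValueError("draws must be a non-empty (n, 2) array")
        if not np.isfinite(d).all():
            raise ValueError("non-finite draws")
        object.__setattr__(self, "draws", d)

    @property
    def n(self) -> int:
        return self.draws.shape[0]


def run_psa(base: ParameterSet, library: MortalityLibrary, acs: bool,
            specs: list[DistributionSpec], n_draws: int, seed: int,
            scenario: str = "") -> PSAResult:
    """Monte-Carlo propagation: per draw, sample the inputs, rerun both
    arms for every subgroup cell and record the family-aggregate (ΔC, ΔE).

    Draw i uses the child stream (seed, i), so extending ``n_draws``
    reproduces the earlier draws unchanged.  More than 1% failed draws
    aborts with a summary.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    out = np.empty((n_draws, 2))
    failures = []
    for i in range(n_draws):
        rng = np.random.default_rng([seed, i])
        try:
            draw = sample_inputs(base, specs, rng)
            res = family_results(draw, library, acs)
            out[i] = res["aggregate"]
        except Exception as exc:  # recorded, draw skipped
            failures.append((i, repr(exc)))
            out[i] = np.nan
            if len(failures) > max(1, 0.01 * n_draws):
                raise RuntimeError(
                    f"PSA aborted: {len(failures)} failed draws, first: "
                    f"{failures[0]}") from exc
    ok = np.isfinite(out).all(axis=1)
    return PSAResult(out[ok], seed, scenario, tuple(failures))


# ---------------------------------------------------------------------------
# summaries

@dataclass(frozen=True)
class CEAC:
    """Probability the increased-rate strategy is cost-effective vs λ."""

    lambdas: np.ndarray
    probability: np.ndarray

    def at(self, lam: float) -> float:
        i = int(np.argmin(np.abs(self.lambdas - lam)))
        return float(self.probability[i])


def ceac(result: PSAResult, lambdas: np.ndarray | None = None) -> CEAC:
    """P(λ) = fraction of draws with positive net monetary benefit
    λ ΔE - ΔC."""
    if lambdas is None:
        lambdas = np.arange(0, 200_001, 1000, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    if lambdas.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    dc = result.draws[:, 0]
    de = result.draws[:, 1]
    nmb = lambdas[:, None] * de[None, :] - dc[None, :]
    return CEAC(lambdas, (nmb > 0).mean(axis=1))


def quadrant_shares(result: PSAResult) -> dict[str, float]:
    """CE-plane quadrant fractions (boundaries: ΔE > 0 is more effective,
    ΔC > 0 is more costly); they sum to 1."""
    dc = result.draws[:, 0]
    de = result.draws[:, 1]
    more_eff = de > 0
    costlier = dc > 0
    n = result.n
    return {
        "cheaper_more_effective": float((~costlier & more_eff).sum() / n),
        "costlier_more_effective": float((costlier & more_eff).sum() / n),
        "costlier_less_effective": float((costlier & ~more_eff).sum() / n),
        "cheaper_less_effective": float((~costlier & ~more_eff).sum() / n),
    }


@dataclass(frozen=True)
class Ellipse:
    center: tuple[float, float]
    semi_axes: tuple[float, float]   # major, minor
    angle_rad: float                 # rotation of the major axis

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Membership test (used for coverage checks)."""
        p = np.asarray(points, dtype=float) - np.asarray(self.center)
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        rot = np.array([[c, s], [-s, c]])
        q = p @ rot.T
        a, b = self.semi_axes
        return (q[:, 0] / a) ** 2 + (q[:, 1] / b) ** 2 <= 1.0


def ellipse_95(result: PSAResult) -> Ellipse:
    """95% bivariate-normal confidence ellipse of the (ΔC, ΔE) cloud from
    the sample mean and covariance at chi-square(2df) = 5.991."""
    if result.n < 3:
        raise ValueError("need at least 3 draws for an ellipse")
    x = result.draws
    cov = np.cov(x.T)
    if np.linalg.matrix_rank(cov) < 2 or np.linalg.det(cov) <= 0:
        raise ValueError("singular covariance; run more draws")
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    axes = tuple(float(np.sqrt(_CHI2_2DF_95 * v)) for v in vals)
    angle = float(np.arctan2(vecs[1, 0], vecs[0, 0]))
    return Ellipse((float(x[:, 0].mean()), float(x[:, 1].mean())), axes,
                   angle)


# ---------------------------------------------------------------------------
# plots

def plot_ce_plane(result: PSAResult, path=None, ax=None):
    """Scatter of (ΔE, ΔC) draws with the 95% confidence ellipse."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    de, dc = result.draws[:, 1], result.draws[:, 0]
    ax.scatter(de, dc, s=4, alpha=0.3, color="tab:blue")
    ell = ellipse_95(result)
    # the ellipse lives in (ΔC, ΔE) space; draw it parametrically on the
    # plotted (ΔE, ΔC) axes
    t = np.linspace(0, 2 * np.pi, 200)
    a, b = ell.semi_axes
    c, s = np.cos(ell.angle_rad), np.sin(ell.angle_rad)
    xs = ell.center[0] + a * np.cos(t) * c - b * np.sin(t) * s
    ys = ell.center[1] + a * np.cos(t) * s + b * np.sin(t) * c
    ax.plot(ys, xs, color="tab:red", lw=1.5)
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    ax.set_xlabel("Incremental QALYs per catheterization")
    ax.set_ylabel("Incremental cost per catheterization (2006 CAD)")
    ax.set_title(f"CE plane {result.scenario} (n={result.n})")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax


def plot_ceac(curve: CEAC, path=None, ax=None, label: str = ""):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.lambdas, curve.probability, label=label or None)
    ax.set_xlabel("Willingness to pay (CAD per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(0, 1)
    if label:
        ax.legend()
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
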