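"""Yield analysis: detection rate vs. population catheterization rate.

Fits a random-intercept (health-region) linear model of the disease
detection rate on the population catheterization rate, optionally weighted
by regional adult population, refits with a quadratic term to test for a
plateau in yield, and converts headline yield ratios (e.g. one high-risk
case per 3 catheterizations in males) into the anatomy mix of the marginal
additional catheterization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm

from .keys import HIGH_RISK_ANATOMIES

_PLATEAU_ALPHA = 0.05


@dataclass(frozen=True)
class YieldFit:
    """Random-intercept fit of detection rate on catheterization rate."""

    category: str
    slope: float
    intercept: float
    slope_se: float
    slope_ci: tuple[float, float]
    region_effect_sd: float
    residual_sd: float
    quadratic_coef: float
    quadratic_p: float
    n_regions: int
    n_obs: int
    weight_mode: str

    @property
    def plateau_evidence(self) -> bool:
        """Whether the quadratic term is significant at the 5% level."""
        return self.quadratic_p < _PLATEAU_ALPHA


@dataclass(frozen=True)
class AnatomyMix:
    """Anatomy distribution of the marginal additional catheterization."""

    left_main: float
    three_vessel: float
    one_two_vessel: float
    normal: float
    high_risk_ratio: float

    def as_dict(self) -> dict[str, float]:
        return {"left_main": self.left_main,
                "three_vessel": self.three_vessel,
                "one_two_vessel": self.one_two_vessel,
                "normal": self.normal}

    @property
    def high_risk(self) -> float:
        return self.left_main + self.three_vessel

    def __post_init__(self):
        probs = self.as_dict()
        for k, v in probs.items():
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValueError(f"mix probability {k}={v} outside [0, 1]")
        if abs(sum(probs.values()) - 1.0) > 1e-9:
            raise ValueError(f"mix probabilities sum to "
                             f"{sum(probs.values())}, expected 1")


def _mixed_fit(y, x_cols, groups, w):
    """Weighted random-intercept LMM via row scaling: multiplying the
    response and design by sqrt(w) and using sqrt(w) as the random-effect
    design is exactly the model with Var(e_i) = sigma^2 / w_i."""
    import warnings as _warnings

    sw = np.sqrt(w)
    X = sm.add_constant(np.column_stack(x_cols))
    model = sm.MixedLM(y * sw, X * sw[:, None], groups=groups,
                       exog_re=sw[:, None])
    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        res = model.fit(reml=True, method=["lbfgs", "powell"])
    return res


def fit_yield_line(records: pd.DataFrame, category: str,
                   weight_mode: str = "population") -> YieldFit:
    """Fit the linear yield relation for one detection category.

    Parameters
    ----------
    records
        Long-format region-year table with columns ``region``, ``year``,
        ``adult_population``, ``cath_rate``, ``category``, ``det_rate``.
    weight_mode
        ``"population"`` (adult population counts) or ``"none"``.

    Notes
    -----
    Noise-free data (all residuals numerically zero) short-circuits to the
    exact least-squares solution, since REML is singular there.
    """
    df = records[records["category"] == category]
    if df.empty:
        raise ValueError(f"no records for category {category!r}")
    if df["region"].nunique() < 3:
        raise ValueError("need at least 3 regions to fit a region "
                         "random effect")
    x = df["cath_rate"].to_numpy(float)
    y = df["det_rate"].to_numpy(float)
    if np.ptp(x) == 0:
        raise ValueError("singular design: all catheterization rates equal")
    if weight_mode == "population":
        w = df["adult_population"].to_numpy(float)
    elif weight_mode == "none":
        w = np.ones(len(df))
    else:
        raise ValueError(f"unknown weight_mode {weight_mode!r}")
    w = w / w.mean()  # slope invariant to rescaling; keeps REML well-scaled
    groups = df["region"].to_numpy()

    # exact-fit short circuit for noiseless data
    X = sm.add_constant(x)
    ols = sm.WLS(y, X, weights=w).fit()
    scale = max(float(np.abs(y).max()), 1.0)
    if float(np.abs(ols.resid).max()) < 1e-8 * scale:
        intercept, slope = ols.params
        quad = sm.WLS(y, sm.add_constant(np.column_stack([x, x ** 2])),
                      weights=w).fit()
        return YieldFit(category, float(slope), float(intercept), 0.0,
                        (float(slope), float(slope)), 0.0, 0.0,
                        float(quad.params[2]), 1.0, df["region"].nunique(),
                        len(df), weight_mode)

    import warnings as _warnings
    with _warnings.catch_warnings(), np.errstate(all="ignore"):
        _warnings.simplefilter("ignore")
        res = _mixed_fit(y, [x], groups, w)
        slope = float(res.fe_params[1])
        se = float(res.bse_fe[1])
        region_sd = float(np.sqrt(max(np.asarray(res.cov_re)[0, 0], 0.0)))
        resid_sd = float(np.sqrt(res.scale))
        # quadratic refit on a centred/scaled predictor to avoid the
        # extreme collinearity of (x, x^2) at rates in the hundreds; the
        # Wald test is invariant to this reparameterization
        xc = (x - x.mean()) / x.std()
        res_q = _mixed_fit(y, [xc, xc ** 2], groups, w)
        qcoef_scaled = float(res_q.fe_params[2])
        qse = float(res_q.bse_fe[2])
    ci = (slope - 1.959963984540054 * se, slope + 1.959963984540054 * se)
    qp = 2.0 * sps.norm.sf(abs(qcoef_scaled / qse)) if qse > 0 else 1.0
    qcoef = qcoef_scaled / x.std() ** 2

    return YieldFit(category, slope, float(res.fe_params[0]), se, ci,
                    region_sd, resid_sd, qcoef, float(qp),
                    df["region"].nunique(), len(df), weight_mode)


def marginal_anatomy_mix(high_risk_ratio: float, lm_to_3vd_split: float,
                         normal_fraction: float) -> AnatomyMix:
    """Anatomy mix of the marginal catheterization from a yield ratio.

    ``high_risk_ratio`` r means one left-main-or-3-vessel case per r
    catheterizations: pi(LM) + pi(3VD) = 1/r, divided between left main and
    3-vessel by ``lm_to_3vd_split`` (left-main share); the remainder is
    split between 1-2-vessel disease and normal coronaries by
    ``normal_fraction`` (normal share of the remainder).
    """
    if high_risk_ratio <= 1:
        raise ValueError("high_risk_ratio must exceed 1 (a ratio of r "
                         "catheterizations per high-risk case)")
    if not (0 <= lm_to_3vd_split <= 1 and 0 <= normal_fraction <= 1):
        raise ValueError("lm_to_3vd_split and normal_fraction must lie "
                         "in [0, 1]")
    high = 1.0 / high_risk_ratio
    rest = 1.0 - high
    return AnatomyMix(
        left_main=high * lm_to_3vd_split,
        three_vessel=high * (1.0 - lm_to_3vd_split),
        one_two_vessel=rest * (1.0 - normal_fraction),
        normal=rest * normal_fraction,
        high_risk_ratio=high_risk_ratio,
    )


def lm_split_from_prevalence(table1: pd.DataFrame, sex: str,
                             age_band: str) -> float:
    """Default left-main share of high-risk disease from the published
    prevalences within a (sex, age band) cell, e.g. 5.3/(5.3+21.3)."""
    cell = table1[(table1["sex"] == sex) & (table1["age_band"] == age_band)]
    prev = dict(zip(cell["anatomy"], cell["prevalence_pct"]))
    lm, tv = (prev[a] for a in HIGH_RISK_ANATOMIES)
    return lm / (lm + tv)


def yield_fits_to_frame(fits: list[YieldFit]) -> pd.DataFrame:
    return pd.DataFrame([{
        "category": f.category, "slope": f.slope, "intercept": f.intercept,
        "slope_se": f.slope_se, "slope_ci_low": f.slope_ci[0],
        "slope_ci_high": f.slope_ci[1],
        "region_effect_sd": f.region_effect_sd,
        "residual_sd": f.residual_sd, "quadratic_coef": f.quadratic_coef,
        "quadratic_p": f.quadratic_p, "n_regions": f.n_regions,
        "n_obs": f.n_obs, "weight_mode": f.weight_mode,
    } for f in fits])
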