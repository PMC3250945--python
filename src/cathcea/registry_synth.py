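"""Synthetic catheterization-registry generator.

Produces patient-level survival records, regional catheterization/detection
rates, EQ-5D survey records, annual cost records and a Gompertz life table
with the statistical structure the downstream analysis assumes, so the whole
pipeline is testable without access to any proprietary registry.

Every operation is deterministic under the configured seed; each operation
draws from its own child stream so datasets can be regenerated independently.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import SynthConfig, piecewise_cumulative_hazard
from .keys import AGE_BANDS, SEXES

# child-stream identifiers so each generator has an independent substream
_STREAM = {"patients": 1, "regions": 2, "lifetable": 3, "surveys": 4,
           "costs": 5}


def _rng(config: SynthConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAM[stream], config.seed])


def _sample_piecewise_exponential(breaks, rates, n: int,
                                  rng: np.random.Generator) -> np.ndarray:
    """Draw n event times from a piecewise-exponential hazard by inverting
    the cumulative hazard at Exp(1) deviates; returns inf where the total
    hazard is exhausted (e.g. all-zero rates)."""
    breaks = np.asarray(breaks, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if (rates < 0).any():
        raise ValueError("negative hazard rate")
    e = rng.exponential(size=n)
    H_at_break = piecewise_cumulative_hazard(breaks, rates, breaks)
    t = np.full(n, np.inf)
    for i in range(len(rates)):
        lo = H_at_break[i]
        hi = H_at_break[i + 1] if i + 1 < len(rates) else np.inf
        in_seg = (e >= lo) & (e < hi)
        if rates[i] > 0:
            t[in_seg] = breaks[i] + (e[in_seg] - lo) / rates[i]
        # zero-rate segment: survival flat, event pushed past the segment;
        # with e < hi impossible unless hi == lo, handled by next segments
    return t


def generate_patients(config: SynthConfig,
                      subgroup: dict | None = None) -> pd.DataFrame:
    """Generate the patient-level survival cohort.

    Subgroup sizes follow the configured composition multinomially; event
    times come from the subgroup's piecewise-exponential hazard with
    administrative censoring at ``config.years``.

    Parameters
    ----------
    subgroup
        Optional restriction, e.g. ``{"sex": "male", "age_band": "lt65"}``;
        all ``config.n_patients`` records are then drawn from that cell.
        Requesting a zero-probability cell raises ``ValueError``.
    """
    config.validate()
    rng = _rng(config, "patients")
    n = config.n_patients

    cells = list(config.subgroup_weights)
    weights = np.array([config.subgroup_weights[c] for c in cells])
    if subgroup:
        keep = [i for i, (sex, band) in enumerate(cells)
                if subgroup.get("sex", sex) == sex
                and subgroup.get("age_band", band) == band]
        mask = np.zeros_like(weights)
        mask[keep] = weights[keep]
        if mask.sum() <= 0:
            raise ValueError(f"requested subgroup {subgroup} has zero "
                             "probability under the configured composition")
        weights = mask / mask.sum()
    else:
        weights = weights / weights.sum()

    cell_idx = rng.choice(len(cells), size=n, p=weights)
    sex = np.array([cells[i][0] for i in cell_idx])
    band = np.array([cells[i][1] for i in cell_idx])
    if subgroup and "acs" in subgroup:
        acs = np.full(n, bool(subgroup["acs"]))
    else:
        acs = rng.random(n) < config.acs_fraction

    anatomy = np.empty(n, dtype=object)
    treatment = np.empty(n, dtype=object)
    for (s, b), prevs in config.anatomy_prevalence.items():
        m = (sex == s) & (band == b)
        k = int(m.sum())
        if k == 0:
            continue
        cats = list(prevs)
        anatomy[m] = rng.choice(cats, size=k,
                                p=np.array([prevs[c] for c in cats]))
        for a in cats:
            ma = m & (anatomy == a)
            ka = int(ma.sum())
            if ka == 0:
                continue
            if a == "normal":
                treatment[ma] = "medical"
                continue
            p_rev, cabg_share = config.treatment_probs[(s, b, a)]
            rev = rng.random(ka) < p_rev
            cabg = rng.random(ka) < cabg_share
            tx = np.where(rev, np.where(cabg, "cabg", "pci"), "medical")
            treatment[ma] = tx
    if subgroup and "anatomy" in subgroup:
        raise ValueError("restrict by sex/age_band/acs only; anatomy is "
                         "drawn from the configured prevalences")

    mgmt = np.where(treatment == "medical", "medical", "revascularized")
    event_time = np.empty(n)
    for key, (breaks, rates) in config.hazard_params.items():
        a_, s_, b_, an_, mg_ = key
        m = (acs == a_) & (sex == s_) & (band == b_) & (anatomy == an_) \
            & (mgmt == mg_)
        k = int(m.sum())
        if k:
            event_time[m] = _sample_piecewise_exponential(breaks, rates, k,
                                                          rng)

    died = event_time <= config.years
    event_time = np.where(died, event_time, float(config.years))
    df = pd.DataFrame({
        "id": np.arange(n),
        "acs": acs,
        "sex": sex,
        "age_band": band,
        "anatomy": anatomy,
        "treatment": treatment,
        "event_time": event_time,
        "event": died,
        "censor_time": np.where(died, event_time, float(config.years)),
    })
    return df


def generate_region_rates(config: SynthConfig) -> pd.DataFrame:
    """Generate regional catheterization and disease-detection rates.

    One row per (region, year, category); detection rate (per 100,000
    adults) lies on the configured line plus a region random effect and
    residual noise; counts are rounded, non-negative integers.
    """
    config.validate()
    rng = _rng(config, "regions")
    yl = config.yield_line
    lo, hi = yl.cath_rate_range
    plo, phi = yl.adult_population_range
    pops = rng.integers(plo, phi, size=config.n_regions)

    rows = []
    clamped = 0
    for cat, slope in yl.slopes.items():
        intercept = yl.intercepts.get(cat, 0.0)
        region_fx = rng.normal(0.0, yl.region_effect_sd,
                               size=config.n_regions)
        for r in range(config.n_regions):
            for y in range(config.years):
                rate = rng.uniform(lo, hi)
                det = (intercept + slope * rate + region_fx[r]
                       + rng.normal(0.0, yl.residual_sd))
                if det < 0:
                    det = 0.0
                    clamped += 1
                count = int(round(det * pops[r] / 1e5))
                rows.append((r, y, int(pops[r]), rate, cat, det,
                             max(count, 0)))
    if clamped:
        warnings.warn(f"{clamped} negative expected detection rates clamped "
                      "to 0", stacklevel=2)
    return pd.DataFrame(rows, columns=[
        "region", "year", "adult_population", "cath_rate", "category",
        "det_rate", "detected"])


def generate_life_table(config: SynthConfig) -> pd.DataFrame:
    """Gompertz life table m(age, sex) = min(0.999, a * exp(b * age))."""
    config.validate()
    lo, hi = config.life_table_ages
    ages = np.arange(lo, hi + 1)
    rows = []
    for sex, (a, b) in config.life_table_params.items():
        m = np.minimum(0.999, a * np.exp(b * ages))
        rows.append(pd.DataFrame({"age": ages, "sex": sex, "m": m}))
    return pd.concat(rows, ignore_index=True)


def generate_survey_and_cost_records(
        config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """EQ-5D survey records (truncated-normal utilities in [0, 1]) and
    annual cost records (gamma, matching the configured mean/shape)."""
    config.validate()
    rng_s = _rng(config, "surveys")
    rng_c = _rng(config, "costs")

    srows = []
    for (sex, band, anatomy, mgmt), (mean, sd) in \
            sorted(config.utility_params.items()):
        k = config.surveys_per_cell
        if sd == 0:
            u = np.full(k, mean)
        else:
            a, b = (0.0 - mean) / sd, (1.0 - mean) / sd
            u = stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=k,
                                    random_state=rng_s)
        srows.append(pd.DataFrame({
            "sex": sex, "age_band": band, "anatomy": anatomy,
            "management": mgmt, "utility": u}))
    surveys = pd.concat(srows, ignore_index=True)

    crows = []
    for (anatomy, tx, band, year), (mean, shape) in \
            sorted(config.cost_params.items()):
        k = config.cost_records_per_cell
        cost = rng_c.gamma(shape, mean / shape, size=k)
        crows.append(pd.DataFrame({
            "anatomy": anatomy, "treatment": tx, "age_band": band,
            "year": year, "cost": cost}))
    costs = pd.concat(crows, ignore_index=True)
    return surveys, costs


def write_synthetic_dataset(config: SynthConfig, outdir: str | Path) -> dict:
    """Write patients/regions/lifetable/surveys/costs CSVs; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    datasets = {
        "patients": generate_patients(config),
        "regions": generate_region_rates(config),
        "lifetable": generate_life_table(config),
    }
    datasets["surveys"], datasets["costs"] = \
        generate_survey_and_cost_records(config)
    for name, df in datasets.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False)
        paths[name] = str(p)
    return paths
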