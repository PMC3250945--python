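"""Loading and validation of the published parameter tables.

Three CSV transcriptions ship with the package:

``table1.csv``
    Anatomy prevalence, revascularization probabilities, CABG share,
    procedural death risk and EQ-5D utilities by sex and age band.
``table2.csv``
    Annual health-care costs (2006 CAD) by anatomy, treatment, age band and
    follow-up year (1-3) with 95% CIs.
``table3.csv``
    Relative risk of death for medical management vs. revascularization, by
    time window; "yusuf" rows are anatomy-specific (non-ACS), "frisc2" rows
    are pooled across anatomies (ACS).

Validation fails fast and names the offending row/column.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .keys import AGE_BANDS, DISEASE_ANATOMIES, SEXES, TREATMENTS

#: Procedure costs (2006 CAD): catheterization, CABG, PCI including
#: hospitalization and physician costs.
PROCEDURE_COSTS = {"cath": 2048.0, "cabg": 17958.0, "pci": 7927.0}

#: Utility decrement applied to undetected left-main/3-vessel patients who
#: would have been revascularized (SF-36 derived, MASS-2).
UNDETECTED_UTILITY_DECREMENT = 0.03

#: Seattle Angina Questionnaire alternative utility set
#: {anatomy: (revascularized, medical)}.
SAQ_UTILITIES = {
    "left_main": (0.87, 0.71),
    "three_vessel": (0.83, 0.72),
    "one_two_vessel": (0.80, 0.78),
}

#: Annual discount rate for costs and outcomes (base case).
DISCOUNT_RATE = 0.05

_TABLE1_COLS = [
    "sex", "age_band", "n_subgroup", "p_cath_death_pct", "anatomy",
    "prevalence_pct", "prevalence_n", "p_revasc_pct", "p_cabg_pct",
    "n_utility", "u_revasc_mean", "u_revasc_sd", "u_medical_mean",
    "u_medical_sd",
]
_TABLE2_COLS = ["anatomy", "treatment", "age_band", "n", "year", "mean",
                "ci_low", "ci_high"]
_TABLE3_COLS = ["scenario", "anatomy", "window_start", "window_end", "rr",
                "ci_low", "ci_high", "source"]


class TableValidationError(ValueError):
    """A parameter table failed schema or range validation."""


def _default_path(name: str) -> Path:
    return Path(str(importlib.resources.files("cathcea") / "tables" / name))


def _check_columns(df: pd.DataFrame, cols: list[str], name: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise TableValidationError(f"{name}: missing columns {missing}")
    if df.empty:
        raise TableValidationError(f"{name}: table is empty")


def _check_pct(df: pd.DataFrame, col: str, name: str) -> None:
    bad = df[(df[col] < 0) | (df[col] > 100) | df[col].isna()]
    if not bad.empty:
        raise TableValidationError(
            f"{name}: column {col} out of [0, 100] at rows {list(bad.index)}")


def load_table1(path: str | Path | None = None) -> pd.DataFrame:
    path = path or _default_path("table1.csv")
    df = pd.read_csv(path)
    _check_columns(df, _TABLE1_COLS, "table1")
    for col in ("prevalence_pct", "p_revasc_pct", "p_cabg_pct",
                "p_cath_death_pct"):
        _check_pct(df, col, "table1")
    for col in ("u_revasc_mean", "u_medical_mean"):
        bad = df[(df[col] < 0) | (df[col] > 1)]
        if not bad.empty:
            raise TableValidationError(
                f"table1: utility column {col} outside [0, 1] at rows "
                f"{list(bad.index)}")
    expected = {(s, a, d) for s in SEXES for a in AGE_BANDS
                for d in DISEASE_ANATOMIES}
    got = set(zip(df["sex"], df["age_band"], df["anatomy"]))
    if got != expected:
        raise TableValidationError(
            f"table1: cell mismatch, missing {sorted(expected - got)}, "
            f"unexpected {sorted(got - expected)}")
    # procedural risk / n repeated per anatomy row must agree within a cell
    per_cell = df.groupby(["sex", "age_band"])[
        ["n_subgroup", "p_cath_death_pct"]].nunique()
    if (per_cell > 1).any().any():
        raise TableValidationError(
            "table1: inconsistent n_subgroup/p_cath_death_pct within a "
            "(sex, age_band) cell")
    return df


def load_table2(path: str | Path | None = None) -> pd.DataFrame:
    path = path or _default_path("table2.csv")
    df = pd.read_csv(path)
    _check_columns(df, _TABLE2_COLS, "table2")
    if df["mean"].isna().any() or (df["mean"] <= 0).any():
        raise TableValidationError("table2: non-positive or missing mean cost")
    bad = df[df["ci_low"] > df["ci_high"]]
    if not bad.empty:
        raise TableValidationError(
            f"table2: inverted CI bounds at rows {list(bad.index)}")
    expected = {(a, t, b, y) for a in DISEASE_ANATOMIES for t in TREATMENTS
                for b in AGE_BANDS for y in (1, 2, 3)}
    got = set(zip(df["anatomy"], df["treatment"], df["age_band"], df["year"]))
    if got != expected:
        raise TableValidationError(
            f"table2: cell mismatch, missing {sorted(expected - got)[:5]} ...")
    return df


def load_table3(path: str | Path | None = None) -> pd.DataFrame:
    path = path or _default_path("table3.csv")
    df = pd.read_csv(path)
    _check_columns(df, _TABLE3_COLS, "table3")
    if (df["rr"] <= 0).any():
        raise TableValidationError("table3: non-positive relative risk")
    has_ci = df["ci_low"].notna() & df["ci_high"].notna()
    bad = df[has_ci & (df["ci_low"] > df["ci_high"])]
    if not bad.empty:
        raise TableValidationError(
            f"table3: inverted CI bounds at rows {list(bad.index)}")
    for (scenario, anatomy), grp in df.groupby(["scenario", "anatomy"]):
        grp = grp.sort_values("window_start")
        if grp["window_start"].iloc[0] != 0:
            raise TableValidationError(
                f"table3: {scenario}/{anatomy} windows do not start at 0")
        if (grp["window_start"].values[1:] !=
                grp["window_end"].values[:-1]).any():
            raise TableValidationError(
                f"table3: {scenario}/{anatomy} windows are not contiguous")
    return df


@dataclass(frozen=True)
class ParameterTables:
    """The three validated parameter tables used to assemble model inputs."""

    table1: pd.DataFrame
    table2: pd.DataFrame
    table3: pd.DataFrame


def load_tables(table1: str | Path | None = None,
                table2: str | Path | None = None,
                table3: str | Path | None = None) -> ParameterTables:
    """Load and validate all parameter tables (package copies by default)."""
    return ParameterTables(load_table1(table1), load_table2(table2),
                           load_table3(table3))


def subgroup_counts(table1: pd.DataFrame) -> dict[tuple[str, str], int]:
    """Cohort size per (sex, age band), the default aggregation weights."""
    out = {}
    for (sex, band), grp in table1.groupby(["sex", "age_band"]):
        out[(sex, band)] = int(grp["n_subgroup"].iloc[0])
    return out
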