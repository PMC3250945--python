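"""Shared categorical vocabulary and subgroup keys."""

from __future__ import annotations

from typing import NamedTuple

SEXES = ("male", "female")
AGE_BANDS = ("lt65", "65_75", "gt75")
DISEASE_ANATOMIES = ("left_main", "three_vessel", "one_two_vessel")
HIGH_RISK_ANATOMIES = ("left_main", "three_vessel")
ANATOMIES = DISEASE_ANATOMIES + ("normal",)
TREATMENTS = ("cabg", "pci", "medical")
MANAGEMENTS = ("revascularized", "medical")

#: Representative starting age attached to each published age band.
START_AGES = {"lt65": 57, "65_75": 70, "gt75": 80}

#: RR-schedule scenario families.
RR_SCENARIOS = ("yusuf", "frisc2")


class Subgroup(NamedTuple):
    """Stratification cell used throughout: indication x sex x age band."""

    acs: bool
    sex: str
    age_band: str

    def label(self) -> str:
        return f"{'acs' if self.acs else 'nonacs'}-{self.sex}-{self.age_band}"


class SurvivalKey(NamedTuple):
    """Key for a registry survival curve: subgroup cell plus anatomy/management."""

    acs: bool
    sex: str
    age_band: str
    anatomy: str
    management: str  # "revascularized" | "medical"


def validate_category(value: str, allowed: tuple, what: str) -> str:
    if value not in allowed:
        raise ValueError(f"unknown {what} {value!r}; expected one of {allowed}")
    return value
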