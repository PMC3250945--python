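"""End-to-end orchestration: synthetic registry -> yield fit -> survival ->
Markov model -> scenario grid -> optional PSA, with CSV/plot outputs and a
reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, cea, psa as psa_mod, registry_synth, tables
from .assemble import (build_mortality_library, build_parameter_set,
                       family_results)
from .config import default_config
from .keys import AGE_BANDS, SEXES
from .survival_model import LifeTable
from .yield_model import fit_yield_line, yield_fits_to_frame

log = logging.getLogger("cathcea")


@dataclass
class RunConfig:
    """Configuration for one pipeline run."""

    outdir: str = "cathcea_out"
    seed: int = 0
    n_patients: int = 100_000
    acs_fraction: float = 0.5
    normal_fraction: float = 0.15
    discount_rate: float = tables.DISCOUNT_RATE
    run_sensitivity: bool = True
    run_psa: bool = False
    psa_draws: int = 10_000
    psa_family: str = "acs_yusuf"
    make_plots: bool = True
    subgroups: list = field(default_factory=list)  # e.g. ["acs,female,gt75"]
    table1: str | None = None
    table2: str | None = None
    table3: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    log.info("stage %-12s %.1fs", name, t1 - t0)
    return t1


def mortality_to_frame(library) -> pd.DataFrame:
    rows = []
    for (acs, sex, band, anatomy, mgmt), mort in library.curves.items():
        for t, (q, src) in enumerate(zip(mort.q, mort.source), start=1):
            rows.append({"acs": acs, "sex": sex, "age_band": band,
                         "anatomy": anatomy, "management": mgmt,
                         "cycle": t, "q": q, "source": src})
    for (sex, band), mort in library.population.items():
        for t, q in enumerate(mort.q, start=1):
            rows.append({"acs": "", "sex": sex, "age_band": band,
                         "anatomy": "normal", "management": "medical",
                         "cycle": t, "q": q, "source": "population"})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full pipeline; returns the manifest dictionary."""
    t0 = time.perf_counter()
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    tbls = tables.load_tables(config.table1, config.table2, config.table3)

    synth_cfg = default_config(tbls, seed=config.seed,
                               n_patients=config.n_patients,
                               acs_fraction=config.acs_fraction)
    paths = registry_synth.write_synthetic_dataset(synth_cfg, out / "synth")
    patients = pd.read_csv(paths["patients"])
    regions = pd.read_csv(paths["regions"])
    life = LifeTable(pd.read_csv(paths["lifetable"]))
    t0 = _stage("synth", t0)

    fits = [fit_yield_line(regions, cat)
            for cat in sorted(regions["category"].unique())]
    yield_fits_to_frame(fits).to_csv(out / "yieldfit.csv", index=False)
    t0 = _stage("yield", t0)

    library = build_mortality_library(patients, life)
    mortality_to_frame(library).to_csv(out / "mortality.csv", index=False)
    t0 = _stage("survival", t0)

    base_options = {"normal_fraction": config.normal_fraction,
                    "acs_fraction": config.acs_fraction,
                    "discount_rate": config.discount_rate}
    params = build_parameter_set(tbls, **base_options)
    mix_rows = []
    for sex in SEXES:
        for band in AGE_BANDS:
            from .assemble import anatomy_mix_for
            mix = anatomy_mix_for(params, sex, band)
            mix_rows.append({"sex": sex, "age_band": band,
                             **mix.as_dict(),
                             "high_risk_ratio": mix.high_risk_ratio})
    pd.DataFrame(mix_rows).to_csv(out / "anatomy_mix.csv", index=False)

    table4 = cea.base_case_table(tbls, library, base_options)
    if config.subgroups:
        keep = set()
        for spec in config.subgroups:
            parts = set(spec.split(","))
            for _, row in table4.iterrows():
                if {row["strategy"], row["subgroup"]} & parts:
                    keep.add(row.name)
        table4 = table4.loc[sorted(keep)]
    table4.to_csv(out / "table4.csv", index=False)
    t0 = _stage("markov", t0)

    if config.run_sensitivity:
        table5 = cea.run_scenarios(tbls, library, base_options=base_options)
        table5.to_csv(out / "table5.csv", index=False)
        t0 = _stage("scenarios", t0)

    if config.run_psa:
        acs, rr = cea.FAMILIES[config.psa_family]
        psa_params = build_parameter_set(tbls, rr_scenario=rr,
                                         **base_options)
        specs = psa_mod.default_distribution_specs(psa_params, tbls.table2)
        result = psa_mod.run_psa(psa_params, library, acs, specs,
                                 config.psa_draws, config.seed,
                                 scenario=config.psa_family)
        pd.DataFrame(result.draws,
                     columns=["delta_cost", "delta_qaly"]).to_csv(
            out / "psa_draws.csv", index=False)
        curve = psa_mod.ceac(result)
        pd.DataFrame({"lambda": curve.lambdas,
                      "probability": curve.probability}).to_csv(
            out / "ceac.csv", index=False)
        pd.DataFrame([psa_mod.quadrant_shares(result)]).to_csv(
            out / "quadrants.csv", index=False)
        ell = psa_mod.ellipse_95(result)
        pd.DataFrame([{"center_cost": ell.center[0],
                       "center_qaly": ell.center[1],
                       "semi_major": ell.semi_axes[0],
                       "semi_minor": ell.semi_axes[1],
                       "angle_rad": ell.angle_rad}]).to_csv(
            out / "ellipse.csv", index=False)
        if config.make_plots:
            psa_mod.plot_ce_plane(result, out / "ce_plane.png")
            psa_mod.plot_ceac(curve, out / "ceac.png",
                              label=config.psa_family)
        t0 = _stage("psa", t0)

    config.to_yaml(out / "config.yaml")
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
        "config_sha256": hashlib.sha256(
            json.dumps(asdict(config), sort_keys=True).encode()).hexdigest(),
        "outputs": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    write_summary(out)
    return manifest


def write_summary(outdir: str | Path) -> Path:
    """Human-readable summary mirroring the base-case and scenario grids."""
    out = Path(outdir)
    lines = ["Cost per QALY of increasing the catheterization rate",
             "(2006 CAD per additional catheterization)", ""]
    t4 = out / "table4.csv"
    if t4.exists():
        df = pd.read_csv(t4)
        lines.append("Base case:")
        for _, r in df.iterrows():
            icer_txt = (f"{r['icer']:>12,.0f}" if r["status"] == "icer"
                        else f"{r['status']:>12}")
            lines.append(f"  {r['strategy']:<12} {r['subgroup']:<8} "
                         f"dC={r['delta_cost']:>9,.0f}  "
                         f"dE={r['delta_qaly']:>7.3f}  ICER={icer_txt}")
        lines.append("")
    t5 = out / "table5.csv"
    if t5.exists():
        df = pd.read_csv(t5)
        lines.append("Sensitivity analyses (ICER by scenario and family):")
        for scenario, grp in df.groupby("scenario", sort=False):
            cells = "  ".join(
                f"{r['family']}={'dominated' if r['status'] == 'dominated' else 'dominant' if r['status'] == 'dominant' else format(r['icer'], ',.0f')}"
                for _, r in grp.iterrows())
            lines.append(f"  {scenario:<24} {cells}")
        lines.append("")
    path = out / "summary.txt"
    path.write_text("\n".join(lines))
    return path
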