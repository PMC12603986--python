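"""Pipeline orchestration and the summary surfaces of a study.

``run_pipeline`` drives simulate-or-load -> deconvolute -> calibrate -> fit
-> Monte-Carlo for the luminescence, calorimetry and competition stages and
collects everything into a :class:`PipelineReport`: a per-peptide parameter
table (dissociation constants, lifetimes, ΔG°/ΔH°/−TΔS° with quartiles),
the speciation curves, and the competition ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .competition import analyze_competition, rank_lanthanides
from .errors import ConfigError
from .itc import compute_thermo, fit_itc_global
from .speciation import BindingModel, MixtureComposition, solve_speciation
from .synthetic import PRESETS, ScenarioConfig, generate_competition_panel, \
    generate_itc_scenario, generate_trlfs_scenario
from .trlfs import (calibrate_concentrations, competition_basis,
                    fit_binding_constants, fit_parafac)
from .uncertainty import mc_itc_global, mc_trlfs_pipeline

log = logging.getLogger("lanthafit")

__all__ = ["PipelineReport", "run_pipeline", "species_distribution_table"]


def species_distribution_table(model: BindingModel,
                               compositions: list[MixtureComposition]) -> pd.DataFrame:
    """Per-step metal-basis species fractions along a titration.

    Fractions are of total metal (aquo / 1:1 / 1:2 on a metal-ion basis) and
    sum to 1 at every step with metal present.
    """
    rows = []
    for i, comp in enumerate(compositions):
        st = solve_speciation(comp, model)
        eu = st.eu_species()
        total = eu.sum()
        frac = eu / total if total > 0 else np.zeros(3)
        rows.append({
            "step": i,
            "l_tot_uM": comp.l_tot * 1e6,
            "m_tot_uM": comp.m_tot * 1e6,
            "aquo_uM": eu[0] * 1e6,
            "complex_11_uM": eu[1] * 1e6,
            "complex_12_uM": eu[2] * 1e6,
            "frac_aquo": frac[0],
            "frac_11": frac[1],
            "frac_12": frac[2],
        })
    return pd.DataFrame(rows)


@dataclass
class PipelineReport:
    """Everything a study run produces, with provenance."""

    peptide: str
    seed: int
    parameter_table: pd.DataFrame
    speciation_table: pd.DataFrame | None = None
    competition_table: pd.DataFrame | None = None
    dry_run: bool = False
    plan: list[str] = field(default_factory=list)
    version: str = __version__

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.parameter_table.to_csv(out / "parameters.csv", index=False)
        if self.speciation_table is not None:
            self.speciation_table.to_csv(out / "speciation.csv", index=False)
        if self.competition_table is not None:
            self.competition_table.to_csv(out / "competition.csv", index=False)
        lines = [f"# lanthafit report — {self.peptide}",
                 f"seed: {self.seed}  version: {self.version}", "",
                 self.parameter_table.to_string(index=False)]
        (out / "report.md").write_text("\n".join(lines) + "\n")
        return out


_STAGES = ("trlfs", "itc", "competition")


def run_pipeline(config: dict | str | Path, dry_run: bool = False) -> PipelineReport:
    """Execute a full study from a config mapping or YAML path.

    Config keys: ``peptide`` (preset name), ``seed`` (mandatory), optional
    ``noise``, ``stages`` (subset of trlfs/itc/competition), ``mc_runs``,
    ``n_restarts``, ``out_dir``.  ``dry_run`` validates and returns the
    execution plan without computing.
    """
    if not isinstance(config, dict):
        from .io import read_config
        config = read_config(config)

    peptide = config.get("peptide")
    if peptide not in PRESETS:
        raise ConfigError(f"config field 'peptide' must be one of {sorted(PRESETS)}, "
                          f"got {peptide!r}")
    if "seed" not in config:
        raise ConfigError("config field 'seed' is required")
    try:
        seed = int(config["seed"])
    except (TypeError, ValueError):
        raise ConfigError(f"config field 'seed' must be an integer, got "
                          f"{config['seed']!r}") from None
    stages = tuple(config.get("stages", _STAGES))
    unknown = set(stages) - set(_STAGES)
    if unknown:
        raise ConfigError(f"unknown stages {sorted(unknown)}; valid: {_STAGES}")
    noise = float(config.get("noise", 0.01))
    mc_runs = int(config.get("mc_runs", 100))
    n_restarts = int(config.get("n_restarts", 20))

    scenario = ScenarioConfig(peptide=peptide, seed=seed, noise=noise)
    preset = PRESETS[peptide]
    plan = [f"{s}: simulate({peptide}, seed={seed}, noise={noise}) -> fit -> "
            f"mc(n_runs={mc_runs})" for s in stages]
    if dry_run:
        return PipelineReport(peptide=peptide, seed=seed,
                              parameter_table=pd.DataFrame(), dry_run=True,
                              plan=plan)

    log.info("pipeline start: peptide=%s seed=%d noise=%g version=%s",
             peptide, seed, noise, __version__)
    row: dict[str, float | str] = {"peptide": peptide}
    speciation_table = None
    competition_table = None
    trlfs_artifacts = None

    if "trlfs" in stages:
        data, truth = generate_trlfs_scenario(scenario)
        n_comp = 3 if preset.two_step else 2
        log.info("trlfs: fitting %d components, %d restarts, seed=%d",
                 n_comp, n_restarts, seed)
        fit = fit_parafac(data, n_comp, init_seed=seed, n_restarts=n_restarts)
        calib = calibrate_concentrations(fit, data.compositions)
        binding = fit_binding_constants(calib, data.compositions,
                                        two_step=preset.two_step,
                                        refine_with=data)
        ens = mc_trlfs_pipeline(data, fit, calib, binding,
                                n_runs=mc_runs, seed=seed)
        row["trlfs_kd_11_uM"] = binding.model.kd_11 * 1e6
        row["trlfs_kd_11_q25_uM"], row["trlfs_kd_11_q75_uM"] = [
            v * 1e6 for v in ens.quartile_interval("kd_11")]
        if preset.two_step:
            row["trlfs_kd_12_uM"] = binding.model.kd_12 * 1e6
            row["trlfs_kd_12_q25_uM"], row["trlfs_kd_12_q75_uM"] = [
                v * 1e6 for v in ens.quartile_interval("kd_12")]
        if binding.refined and binding.lifetimes_us is not None:
            labels = ["aquo", "11", "12"][:binding.lifetimes_us.size]
            for lab, tau in zip(labels, binding.lifetimes_us):
                row[f"tau_{lab}_us"] = tau
        else:
            for k, tau in enumerate(fit.lifetimes_us):
                row[f"tau_component_{k}_us"] = tau
        speciation_table = species_distribution_table(binding.model,
                                                      data.compositions)
        trlfs_artifacts = (data, fit, calib, binding)

    if "itc" in stages:
        replicates, truth = generate_itc_scenario(scenario)
        log.info("itc: global fit over %d replicates, seed=%d",
                 len(replicates), seed)
        fit = fit_itc_global(replicates, two_step=preset.two_step,
                             exclude_first=True)
        ens = mc_itc_global(replicates, fit, n_runs=mc_runs, seed=seed,
                            two_step=preset.two_step)
        p = fit.params
        row["itc_kd_11_uM"] = p.model.kd_11 * 1e6
        row["itc_kd_11_q25_uM"], row["itc_kd_11_q75_uM"] = [
            v * 1e6 for v in ens.quartile_interval("kd_11")]
        dg1, mtds1 = compute_thermo(p.model.kd_11, p.dh_1)
        row["dG_1_kJ_mol"] = dg1
        row["dH_1_kJ_mol"] = p.dh_1
        row["minus_TdS_1_kJ_mol"] = mtds1
        if preset.two_step:
            row["itc_kd_12_uM"] = p.model.kd_12 * 1e6
            row["itc_kd_12_q25_uM"], row["itc_kd_12_q75_uM"] = [
                v * 1e6 for v in ens.quartile_interval("kd_12")]
            dg2, mtds2 = compute_thermo(p.model.kd_12, p.dh_2)
            row["dG_2_kJ_mol"] = dg2
            row["dH_2_kJ_mol"] = p.dh_2
            row["minus_TdS_2_kJ_mol"] = mtds2

    if "competition" in stages:
        if trlfs_artifacts is None:
            raise ConfigError("the competition stage needs the trlfs stage "
                              "(its fit is the speciation basis)")
        data, fit, calib, binding = trlfs_artifacts
        basis = competition_basis(data, binding) if binding.refined else calib
        panel, truth = generate_competition_panel(scenario)
        log.info("competition: projecting %d samples, seed=%d", len(panel), seed)
        results = {}
        for ln, (sample, sample_data) in panel.items():
            results[ln] = analyze_competition(
                sample_data, basis, sample=sample,
                n_runs=min(mc_runs, 100), seed=seed)
        competition_table = rank_lanthanides(results)

    report = PipelineReport(peptide=peptide, seed=seed,
                            parameter_table=pd.DataFrame([row]),
                            speciation_table=speciation_table,
                            competition_table=competition_table,
                            plan=plan)
    out_dir = config.get("out_dir")
    if out_dir:
        report.save(out_dir)
        log.info("report written to %s", out_dir)
    return report
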