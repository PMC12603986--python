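"""Synthetic study scenarios: luminescence titrations, calorimetric
replicate sets and lanthanide competition panels with known ground truth.

Every generator composes the forward models of the other modules
(titration bookkeeping -> equilibrium speciation -> signal synthesis) and
returns the data together with a machine-readable truth record, so each
downstream fit can be validated by parameter recovery.  Presets named after
the studied peptides carry the published dissociation constants and
lifetimes as generating truth.

Defaults that stand in for unpublished experimental detail (emission band
shapes, titration concentrations, binding enthalpies) are fixed package
choices documented in the methods note; they emulate the statistical
structure of the measurements, not the instrument.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .competition import CompetitionSample
from .errors import ConfigError
from .itc import ITCProtocol, Thermogram, ThermoParams, simulate_itc
from .speciation import (
    BindingModel,
    MixtureComposition,
    solve_competition_speciation,
    solve_speciation,
)
from .trlfs import SpeciesPhotophysics, TRLFSDataset, normalize_spectrum, simulate_trlfs

__all__ = [
    "PeptidePreset",
    "PRESETS",
    "ScenarioConfig",
    "default_wavelengths",
    "default_delays",
    "default_photophysics",
    "generate_trlfs_scenario",
    "generate_itc_scenario",
    "generate_competition_panel",
]

#: Eu(III)-aquo luminescence lifetime used in all generators (µs); strongly
#: O-H quenched, hence the shortest of the three species.  Configurable.
AQUO_LIFETIME_US = 110.0


@dataclass(frozen=True)
class PeptidePreset:
    """Published ground-truth parameters of one peptide."""

    label: str
    trlfs_kd_11: float | None = None      # molar
    trlfs_kd_12: float | None = None
    tau_11_us: float = 204.0
    tau_12_us: float = 134.0
    itc_kd_11: float | None = None
    itc_kd_12: float | None = None
    dh_1_kj: float = 15.0                 # endothermic step enthalpies
    dh_2_kj: float = 10.0
    two_step: bool = True

    def trlfs_model(self) -> BindingModel:
        if self.trlfs_kd_11 is None:
            raise ConfigError(f"{self.label} has no luminescence-titration preset")
        kd12 = self.trlfs_kd_12 if self.two_step else math.inf
        return BindingModel(kd_11=self.trlfs_kd_11, kd_12=kd12 or math.inf,
                            label=self.label)

    def itc_model(self) -> BindingModel:
        if self.itc_kd_11 is None:
            raise ConfigError(f"{self.label} has no calorimetry preset")
        kd12 = self.itc_kd_12 if self.two_step else math.inf
        return BindingModel(kd_11=self.itc_kd_11, kd_12=kd12 or math.inf,
                            label=self.label)


PRESETS: dict[str, PeptidePreset] = {
    "EF1-R": PeptidePreset("EF1-R",
                           trlfs_kd_11=0.50e-6, trlfs_kd_12=1.1e-6,
                           tau_11_us=204.0, tau_12_us=134.0,
                           itc_kd_11=0.52e-6, itc_kd_12=10.9e-6),
    "EF2-R": PeptidePreset("EF2-R",
                           trlfs_kd_11=0.59e-6, trlfs_kd_12=2.9e-6,
                           tau_11_us=199.0, tau_12_us=131.0,
                           itc_kd_11=0.66e-6, itc_kd_12=13.6e-6),
    "EF3-R": PeptidePreset("EF3-R",
                           trlfs_kd_11=0.32e-6, trlfs_kd_12=1.6e-6,
                           tau_11_us=202.0, tau_12_us=134.0,
                           itc_kd_11=0.30e-6, itc_kd_12=9.3e-6),
    "EF4-R": PeptidePreset("EF4-R",
                           trlfs_kd_11=2.5e-6, trlfs_kd_12=10.8e-6,
                           tau_11_us=201.0, tau_12_us=131.0,
                           itc_kd_11=8.8e-6, itc_kd_12=87e-6),
    # single-point N->D mutant: 150 nM 1:1 affinity by both methods; the 1:2
    # step is set at ~20x the first step, the ratio seen for the other
    # reverse peptides
    "EF4-R_mod": PeptidePreset("EF4-R_mod",
                               trlfs_kd_11=150e-9, trlfs_kd_12=3.0e-6,
                               tau_11_us=201.0, tau_12_us=131.0,
                               itc_kd_11=150e-9, itc_kd_12=3.0e-6),
    # C-terminal methyl ester: carboxylate blocked, 1:1-only binder
    "EF1-R-OMe": PeptidePreset("EF1-R-OMe",
                               trlfs_kd_11=8.6e-6, trlfs_kd_12=None,
                               tau_11_us=204.0,
                               itc_kd_11=31.8e-6, itc_kd_12=None,
                               two_step=False),
}

#: competitor affinity profile across the series, as kd multipliers relative
#: to Eu: a mid-series affinity peak (Nd/Sm strongest), a smooth decline
#: toward Lu, and an out-of-trend strong binder at Yb
LN_KD_FACTORS: dict[str, float] = {
    "La": 4.0, "Ce": 2.5, "Pr": 1.5, "Nd": 0.85, "Sm": 0.90, "Eu": 1.0,
    "Gd": 1.4, "Tb": 2.0, "Dy": 2.8, "Ho": 3.8, "Er": 5.0, "Tm": 6.5,
    "Yb": 2.2, "Lu": 8.0,
}


def default_wavelengths() -> np.ndarray:
    """Emission axis (nm) covering the 7F0/7F1/7F2 Eu bands."""
    return np.arange(570.0, 640.5, 0.5)


def default_delays(n_gates: int = 40, t_max_us: float = 800.0) -> np.ndarray:
    """Delay-gate axis (µs) from t = 0 to t_max.

    40 gates over 0-800 µs cover 4-7 lifetimes of every species while
    keeping several gates per e-folding of the fastest decay.
    """
    return np.linspace(0.0, t_max_us, n_gates)


def _gaussians(wl: np.ndarray, bands: list[tuple[float, float, float]]) -> np.ndarray:
    out = np.zeros_like(wl)
    for centre, width, amp in bands:
        out += amp * np.exp(-0.5 * ((wl - centre) / width) ** 2)
    return out


def default_photophysics(preset: PeptidePreset,
                         wavelengths: np.ndarray | None = None,
                         aquo_lifetime_us: float = AQUO_LIFETIME_US,
                         ) -> list[SpeciesPhotophysics]:
    """Mock species spectra/lifetimes/brightnesses for a preset.

    Gaussian-mixture bands over 570-640 nm: the symmetry-forbidden 7F0 band
    appears only for the low-symmetry complexes, and the hypersensitive 7F2
    band grows relative to 7F1 upon complexation, with clearly different
    7F2 splitting/position for the 1:1 and 1:2 ligand fields — the species
    must be as distinguishable as real deconvoluted Eu spectra are, or the
    emulation would pose a harder problem than the experiment it mirrors.
    Shapes are synthetic, not digitised spectra.  Complexes are brighter
    per mole than the water-quenched aquo ion (2-2.5x).
    """
    wl = default_wavelengths() if wavelengths is None else np.asarray(wavelengths)
    aquo = _gaussians(wl, [(592.0, 3.5, 1.0), (616.0, 4.0, 0.35)])
    lm = _gaussians(wl, [(579.0, 1.5, 0.10), (591.5, 3.0, 1.0),
                         (613.0, 2.5, 2.2), (619.0, 2.5, 1.1)])
    lm2 = _gaussians(wl, [(580.0, 1.2, 0.30), (593.0, 2.8, 1.0),
                          (616.0, 2.0, 0.8), (622.5, 2.5, 3.2)])
    species = [
        SpeciesPhotophysics(normalize_spectrum(aquo, wl),
                            lifetime_us=aquo_lifetime_us,
                            brightness=1.0e5, label="aquo"),
        SpeciesPhotophysics(normalize_spectrum(lm, wl),
                            lifetime_us=preset.tau_11_us,
                            brightness=2.0e5, label="1:1"),
    ]
    if preset.two_step:
        species.append(
            SpeciesPhotophysics(normalize_spectrum(lm2, wl),
                                lifetime_us=preset.tau_12_us,
                                brightness=2.5e5, label="1:2"))
    return species


@dataclass(frozen=True)
class ScenarioConfig:
    """Complete description of one synthetic study scenario.

    The two-regime luminescence design follows the combined titration:
    part 1 raises the peptide at fixed Eu (aquo -> 1:1 transition), part 2
    raises Eu at fixed peptide (1:1 -> 1:2 transition).  The calorimetric
    design is three replicates at different cell peptide concentrations
    sharing one syringe solution.
    """

    peptide: str
    seed: int
    noise: float = 0.01
    # TRLFS two-regime design: peptide additions are dense through the
    # binding transition (titrations resolve KD from curvature there), the
    # Eu additions dense where the second binding step develops
    trlfs_eu_fixed: float = 10e-6
    trlfs_part1_peptide: tuple[float, ...] = tuple(
        x * 1e-6 for x in (0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 6.5, 8.0, 10.0,
                           13.0, 17.0, 22.0, 30.0, 40.0, 50.0))
    trlfs_peptide_fixed: float = 10e-6
    trlfs_part2_eu: tuple[float, ...] = tuple(
        x * 1e-6 for x in (12.0, 15.0, 18.0, 22.0, 27.0, 33.0, 40.0,
                           50.0, 65.0, 80.0))
    n_delay_gates: int = 40
    delay_max_us: float = 800.0
    # ITC three-replicate design
    itc_cell_peptides: tuple[float, ...] = (30e-6, 45e-6, 60e-6)
    itc_syringe_eu: float = 900e-6
    itc_cell_volume_ul: float = 200.0
    itc_n_injections: int = 40
    itc_injection_ul: float = 1.25
    # competition panel
    panel_l_tot: float = 10e-6
    panel_eu: float = 10e-6
    ln_kd_factors: dict[str, float] = field(
        default_factory=lambda: dict(LN_KD_FACTORS))
    aquo_lifetime_us: float = AQUO_LIFETIME_US

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ConfigError("a seed is mandatory for every scenario")
        if len(self.trlfs_part1_peptide) + len(self.trlfs_part2_eu) < 6:
            raise ConfigError("the luminescence design needs >= 6 steps")
        if self.itc_n_injections < 10:
            raise ConfigError("the calorimetric design needs >= 10 injections")
        if self.noise < 0:
            raise ConfigError("noise level must be >= 0")
        if self.peptide not in PRESETS:
            raise ConfigError(
                f"unknown peptide {self.peptide!r}; presets: {sorted(PRESETS)}")

    @property
    def preset(self) -> PeptidePreset:
        return PRESETS[self.peptide]


def two_regime_compositions(config: ScenarioConfig) -> list[MixtureComposition]:
    """Per-step totals of the combined peptide-into-Eu / Eu-into-peptide design."""
    part1 = [MixtureComposition(l_tot=l, m_tot=config.trlfs_eu_fixed)
             for l in config.trlfs_part1_peptide]
    part2 = [MixtureComposition(l_tot=config.trlfs_peptide_fixed, m_tot=m)
             for m in config.trlfs_part2_eu]
    return part1 + part2


def generate_trlfs_scenario(config: ScenarioConfig | str, seed: int | None = None,
                            **overrides) -> tuple[TRLFSDataset, dict]:
    """Simulate the two-regime luminescence titration of one preset.

    Accepts either a full :class:`ScenarioConfig` or a preset name plus a
    seed.  Returns the dataset and a truth record carrying the generating
    binding model, lifetimes, brightnesses and exact speciation.
    """
    config = _as_config(config, seed, overrides)
    preset = config.preset
    model = preset.trlfs_model()
    compositions = two_regime_compositions(config)
    states = [solve_speciation(c, model) for c in compositions]
    wl = default_wavelengths()
    delays = default_delays(config.n_delay_gates, config.delay_max_us)
    photo = default_photophysics(preset, wl, config.aquo_lifetime_us)
    data = simulate_trlfs(states, photo, wl, delays, noise=config.noise,
                          seed=config.seed, compositions=compositions)
    n_sp = len(photo)
    truth = {
        "peptide": preset.label,
        "kd_11": model.kd_11,
        "kd_12": model.kd_12,
        "lifetimes_us": [ph.lifetime_us for ph in photo],
        "brightness": [ph.brightness for ph in photo],
        "spectra": np.stack([ph.spectrum for ph in photo], axis=1),
        "concentrations": np.array([st.eu_species()[:n_sp] for st in states]),
        "states": states,
        "seed": config.seed,
        "noise": config.noise,
    }
    return data, truth


def generate_itc_scenario(config: ScenarioConfig | str, seed: int | None = None,
                          **overrides) -> tuple[list[tuple[ITCProtocol, Thermogram]], dict]:
    """Simulate the three-replicate calorimetric design of one preset."""
    config = _as_config(config, seed, overrides)
    preset = config.preset
    params = ThermoParams(model=preset.itc_model(),
                          dh_1=preset.dh_1_kj,
                          dh_2=preset.dh_2_kj if preset.two_step else 0.0,
                          q_dil=0.5)
    rng = np.random.default_rng(config.seed)
    replicates = []
    for cell_l in config.itc_cell_peptides:
        protocol = ITCProtocol(
            cell_volume_ul=config.itc_cell_volume_ul,
            cell_peptide=cell_l,
            syringe_metal=config.itc_syringe_eu,
            injection_volumes_ul=(config.itc_injection_ul,) * config.itc_n_injections,
        )
        thermo = simulate_itc(protocol, params, noise=config.noise,
                              seed=int(rng.integers(0, 2**31 - 1)))
        replicates.append((protocol, thermo))
    truth = {
        "peptide": preset.label,
        "kd_11": params.model.kd_11,
        "kd_12": params.model.kd_12,
        "dh_1": params.dh_1,
        "dh_2": params.dh_2,
        "q_dil": params.q_dil,
        "two_step": preset.two_step,
        "seed": config.seed,
        "noise": config.noise,
    }
    return replicates, truth


def generate_competition_panel(config: ScenarioConfig | str, seed: int | None = None,
                               **overrides) -> tuple[dict[str, tuple[CompetitionSample, TRLFSDataset]], dict]:
    """Simulate one equimolar Eu/Ln competition sample per lanthanide.

    The competitor is spectroscopically silent: only the Eu species emit.
    Competitor binding models scale the peptide's Eu dissociation constants
    by the per-element factors in the config.
    """
    config = _as_config(config, seed, overrides)
    preset = config.preset
    model = preset.trlfs_model()
    wl = default_wavelengths()
    delays = default_delays(config.n_delay_gates, config.delay_max_us)
    photo = default_photophysics(preset, wl, config.aquo_lifetime_us)
    rng = np.random.default_rng(config.seed)
    panel: dict[str, tuple[CompetitionSample, TRLFSDataset]] = {}
    truths: dict[str, dict] = {}
    for ln, factor in config.ln_kd_factors.items():
        comp_model = BindingModel(kd_11=model.kd_11 * factor,
                                  kd_12=(model.kd_12 * factor
                                         if model.is_two_step else math.inf),
                                  label=ln)
        sample = CompetitionSample(peptide=preset.label, ln_identity=ln,
                                   l_tot=config.panel_l_tot,
                                   m_tot=config.panel_eu,
                                   n_tot=config.panel_eu)
        mixture = MixtureComposition(l_tot=sample.l_tot, m_tot=sample.m_tot,
                                     n_tot=sample.n_tot,
                                     competitor_model=comp_model)
        state = solve_competition_speciation(mixture, model)
        data = simulate_trlfs([state], photo, wl, delays, noise=config.noise,
                              seed=int(rng.integers(0, 2**31 - 1)),
                              compositions=[mixture])
        panel[ln] = (sample, data)
        eu = state.eu_species()[:len(photo)]
        complexed = eu[1:].sum()
        truths[ln] = {
            "kd_factor": factor,
            "state": state,
            "true_ratio": float(eu[0] / complexed) if complexed > 0 else math.inf,
        }
    truth = {
        "peptide": preset.label,
        "kd_11": model.kd_11,
        "kd_12": model.kd_12,
        "per_ln": truths,
        "seed": config.seed,
        "noise": config.noise,
    }
    return panel, truth


def _as_config(config: ScenarioConfig | str, seed: int | None,
               overrides: dict) -> ScenarioConfig:
    if isinstance(config, ScenarioConfig):
        if seed is not None or overrides:
            updates = dict(overrides)
            if seed is not None:
                updates["seed"] = seed
            config = replace(config, **updates)
        return config
    if seed is None:
        raise ConfigError("a seed is mandatory for every scenario")
    return ScenarioConfig(peptide=config, seed=seed, **overrides)
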