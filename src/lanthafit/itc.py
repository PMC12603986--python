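"""Isothermal titration calorimetry: injection-heat model and global fit.

Each injection of metal into the peptide cell shifts the binding equilibria;
the measured integrated heat is the enthalpy released/absorbed by the moles
of each complex formed between consecutive equilibria::

    q_i = dh_1 * Δn_i(LM) + dh_2 * Δn_i(LM2) + q_dil

Δn counts complex formed in the (fixed-volume, overflow) cell *including*
the material carried out by the displaced liquid — complex leaving the cell
was formed and its heat recorded, so the bookkeeping tracks cumulative moles
formed, not just cell content.  Sequential binding is endothermic for these
peptides (dh > 0) while ΔG° < 0: entropy-driven complexation.

The global fit shares kd_11, kd_12, dh_1, dh_2 across replicates measured at
different cell peptide concentrations and keeps one dilution-heat offset per
replicate; dissociation constants are optimised on a log10 scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import InputError, NumericalError
from .speciation import (
    BindingModel,
    TitrationProtocol,
    expelled_moles,
    solve_speciation,
    titration_path,
)
from .units import R_GAS

__all__ = [
    "ITCProtocol",
    "Thermogram",
    "ThermoParams",
    "ITCFitResult",
    "simulate_itc",
    "fit_itc_global",
    "compute_thermo",
]


@dataclass(frozen=True)
class ITCProtocol:
    """Injection schedule of one calorimetric titration."""

    cell_volume_ul: float
    cell_peptide: float          # molar
    syringe_metal: float         # molar
    injection_volumes_ul: tuple[float, ...]
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not (self.cell_volume_ul > 0 and self.temperature > 0):
            raise InputError("cell volume and temperature must be positive")
        if self.cell_peptide < 0 or self.syringe_metal < 0:
            raise InputError("concentrations must be >= 0")
        if len(self.injection_volumes_ul) < 2:
            raise InputError("need at least two injections")

    def to_titration(self) -> TitrationProtocol:
        return TitrationProtocol(
            cell_volume_ul=self.cell_volume_ul,
            cell={"l": self.cell_peptide},
            syringe={"m": self.syringe_metal},
            injection_volumes_ul=tuple(self.injection_volumes_ul),
            mode="overflow",
            temperature=self.temperature,
        )


@dataclass
class Thermogram:
    """Integrated heat per injection (µJ) plus the analysis mask."""

    heats: np.ndarray
    included: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.heats = np.asarray(self.heats, dtype=float)
        if self.included is None:
            self.included = np.ones(self.heats.size, dtype=bool)
        else:
            self.included = np.asarray(self.included, dtype=bool)
            if self.included.size != self.heats.size:
                raise InputError("included mask length must match heats")


@dataclass(frozen=True)
class ThermoParams:
    """Thermodynamic parameters of the two-step binding model.

    ΔG° and −TΔS° are derived on demand (:func:`compute_thermo`), never
    stored, so they cannot drift out of sync with kd and ΔH.
    """

    model: BindingModel
    dh_1: float                 # kJ/mol, step 1
    dh_2: float = 0.0           # kJ/mol, step 2
    q_dil: float = 0.0          # µJ per injection

    def __post_init__(self) -> None:
        for v in (self.dh_1, self.dh_2, self.q_dil):
            if not math.isfinite(v):
                raise InputError("thermodynamic parameters must be finite")


def compute_thermo(kd: float, dh: float,
                   temperature: float = 298.15) -> tuple[float, float]:
    """Standard free energy and entropic term from kd and ΔH.

    Returns ``(ΔG°, −TΔS°)`` in kJ/mol with ``ΔG° = R T ln(kd)`` (kd in
    molar; the dissociation direction makes tighter binding more negative)
    and ``−TΔS° = ΔG° − ΔH°``.
    """
    if not kd > 0:
        raise InputError(f"kd must be positive, got {kd}")
    dg = R_GAS * temperature * math.log(kd) / 1000.0
    return dg, dg - dh


def _complex_moles_formed(protocol: ITCProtocol,
                          model: BindingModel) -> tuple[np.ndarray, np.ndarray]:
    """Per-injection moles of LM and LM2 formed, displacement included."""
    path = titration_path(protocol.to_titration())
    states = [solve_speciation(c, model) for c in path]
    v_cell_l = protocol.cell_volume_ul * 1e-6  # litres
    tit = protocol.to_titration()
    d1 = np.empty(len(path) - 1)
    d2 = np.empty(len(path) - 1)
    for i, v in enumerate(protocol.injection_volumes_ul):
        prev, cur = states[i], states[i + 1]
        d1[i] = (cur.c_lm - prev.c_lm) * v_cell_l + expelled_moles(
            tit, prev.c_lm, cur.c_lm, v)
        d2[i] = (cur.c_lm2 - prev.c_lm2) * v_cell_l + expelled_moles(
            tit, prev.c_lm2, cur.c_lm2, v)
    return d1, d2


def simulate_itc(protocol: ITCProtocol, params: ThermoParams,
                 noise: float = 0.0, seed: int | None = None) -> Thermogram:
    """Forward-simulate integrated injection heats (µJ).

    Noise is additive Gaussian with sigma = ``noise`` times the maximum
    absolute clean heat (a fraction of full scale, the natural way to quote
    calorimeter noise).
    """
    if noise < 0:
        raise InputError("noise level must be >= 0")
    d1, d2 = _complex_moles_formed(protocol, params.model)
    # kJ/mol * mol = kJ -> µJ
    heats = (params.dh_1 * d1 + params.dh_2 * d2) * 1e9 + params.q_dil
    if noise > 0:
        rng = np.random.default_rng(seed)
        sigma = noise * np.max(np.abs(heats)) if np.any(heats) else noise
        heats = heats + rng.normal(0.0, sigma, heats.shape)
    return Thermogram(heats=heats)


@dataclass
class ITCFitResult:
    """Global-fit output: shared thermodynamics plus per-replicate pieces."""

    params: ThermoParams
    q_dil: np.ndarray                # per replicate, µJ
    residuals: list[np.ndarray]      # per replicate, included injections only
    rss: float
    at_bound: dict[str, bool]
    n_obs: int

    @property
    def flagged(self) -> bool:
        return any(self.at_bound.values())


def fit_itc_global(replicates: list[tuple[ITCProtocol, Thermogram]],
                   two_step: bool = True,
                   exclude_first: bool = True,
                   kd_log10_bounds: tuple[float, float] = (-10.0, -2.0),
                   weighting: str = "uniform",
                   x0: np.ndarray | None = None) -> ITCFitResult:
    """Global weighted least squares across calorimetric replicates.

    kd_11, kd_12 (two-step model), dh_1, dh_2 are shared; each replicate
    gets its own per-injection dilution heat.  The first injection is
    excluded by default (syringe-tip diffusion artefact).  With
    ``weighting="auto"`` a per-replicate noise scale is estimated from
    late-titration residuals of a first uniform pass and the fit repeated.

    ``at_bound`` flags a step the data cannot support: a fitted log-kd
    within 1e-3 of a search bound, or — for the second step — a two-step
    fit that does not reduce the residual meaningfully over the nested
    one-site fit (fitting a two-step model to a 1:1-only binder either
    pushes kd_12 to the upper bound or invents a weak step that only
    absorbs noise; the nested comparison catches both).
    """
    if not replicates:
        raise InputError("at least one replicate is required")
    masks = []
    for protocol, thermo in replicates:
        if thermo.heats.size != len(protocol.injection_volumes_ul):
            raise InputError("thermogram length does not match protocol")
        mask = thermo.included.copy()
        if exclude_first:
            mask[0] = False
        masks.append(mask)
    obs = [t.heats[m] for (_, t), m in zip(replicates, masks)]
    if all(np.ptp(o) == 0 for o in obs):
        raise InputError("all heats identical in every replicate; singular design")

    lo, hi = kd_log10_bounds
    n_rep = len(replicates)
    n_kd = 2 if two_step else 1
    # parameter vector: [log10 kd_11 (, log10 kd_12), dh_1 (, dh_2), q_dil * n_rep]

    def unpack(p: np.ndarray) -> tuple[BindingModel, float, float, np.ndarray]:
        kd11 = 10.0 ** p[0]
        kd12 = 10.0 ** p[1] if two_step else math.inf
        dh1 = p[n_kd]
        dh2 = p[n_kd + 1] if two_step else 0.0
        qd = p[n_kd * 2:]
        return BindingModel(kd_11=kd11, kd_12=kd12), dh1, dh2, qd

    def model_heats(p: np.ndarray) -> list[np.ndarray]:
        model, dh1, dh2, qd = unpack(p)
        out = []
        for r, (protocol, _) in enumerate(replicates):
            d1, d2 = _complex_moles_formed(protocol, model)
            out.append((dh1 * d1 + dh2 * d2) * 1e9 + qd[r])
        return out

    heat_scale = max(float(np.max(np.abs(np.concatenate(obs)))), 1e-12)
    weights = [np.ones(o.size) / heat_scale for o in obs]

    def resid(p: np.ndarray) -> np.ndarray:
        mh = model_heats(p)
        return np.concatenate([
            (mh[r][masks[r]] - obs[r]) * weights[r] for r in range(n_rep)
        ])

    if x0 is None:
        dh_guess = heat_scale * 1e-9 / max(
            replicates[0][0].cell_peptide * replicates[0][0].cell_volume_ul * 1e-6,
            1e-15)
        starts = []
        for k1 in (-7.0, -6.0, -5.0):
            base = [k1] + ([k1 + 1.5] if two_step else [])
            base += [dh_guess] + ([dh_guess / 2] if two_step else [])
            starts.append(np.array(base + [0.0] * n_rep))
    else:
        starts = [np.asarray(x0, dtype=float)]

    lower = np.array([lo] * n_kd + [-1e4] * n_kd + [-1e6] * n_rep)
    upper = np.array([hi] * n_kd + [1e4] * n_kd + [1e6] * n_rep)
    best = None
    for s in starts:
        sol = least_squares(resid, x0=np.clip(s, lower, upper),
                            bounds=(lower, upper))
        if best is None or sol.cost < best.cost:
            best = sol
    assert best is not None
    if not best.success:
        raise NumericalError(f"ITC global fit failed: {best.message}")

    if weighting == "auto":
        # second pass: per-replicate sigma from the flattest (late) third
        mh = model_heats(best.x)
        for r in range(n_rep):
            res_r = (mh[r][masks[r]] - obs[r])
            tail = res_r[-max(3, res_r.size // 3):]
            sigma = max(float(np.std(tail)), 1e-9)
            weights[r] = np.ones(obs[r].size) / sigma
        sol = least_squares(resid, x0=best.x, bounds=(lower, upper))
        if sol.success:
            best = sol

    p = best.x
    model, dh1, dh2, qd = unpack(p)
    mh = model_heats(p)
    residuals = [mh[r][masks[r]] - obs[r] for r in range(n_rep)]
    rss = float(sum(np.sum(r**2) for r in residuals))
    at_bound = {"kd_11": bool(min(p[0] - lo, hi - p[0]) < 1e-3)}
    if two_step:
        at_bound["kd_12"] = bool(min(p[1] - lo, hi - p[1]) < 1e-3)
        if not at_bound["kd_12"] and x0 is None:
            # nested-model check: an unsupported second step improves the
            # residual no more than fitting noise would
            reduced = fit_itc_global(replicates, two_step=False,
                                     exclude_first=exclude_first,
                                     kd_log10_bounds=kd_log10_bounds,
                                     weighting=weighting)
            if rss > 0.95 * reduced.rss:
                at_bound["kd_12"] = True
    params = ThermoParams(model=model, dh_1=dh1, dh_2=dh2,
                          q_dil=float(np.mean(qd)))
    return ITCFitResult(params=params, q_dil=qd, residuals=residuals,
                        rss=rss, at_bound=at_bound,
                        n_obs=sum(int(m.sum()) for m in masks))
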