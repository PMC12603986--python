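"""Equilibrium speciation for sequential metal:peptide binding.

The chemical model is the two-step sequence observed for EF-hand loop
peptides binding trivalent lanthanides::

    L + M  <=>  LM      kd_11 = [L][M] / [LM]
    LM + M <=>  LM2     kd_12 = [LM][M] / [LM2]

with stepwise *dissociation* constants in molar units (smaller = tighter).
``LM2`` is one peptide accommodating two metal ions.  A competition variant
adds a second metal N with its own two-step model on the same peptide;
hetero-bimetallic species (one peptide holding one M and one N) are not part
of the model.

Given the free metal concentration ``m`` the free ligand follows in closed
form, so the single-metal problem reduces to one monotone scalar
mass-balance equation in ``m``, solved by a safeguarded Newton iteration
with a bisection fallback (the root is always bracketed by ``[0, m_tot]``).
The two-metal problem nests two such monotone solves.

Concentrations are treated as activities (constant ionic strength
background); protonation side-equilibria are outside the model.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import InputError, NumericalError, ProtocolError

__all__ = [
    "BindingModel",
    "MixtureComposition",
    "SpeciationState",
    "TitrationProtocol",
    "solve_speciation",
    "solve_competition_speciation",
    "titration_path",
]


@dataclass(frozen=True)
class BindingModel:
    """Stepwise dissociation constants (molar) of a peptide for one metal.

    ``kd_12 = inf`` expresses a 1:1-only binder (no second metal uptake),
    the limit in which the model collapses to the single-site quadratic.
    """

    kd_11: float
    kd_12: float = math.inf
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.kd_11 > 0 and math.isfinite(self.kd_11)):
            raise InputError(f"kd_11 must be positive and finite, got {self.kd_11}")
        if not self.kd_12 > 0 or math.isnan(self.kd_12):
            raise InputError(f"kd_12 must be positive, got {self.kd_12}")

    @property
    def is_two_step(self) -> bool:
        return math.isfinite(self.kd_12)


@dataclass(frozen=True)
class MixtureComposition:
    """Total (analytical) concentrations of one sample, molar."""

    l_tot: float
    m_tot: float
    n_tot: float = 0.0
    competitor_model: BindingModel | None = None
    temperature: float = 298.15

    def __post_init__(self) -> None:
        for name in ("l_tot", "m_tot", "n_tot"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise InputError(f"{name} must be finite and >= 0, got {v}")
        if (self.n_tot > 0) != (self.competitor_model is not None):
            raise InputError(
                "competitor_model must be given exactly when n_tot > 0 "
                f"(n_tot={self.n_tot}, model={self.competitor_model})"
            )
        if not self.temperature > 0:
            raise InputError("temperature must be positive kelvin")


@dataclass(frozen=True)
class SpeciationState:
    """Equilibrium concentrations (molar) of every species in the mixture."""

    free_l: float
    free_m: float
    c_lm: float
    c_lm2: float
    free_n: float = 0.0
    c_ln: float = 0.0
    c_ln2: float = 0.0

    @property
    def bound_m(self) -> float:
        """Metal M sequestered in complexes (metal-ion basis)."""
        return self.c_lm + 2.0 * self.c_lm2

    def eu_species(self) -> np.ndarray:
        """Primary-metal concentrations per luminescent species.

        Returns ``[free M, M in LM, M in LM2]`` — the metal-ion-basis
        amounts whose sum closes the metal balance exactly.
        """
        return np.array([self.free_m, self.c_lm, 2.0 * self.c_lm2])


def _binding_polys(m: float, model: BindingModel) -> tuple[float, float]:
    """Return (b, bm): bound-ligand and bound-metal factors per free ligand.

    [LM] + [LM2] = L*b(m),   [LM] + 2[LM2] = L*bm(m).
    """
    x = m / model.kd_11
    if model.is_two_step:
        y = x * m / model.kd_12
    else:
        y = 0.0
    return x + y, x + 2.0 * y


def _mass_balance(m: float, comp_l: float, comp_m: float, model: BindingModel,
                  extra_b: float = 0.0) -> tuple[float, float]:
    """Metal balance residual g(m) and its derivative.

    ``extra_b`` adds a (fixed) bound-ligand factor from a second metal so the
    same kernel serves the competition inner solve.
    """
    b, bm = _binding_polys(m, model)
    denom = 1.0 + b + extra_b
    L = comp_l / denom
    g = m + L * bm - comp_m
    # derivatives of b, bm w.r.t. m
    db = 1.0 / model.kd_11
    dbm = 1.0 / model.kd_11
    if model.is_two_step:
        q = 2.0 * m / (model.kd_11 * model.kd_12)
        db += q
        dbm += 2.0 * q
    dL = -comp_l * db / denom**2
    dg = 1.0 + dL * bm + L * dbm
    return g, dg


def _solve_free_metal(l_tot: float, m_tot: float, model: BindingModel,
                      extra_b: float = 0.0, tol: float = 1e-12,
                      max_iter: int = 200) -> float:
    """Safeguarded Newton for the scalar metal balance on [0, m_tot].

    g is continuous and strictly increasing with g(0) = -m_tot <= 0 and
    g(m_tot) >= 0, so the bracket always holds; Newton steps falling outside
    the current bracket are replaced by bisection.  ``tol`` is absolute on
    the balance residual, scaled by m_tot.
    """
    if m_tot == 0.0:
        return 0.0
    lo, hi = 0.0, m_tot
    m = m_tot * 0.5
    scale = m_tot
    for _ in range(max_iter):
        g, dg = _mass_balance(m, l_tot, m_tot, model, extra_b)
        if abs(g) <= tol * scale:
            return m
        if g > 0:
            hi = m
        else:
            lo = m
        step_ok = dg > 0 and math.isfinite(dg)
        m_new = m - g / dg if step_ok else 0.5 * (lo + hi)
        if not (lo < m_new < hi):
            m_new = 0.5 * (lo + hi)
        if m_new == m:  # bracket collapsed to machine precision
            return m
        m = m_new
    g, _ = _mass_balance(m, l_tot, m_tot, model, extra_b)
    if abs(g) <= 1e-8 * scale:
        return m
    raise NumericalError(
        f"speciation solver did not converge (l_tot={l_tot}, m_tot={m_tot}, "
        f"kd_11={model.kd_11}, kd_12={model.kd_12}, residual={g})"
    )


def solve_speciation(comp: MixtureComposition, model: BindingModel,
                     tol: float = 1e-12) -> SpeciationState:
    """Solve the single-metal equilibrium for one mixture composition.

    Parameters
    ----------
    comp
        Total concentrations; must not contain a competitor metal.
    model
        Stepwise dissociation constants of the peptide for the metal.
    tol
        Absolute tolerance on the metal-balance residual, relative to
        ``m_tot``.

    Returns
    -------
    SpeciationState
        The unique non-negative equilibrium.
    """
    if comp.n_tot > 0:
        raise InputError("composition has a competitor; use solve_competition_speciation")
    m = _solve_free_metal(comp.l_tot, comp.m_tot, model, tol=tol)
    b, bm = _binding_polys(m, model)
    free_l = comp.l_tot / (1.0 + b)
    c_lm = free_l * m / model.kd_11
    c_lm2 = c_lm * m / model.kd_12 if model.is_two_step else 0.0
    return SpeciationState(free_l=free_l, free_m=m, c_lm=c_lm, c_lm2=c_lm2)


def solve_competition_speciation(comp: MixtureComposition, model: BindingModel,
                                 tol: float = 1e-12) -> SpeciationState:
    """Solve the two-metal competition equilibrium.

    Species set {L, M, N, LM, LM2, LN, LN2}: both metals form their own
    homometallic 1:1 and 1:2 complexes with the shared peptide.  The outer
    balance in free N brackets on [0, n_tot]; each evaluation solves the
    inner M balance (closed-form ligand elimination) by the safeguarded
    Newton kernel.
    """
    if comp.n_tot == 0.0:
        return solve_speciation(comp, model, tol=tol)
    nmodel = comp.competitor_model
    assert nmodel is not None  # enforced by MixtureComposition

    def inner_m(n: float) -> float:
        extra_b, _ = _binding_polys(n, nmodel)
        return _solve_free_metal(comp.l_tot, comp.m_tot, model, extra_b, tol=tol)

    def outer(n: float) -> float:
        m = inner_m(n)
        b_m, _ = _binding_polys(m, model)
        b_n, bm_n = _binding_polys(n, nmodel)
        L = comp.l_tot / (1.0 + b_m + b_n)
        return n + L * bm_n - comp.n_tot

    lo, hi = 0.0, comp.n_tot
    n = 0.5 * comp.n_tot
    scale = comp.n_tot
    for _ in range(200):
        g = outer(n)
        if abs(g) <= tol * scale:
            break
        if g > 0:
            hi = n
        else:
            lo = n
        n = 0.5 * (lo + hi)
        if hi - lo <= 1e-17 * scale:
            break
    else:
        raise NumericalError(
            f"competition solver did not converge (l_tot={comp.l_tot}, "
            f"m_tot={comp.m_tot}, n_tot={comp.n_tot})"
        )
    m = inner_m(n)
    b_m, _ = _binding_polys(m, model)
    b_n, _ = _binding_polys(n, nmodel)
    free_l = comp.l_tot / (1.0 + b_m + b_n)
    c_lm = free_l * m / model.kd_11
    c_lm2 = c_lm * m / model.kd_12 if model.is_two_step else 0.0
    c_ln = free_l * n / nmodel.kd_11
    c_ln2 = c_ln * n / nmodel.kd_12 if nmodel.is_two_step else 0.0
    return SpeciationState(free_l=free_l, free_m=m, c_lm=c_lm, c_lm2=c_lm2,
                           free_n=n, c_ln=c_ln, c_ln2=c_ln2)


@dataclass(frozen=True)
class TitrationProtocol:
    """Per-step additions from a syringe into a cell.

    ``cell`` / ``syringe`` map component names ("l", "m", "n") to molar
    totals.  Two mixing modes:

    - ``"additive"``: the cell volume grows; totals follow exact
      conservation ``c -> (c V + c_syr v) / (V + v)``.
    - ``"overflow"``: a fixed-volume perfusion cell; each injection expels
      an equal volume of (partially mixed) contents, modelled with the
      standard trapezoidal displacement factor
      ``c -> [c (V - v/2) + c_syr v] / (V + v/2)``.
    """

    cell_volume_ul: float
    cell: dict[str, float]
    syringe: dict[str, float]
    injection_volumes_ul: tuple[float, ...]
    mode: str = "overflow"
    max_injected_fraction: float = 0.5
    temperature: float = 298.15
    competitor_model: BindingModel | None = None

    def __post_init__(self) -> None:
        if not self.cell_volume_ul > 0:
            raise ProtocolError("cell volume must be positive")
        if len(self.injection_volumes_ul) == 0:
            raise ProtocolError("injection schedule is empty")
        if any(v < 0 for v in self.injection_volumes_ul):
            raise ProtocolError("injection volumes must be >= 0")
        if self.mode not in ("overflow", "additive"):
            raise ProtocolError(f"unknown mixing mode {self.mode!r}")
        if self.mode == "overflow":
            injected = sum(self.injection_volumes_ul)
            limit = self.max_injected_fraction * self.cell_volume_ul
            if injected > limit:
                raise ProtocolError(
                    f"cumulative injection {injected} µL exceeds limit {limit} µL"
                )


def titration_path(protocol: TitrationProtocol) -> list[MixtureComposition]:
    """Per-step total concentrations along a titration, dilution included.

    Returns one composition per state: the initial cell contents followed by
    the state after each injection (length ``len(injections) + 1``).
    """
    comps = {k: float(protocol.cell.get(k, 0.0)) for k in ("l", "m", "n")}
    syr = {k: float(protocol.syringe.get(k, 0.0)) for k in ("l", "m", "n")}
    V = protocol.cell_volume_ul

    def state() -> MixtureComposition:
        has_n = comps["n"] > 0
        return MixtureComposition(
            l_tot=comps["l"], m_tot=comps["m"], n_tot=comps["n"],
            competitor_model=protocol.competitor_model if has_n else None,
            temperature=protocol.temperature,
        )

    path = [state()]
    for v in protocol.injection_volumes_ul:
        if protocol.mode == "additive":
            for k in comps:
                comps[k] = (comps[k] * V + syr[k] * v) / (V + v)
            V = V + v
        else:  # overflow, trapezoidal displacement
            for k in comps:
                comps[k] = (comps[k] * (V - v / 2.0) + syr[k] * v) / (V + v / 2.0)
        path.append(state())
    return path


def expelled_moles(protocol: TitrationProtocol,
                   conc_before: float, conc_after: float, v_ul: float) -> float:
    """Moles of a species expelled by one overflow injection.

    The trapezoidal displacement model expels volume ``v`` at the average of
    the pre- and post-injection concentrations.  Volumes in µL, result in
    moles.
    """
    return 0.5 * (conc_before + conc_after) * v_ul * 1e-6


def dilute_only(comp: MixtureComposition, factor: float) -> MixtureComposition:
    """Scale all totals of a composition by a dilution factor."""
    return replace(comp, l_tot=comp.l_tot * factor, m_tot=comp.m_tot * factor,
                   n_tot=comp.n_tot * factor)
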