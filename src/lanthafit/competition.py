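"""Relative lanthanide affinities from Eu competition measurements.

One sample per lanthanide: peptide mixed with an equimolar EuCl3/LnCl3
solution, measured once by time-resolved luminescence with Eu-selective
excitation (the competitor is spectroscopically silent at 394 nm).  The
spectral and temporal factors of the peptide's own Eu titration serve as a
frozen speciation basis: only the concentration mode is re-estimated by
non-negative least squares.  The readout per lanthanide is the ratio of
Eu-aquo to complexed Eu (1:1 and 1:2 pooled) — the stronger the competitor,
the more Eu it displaces into the aquo pool and the larger the ratio.

Quartile uncertainty comes from the shared parametric bootstrap applied to
the projection step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .trlfs import CalibrationResult, TrilinearFit, project_onto_basis
from .uncertainty import MCEnsemble, mc_refit

__all__ = [
    "LANTHANIDES",
    "CompetitionSample",
    "RelativeAffinityResult",
    "analyze_competition",
    "rank_lanthanides",
]

#: the 14 studied lanthanides in atomic-number order (Pm is radioactive and skipped)
LANTHANIDES = ("La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd",
               "Tb", "Dy", "Ho", "Er", "Tm", "Yb", "Lu")

#: smallest complexed-Eu concentration used when forming the ratio, so an
#: (essentially) aquo-only sample yields a large but finite, flagged ratio
RATIO_FLOOR_FRAC = 1e-6


@dataclass(frozen=True)
class CompetitionSample:
    """One peptide + Eu + competitor lanthanide mixture (molar totals)."""

    peptide: str
    ln_identity: str
    l_tot: float
    m_tot: float          # Eu
    n_tot: float          # competitor Ln

    def __post_init__(self) -> None:
        if self.ln_identity not in LANTHANIDES:
            raise InputError(f"unknown lanthanide {self.ln_identity!r}")
        if not math.isclose(self.m_tot, self.n_tot, rel_tol=1e-9):
            raise InputError(
                "the competition design is equimolar: m_tot must equal n_tot")
        if min(self.l_tot, self.m_tot, self.n_tot) < 0:
            raise InputError("totals must be >= 0")


@dataclass
class RelativeAffinityResult:
    """Aquo/complexed Eu ratio for one competitor, with MC quartiles."""

    ln_identity: str
    ratio: float
    median: float
    q25: float
    q75: float
    floored: bool
    projection_residual: float
    basis_mismatch: bool
    ensemble: MCEnsemble | None = None

    def __post_init__(self) -> None:
        if self.ratio < 0:
            raise InputError("ratio must be >= 0")
        if not self.q25 <= self.median <= self.q75:
            raise InputError("quantiles out of order")


def _ratio_from_amplitudes(amps: np.ndarray, inv_brightness: np.ndarray,
                           aquo_idx: int, m_tot: float) -> tuple[float, bool]:
    conc = amps * inv_brightness
    aquo = conc[aquo_idx]
    complexed = conc.sum() - aquo
    floor = RATIO_FLOOR_FRAC * max(m_tot, conc.sum(), 1e-30)
    floored = complexed < floor
    return float(aquo / max(complexed, floor)), floored


def analyze_competition(sample_tensor, basis: CalibrationResult,
                        sample: CompetitionSample | None = None,
                        residual_threshold: float = 0.2,
                        n_runs: int = 100, seed: int = 0,
                        aquo_index: int | None = None) -> RelativeAffinityResult:
    """Project one competition measurement onto the Eu titration basis.

    Parameters
    ----------
    sample_tensor
        A single-step measurement: either a (wavelength, delay) slab or a
        ``TRLFSDataset`` with one step, on the same axes as the basis.
    basis
        Calibrated trilinear fit of the same peptide's Eu titration; its
        spectral and temporal factors are frozen, and its brightnesses turn
        projected amplitudes into Eu concentrations.
    aquo_index
        Which basis component is the aquo ion.  Defaults to the shortest
        lifetime (O-H quenching makes the fully hydrated ion the fastest
        decaying species).
    """
    fit: TrilinearFit = basis.fit
    slab = np.asarray(getattr(sample_tensor, "intensity", sample_tensor),
                      dtype=float)
    if slab.ndim == 3:
        if slab.shape[0] != 1:
            raise InputError("competition samples are single measurements")
        slab = slab[0]
    if slab.shape != (fit.wavelengths.size, fit.delays.size):
        raise InputError("sample tensor does not match the basis axes")

    if aquo_index is None:
        aquo_index = int(np.argmin(fit.lifetimes_us))
    with np.errstate(divide="ignore"):
        inv_b = np.where(np.isfinite(basis.brightness),
                         1.0 / basis.brightness, 0.0)
    m_tot = sample.m_tot if sample is not None else 0.0

    amps, rel_resid = project_onto_basis(slab, fit)
    ratio, floored = _ratio_from_amplitudes(amps, inv_b, aquo_index, m_tot)

    # parametric bootstrap on the projection: surrogate slabs are the
    # projected reconstruction plus noise at the projection-residual scale
    recon = np.einsum("r,jr,kr->jk", amps, fit.spectral_loadings,
                      fit.temporal_loadings)
    sigma = rel_resid * float(np.linalg.norm(slab)) / math.sqrt(slab.size)

    def perturb(s, rng):
        return recon + rng.normal(0.0, sigma, recon.shape)

    def refit(s):
        a, _ = project_onto_basis(s, fit)
        r, _ = _ratio_from_amplitudes(a, inv_b, aquo_index, m_tot)
        return {"ratio": r}

    ens = mc_refit(refit, perturb, slab, n_runs=n_runs, seed=seed)
    q25, q75 = ens.quartile_interval("ratio")
    return RelativeAffinityResult(
        ln_identity=sample.ln_identity if sample is not None else "Eu",
        ratio=ratio,
        median=float(ens.draws["ratio"].median()),
        q25=q25, q75=q75,
        floored=floored,
        projection_residual=rel_resid,
        basis_mismatch=rel_resid > residual_threshold,
        ensemble=ens,
    )


def rank_lanthanides(results: dict[str, RelativeAffinityResult] |
                     list[RelativeAffinityResult]) -> pd.DataFrame:
    """Order per-lanthanide ratios into an affinity profile table.

    The displaced-Eu readout makes the ratio a strictly increasing function
    of competitor affinity, so the strongest binders carry the *largest*
    ratios.  Returns one row per lanthanide in atomic-number order with the
    point ratio, MC median and quartiles, an affinity ``rank`` (1 = highest
    affinity = largest median ratio), ``highest_affinity`` marking the top
    three ranks, and ``affinity_anomaly`` marking elements whose ratio is
    *quartile-significantly* above both series neighbours (its lower
    quartile clears both neighbours' upper quartiles) — an out-of-trend
    strong binder interrupting the smooth profile, the late-series anomaly
    signature, without flagging mere MC noise wiggles.
    """
    if isinstance(results, dict):
        items = list(results.values())
    else:
        items = list(results)
    if len(items) < 2:
        raise InputError("need results for at least two lanthanides")
    items.sort(key=lambda r: LANTHANIDES.index(r.ln_identity))

    med = np.array([r.median for r in items])
    q25 = np.array([r.q25 for r in items])
    q75 = np.array([r.q75 for r in items])
    order = np.argsort(-med)
    rank = np.empty(len(items), dtype=int)
    rank[order] = np.arange(1, len(items) + 1)
    anomaly = np.zeros(len(items), dtype=bool)
    for i in range(1, len(items) - 1):
        anomaly[i] = (med[i] > med[i - 1] and med[i] > med[i + 1]
                      and q25[i] > max(q75[i - 1], q75[i + 1]))

    return pd.DataFrame({
        "ln": [r.ln_identity for r in items],
        "atomic_number": [57 + LANTHANIDES.index(r.ln_identity)
                          + (1 if LANTHANIDES.index(r.ln_identity) >= 4 else 0)
                          for r in items],
        "ratio": [r.ratio for r in items],
        "median": med,
        "q25": [r.q25 for r in items],
        "q75": [r.q75 for r in items],
        "floored": [r.floored for r in items],
        "basis_mismatch": [r.basis_mismatch for r in items],
        "rank": rank,
        "highest_affinity": rank <= 3,
        "affinity_anomaly": anomaly,
    })
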