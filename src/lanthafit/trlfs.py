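"""Time-resolved luminescence titrations: forward model and deconvolution.

A titration is a 3-way array ``intensity[step, wavelength, delay]``.  With
every luminescent Eu species contributing a fixed emission spectrum and a
monoexponential decay, the noise-free tensor is exactly trilinear::

    I(s, λ, t) = Σ_k  brightness_k · conc_k(s) · spectrum_k(λ) · exp(-t/τ_k)

so non-negative PARAFAC recovers the per-species spectra, decays and
concentration profiles up to scaling and permutation.  The indeterminacies
are resolved by convention: spectra are normalised to unit integral over the
(environment-insensitive) 5D0→7F1 band, temporal modes to 1 at t = 0, all
remaining magnitude is pushed into the concentration loadings, and
components are ordered by descending lifetime.  Absolute concentrations
follow from metal closure: at every step the metal-ion-basis species
concentrations must sum to the known total Eu.

Species are counted on a metal-ion basis throughout (the 1:2 complex holds
two Eu and contributes 2·[LM2] to the balance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares, nnls

from .errors import CalibrationError, InputError
from .parafac import CPDecomposition, khatri_rao, nn_parafac
from .speciation import BindingModel, MixtureComposition, SpeciationState, solve_speciation

__all__ = [
    "TRLFSDataset",
    "SpeciesPhotophysics",
    "TrilinearFit",
    "LifetimeResult",
    "CalibrationResult",
    "BindingFitResult",
    "simulate_trlfs",
    "fit_parafac",
    "extract_lifetimes",
    "calibrate_concentrations",
    "fit_binding_constants",
    "refine_binding_model",
    "competition_basis",
    "normalize_spectrum",
]

#: default integration window (nm) for the 5D0->7F1 normalisation band
F1_BAND = (585.0, 600.0)


@dataclass(frozen=True)
class SpeciesPhotophysics:
    """Emission spectrum, lifetime and brightness of one Eu species."""

    spectrum: np.ndarray
    lifetime_us: float
    brightness: float = 1.0
    label: str = ""

    def __post_init__(self) -> None:
        spec = np.asarray(self.spectrum, dtype=float)
        object.__setattr__(self, "spectrum", spec)
        if not self.lifetime_us > 0:
            raise InputError(f"lifetime must be positive, got {self.lifetime_us}")
        if np.any(spec < 0) or not np.all(np.isfinite(spec)):
            raise InputError("spectrum must be non-negative and finite")
        if not self.brightness > 0:
            raise InputError("brightness must be positive")


@dataclass
class TRLFSDataset:
    """3-way luminescence titration with axes and per-step composition."""

    intensity: np.ndarray
    wavelengths: np.ndarray
    delays: np.ndarray
    compositions: list[MixtureComposition]
    excitation_nm: float = 394.0

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.delays = np.asarray(self.delays, dtype=float)
        s, j, k = self.intensity.shape
        if j != self.wavelengths.size or k != self.delays.size:
            raise InputError(
                f"tensor shape {self.intensity.shape} does not match axes "
                f"({self.wavelengths.size} wavelengths, {self.delays.size} delays)"
            )
        if len(self.compositions) != s:
            raise InputError("one composition per titration step is required")
        if np.any(np.diff(self.delays) <= 0):
            raise InputError("delay axis must be strictly increasing")

    @property
    def n_steps(self) -> int:
        return self.intensity.shape[0]

    def m_tot(self) -> np.ndarray:
        return np.array([c.m_tot for c in self.compositions])

    def l_tot(self) -> np.ndarray:
        return np.array([c.l_tot for c in self.compositions])


@dataclass
class TrilinearFit:
    """Canonicalised trilinear decomposition of a titration tensor.

    Loadings follow the package convention: spectral columns integrate to 1
    over the 7F1 band, temporal columns equal 1 at t = 0 (by their fitted
    monoexponential amplitude), concentration loadings carry all magnitude,
    components are ordered by descending lifetime.
    """

    n_components: int
    concentration_loadings: np.ndarray   # (steps, R)
    spectral_loadings: np.ndarray        # (wavelengths, R)
    temporal_loadings: np.ndarray        # (delays, R)
    explained_variance: float
    residual_tensor_norm: float
    lifetimes_us: np.ndarray             # (R,) from monoexponential fits
    converged: bool
    wavelengths: np.ndarray
    delays: np.ndarray
    band: tuple[float, float] = F1_BAND
    residual_trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    #: unconstrained re-estimate of the concentration mode at fixed spectral
    #: and temporal factors.  The non-negative loadings are truncated at zero,
    #: which biases near-zero amplitudes upward (half-normal mean); the free
    #: least-squares amplitudes are unbiased and are what calibration and the
    #: binding fit consume.  May contain small negative noise excursions.
    concentration_loadings_free: np.ndarray | None = None

    def reconstruct(self) -> np.ndarray:
        return np.einsum("ir,jr,kr->ijk",
                         self.concentration_loadings,
                         self.spectral_loadings,
                         self.temporal_loadings)


@dataclass(frozen=True)
class LifetimeResult:
    """Monoexponential fit of one temporal mode."""

    tau_us: float
    amplitude: float
    residual_rms: float
    unphysical: bool = False


@dataclass
class CalibrationResult:
    """Concentration loadings converted to molar species concentrations."""

    concentrations: np.ndarray       # (steps, R), metal-ion basis, molar
    brightness: np.ndarray           # (R,) intensity per molar, model scale
    closure_residuals: np.ndarray    # (steps,) relative metal-balance error
    fit: TrilinearFit


@dataclass
class BindingFitResult:
    """Binding constants fitted to calibrated speciation profiles.

    When the fit was polished against the raw tensor (equilibrium-
    constrained refinement), ``refined`` is True and the jointly
    re-estimated lifetimes and brightnesses are carried along.
    """

    model: BindingModel
    assignment: tuple[int, ...]      # component columns for (aquo, 1:1, 1:2)
    predicted: np.ndarray            # (steps, species) metal-ion basis
    residual_rms: float              # RMS misfit relative to mean total metal
    warning_large_residual: bool
    refined: bool = False
    lifetimes_us: np.ndarray | None = None   # (species,) aquo, 1:1[, 1:2]
    brightness: np.ndarray | None = None     # (species,) intensity per molar


def normalize_spectrum(spectrum: np.ndarray, wavelengths: np.ndarray,
                       band: tuple[float, float] = F1_BAND) -> np.ndarray:
    """Scale a spectrum so its integral over the 7F1 band equals 1.

    The 7F1 transition is largely insensitive to the coordination
    environment, making its integral the standard internal intensity
    reference for Eu emission spectra.
    """
    spectrum = np.asarray(spectrum, dtype=float)
    wavelengths = np.asarray(wavelengths, dtype=float)
    lo, hi = band
    if wavelengths.min() > lo or wavelengths.max() < hi:
        raise InputError(
            f"wavelength axis [{wavelengths.min()}, {wavelengths.max()}] nm "
            f"does not cover the 7F1 band window {band}"
        )
    mask = (wavelengths >= lo) & (wavelengths <= hi)
    integral = np.trapezoid(spectrum[mask], wavelengths[mask])
    if integral <= 0:
        raise InputError("7F1 band integral is zero; cannot normalise")
    return spectrum / integral


def simulate_trlfs(states: list[SpeciationState],
                   photophysics: list[SpeciesPhotophysics],
                   wavelengths: np.ndarray, delays: np.ndarray,
                   noise: float = 0.0, seed: int | None = None,
                   compositions: list[MixtureComposition] | None = None,
                   excitation_nm: float = 394.0,
                   floor_at_zero: bool = False) -> TRLFSDataset:
    """Forward-simulate a titration tensor from speciation states.

    ``photophysics`` is ordered (aquo, 1:1, 1:2) to match
    :meth:`SpeciationState.eu_species`; pass two entries for a 1:1-only
    system.  Noise is additive Gaussian with sigma = ``noise`` times the
    maximum of the clean tensor — the statistics of background-corrected
    detector counts, which go negative in signal-free voxels.  Clipping at
    zero (``floor_at_zero=True``) is available but biases near-zero voxels
    upward by ~0.4 sigma, which a fixed-rank trilinear model can only
    absorb by distorting a real component; it is off by default.
    """
    if noise < 0:
        raise InputError("noise level must be >= 0")
    wavelengths = np.asarray(wavelengths, dtype=float)
    delays = np.asarray(delays, dtype=float)
    n_species = len(photophysics)
    conc = np.array([st.eu_species()[:n_species] for st in states])  # (S, K)
    for ph in photophysics:
        if ph.spectrum.size != wavelengths.size:
            raise InputError("photophysics spectrum does not match wavelength axis")

    spectra = np.stack([ph.spectrum for ph in photophysics], axis=1)      # (J, K)
    decays = np.stack(
        [np.exp(-delays / ph.lifetime_us) for ph in photophysics], axis=1)  # (T, K)
    amps = conc * np.array([ph.brightness for ph in photophysics])        # (S, K)
    clean = np.einsum("ir,jr,kr->ijk", amps, spectra, decays)

    if noise > 0:
        rng = np.random.default_rng(seed)
        sigma = noise * clean.max()
        tensor = clean + rng.normal(0.0, sigma, clean.shape)
        if floor_at_zero:
            tensor = np.clip(tensor, 0.0, None)
    else:
        tensor = clean

    if compositions is None:
        compositions = [
            MixtureComposition(l_tot=st.free_l + st.c_lm + st.c_lm2,
                               m_tot=st.free_m + st.c_lm + 2 * st.c_lm2)
            for st in states
        ]
    return TRLFSDataset(intensity=tensor, wavelengths=wavelengths,
                        delays=delays, compositions=list(compositions),
                        excitation_nm=excitation_nm)


def _fit_monoexp(t: np.ndarray, y: np.ndarray) -> LifetimeResult:
    """Least-squares monoexponential a*exp(-t/tau) to one temporal mode."""
    ymax = float(np.max(y))
    if ymax <= 0:
        return LifetimeResult(math.inf, 0.0, 0.0, unphysical=True)
    # log-linear start on the informative part of the decay
    mask = y > 1e-3 * ymax
    ty, yy = t[mask], y[mask]
    w = yy  # ~inverse-variance for multiplicative noise, stabilises the log fit
    A = np.vstack([np.ones_like(ty), ty]).T * w[:, None]
    coef, *_ = np.linalg.lstsq(A, np.log(yy) * w, rcond=None)
    slope = coef[1]
    if slope >= 0:
        return LifetimeResult(math.inf, ymax, float(np.std(y)), unphysical=True)
    a0, tau0 = math.exp(coef[0]), -1.0 / slope

    def resid(p: np.ndarray) -> np.ndarray:
        return p[0] * np.exp(-t / p[1]) - y

    sol = least_squares(resid, x0=[a0, tau0],
                        bounds=([0.0, 1e-12], [np.inf, np.inf]))
    a, tau = sol.x
    rms = float(np.sqrt(np.mean(sol.fun**2)))
    return LifetimeResult(float(tau), float(a), rms, unphysical=False)


def fit_parafac(data: TRLFSDataset, n_components: int, init_seed: int = 0,
                n_restarts: int = 20, max_iter: int = 6000,
                band: tuple[float, float] = F1_BAND,
                init: tuple[np.ndarray, ...] | None = None) -> TrilinearFit:
    """Deconvolute a titration tensor into non-negative trilinear components.

    The species count is fixed a priori by the chemical model (3 for
    aquo/1:1/1:2, 2 for 1:1-only binders), never auto-selected.  Runs
    ``n_restarts`` random initialisations and keeps the best; a
    non-converged best run is flagged on the result, not raised.
    """
    cp = nn_parafac(data.intensity, rank=n_components, n_restarts=n_restarts,
                    max_iter=max_iter, seed=init_seed, init=init)
    return _canonicalize(cp, data, band)


def _canonicalize(cp: CPDecomposition, data: TRLFSDataset,
                  band: tuple[float, float]) -> TrilinearFit:
    a, b, c = (f.copy() for f in cp.factors)
    r = a.shape[1]
    taus = np.empty(r)
    for k in range(r):
        # spectral scale: unit 7F1 band integral
        mask = (data.wavelengths >= band[0]) & (data.wavelengths <= band[1])
        s_int = np.trapezoid(b[mask, k], data.wavelengths[mask])
        if s_int > 0:
            b[:, k] /= s_int
            a[:, k] *= s_int
        # temporal scale: monoexponential amplitude 1 at t=0
        lt = _fit_monoexp(data.delays, c[:, k])
        taus[k] = lt.tau_us
        amp = lt.amplitude if (lt.amplitude > 0 and not lt.unphysical) else (
            c[0, k] if c[0, k] > 0 else 1.0)
        c[:, k] /= amp
        a[:, k] *= amp
    order = np.argsort(-taus)
    # unbiased concentration amplitudes: ordinary LS at fixed spectra/decays
    design = khatri_rao(b, c)
    s = data.intensity.shape[0]
    a_free, *_ = np.linalg.lstsq(
        design, data.intensity.reshape(s, -1).T, rcond=None)
    a_free = a_free.T
    return TrilinearFit(
        n_components=r,
        concentration_loadings=a[:, order],
        concentration_loadings_free=a_free[:, order],
        spectral_loadings=b[:, order],
        temporal_loadings=c[:, order],
        explained_variance=cp.explained_variance,
        residual_tensor_norm=cp.residual_norm,
        lifetimes_us=taus[order],
        converged=cp.converged,
        wavelengths=data.wavelengths,
        delays=data.delays,
        band=band,
        residual_trace=cp.residual_trace,
    )


def extract_lifetimes(fit: TrilinearFit,
                      delays: np.ndarray | None = None) -> list[LifetimeResult]:
    """Monoexponential lifetime per component temporal mode.

    A mode that does not decay is returned with ``unphysical=True`` rather
    than raising, so a defective component is visible in diagnostics.
    """
    t = np.asarray(delays if delays is not None else fit.delays, dtype=float)
    results = []
    for k in range(fit.n_components):
        y = fit.temporal_loadings[:, k]
        if not np.any(y > 0):
            raise InputError(f"temporal mode {k} is identically zero")
        results.append(_fit_monoexp(t, y))
    return results


def calibrate_concentrations(fit: TrilinearFit,
                             compositions: list[MixtureComposition],
                             tol: float = 0.15) -> CalibrationResult:
    """Resolve the trilinear scale by enforcing total-metal closure.

    With canonicalised loadings, ``A[s, k] = brightness_k * conc_k(s)``
    where ``conc`` is the metal-ion-basis species concentration.  The
    inverse brightnesses are the non-negative least-squares solution of
    ``A x = m_tot`` over all steps; a step where only the aquo ion emits
    then carries the full m_tot, anchoring the scale.

    Uses the unconstrained concentration amplitudes when the fit provides
    them (unbiased near zero); the returned concentrations may then carry
    small negative noise excursions where a species is absent.
    """
    a = (fit.concentration_loadings_free
         if fit.concentration_loadings_free is not None
         else fit.concentration_loadings)
    m_tot = np.array([c.m_tot for c in compositions])
    if a.shape[0] != m_tot.size:
        raise InputError("compositions do not match the number of steps")
    x, _ = nnls(a, m_tot)
    conc = a * x
    closure = conc.sum(axis=1) - m_tot
    rel = np.abs(closure) / np.maximum(m_tot, 1e-30)
    if np.any(rel > tol):
        worst = int(np.argmax(rel))
        raise CalibrationError(
            f"metal closure violated after calibration: step {worst} off by "
            f"{rel[worst]:.3%} (tolerance {tol:.1%}); residuals={closure}"
        )
    with np.errstate(divide="ignore"):
        brightness = np.where(x > 0, 1.0 / np.maximum(x, 1e-300), np.inf)
    return CalibrationResult(concentrations=conc, brightness=brightness,
                             closure_residuals=rel, fit=fit)


def _predicted_profiles(models_kd: np.ndarray, compositions: list[MixtureComposition],
                        two_step: bool) -> np.ndarray:
    """Metal-ion-basis species profiles for candidate (kd_11[, kd_12])."""
    kd11 = 10.0 ** models_kd[0]
    kd12 = 10.0 ** models_kd[1] if two_step else math.inf
    model = BindingModel(kd_11=kd11, kd_12=kd12)
    n_sp = 3 if two_step else 2
    out = np.empty((len(compositions), n_sp))
    for i, comp in enumerate(compositions):
        st = solve_speciation(comp, model)
        out[i] = st.eu_species()[:n_sp]
    return out


def fit_binding_constants(concentrations: CalibrationResult | np.ndarray,
                          compositions: list[MixtureComposition],
                          two_step: bool | None = None,
                          kd_log10_bounds: tuple[float, float] = (-10.0, -2.0),
                          label: str = "",
                          assignment: tuple[int, ...] | None = None,
                          x0_log10: np.ndarray | None = None,
                          refine_with: TRLFSDataset | None = None) -> BindingFitResult:
    """Fit stepwise dissociation constants to calibrated speciation profiles.

    Least squares of :func:`solve_speciation` predictions against the
    observed metal-ion-basis profiles, optimised on a log10-kd scale from a
    coarse-grid start.  The mapping of components to chemical species
    (aquo, 1:1, 1:2) is not assumed: all assignments are tried and the best
    fit wins (the lifetime ordering of the canonical form is a convention,
    not chemistry).  ``assignment`` pins the mapping and ``x0_log10`` skips
    the grid search — both used by the Monte-Carlo refits, which restart
    from the base estimate.

    Deconvoluted profiles carry a residual rotational ambiguity: at finite
    noise a small, systematic exchange between component profiles costs
    almost no tensor residual yet biases the small concentrations that
    carry the KD information.  Passing the raw dataset as ``refine_with``
    removes it: the profile-space estimate seeds an equilibrium-constrained
    (hard-model) polish in which the concentration mode is generated by
    :func:`solve_speciation`, decays are monoexponential, spectra are
    profiled out linearly, and (kd, brightness, lifetimes) are fitted
    directly against the tensor.  This is the estimator the pipeline and
    the uncertainty ensembles report.
    """
    if isinstance(concentrations, CalibrationResult):
        obs = concentrations.concentrations
    else:
        obs = np.asarray(concentrations, dtype=float)
    n_steps, r = obs.shape
    if n_steps != len(compositions):
        raise InputError("profiles and compositions disagree in step count")
    if n_steps < 6:
        raise InputError("need >= 6 titration steps spanning both regimes")
    if two_step is None:
        two_step = r >= 3
    n_sp = 3 if two_step else 2
    if r < n_sp:
        raise InputError(f"{r} components cannot map onto {n_sp} species")

    scale = float(np.mean([c.m_tot for c in compositions])) or 1.0
    lo, hi = kd_log10_bounds

    from itertools import permutations

    grid = np.linspace(lo + 0.5, hi - 0.5, 7)
    perms = ([tuple(assignment)] if assignment is not None
             else list(permutations(range(r), n_sp)))
    best: tuple[float, tuple[int, ...], np.ndarray] | None = None
    for perm in perms:
        target = obs[:, list(perm)]

        def resid(p: np.ndarray) -> np.ndarray:
            return (_predicted_profiles(p, compositions, two_step) - target).ravel() / scale

        if x0_log10 is not None:
            x0 = np.clip(np.asarray(x0_log10, dtype=float), lo, hi)
        else:
            # coarse grid start, then bounded refinement
            if two_step:
                cand = [(g1, g2) for g1 in grid for g2 in grid]
            else:
                cand = [(g1,) for g1 in grid]
            rss0 = [float(np.sum(resid(np.array(c)) ** 2)) for c in cand]
            x0 = np.array(cand[int(np.argmin(rss0))])
        # tight tolerances: an absent second step must be driven all the way
        # to the kd_12 search bound, not stall on a flat gradient
        sol = least_squares(resid, x0=x0, bounds=(lo, hi),
                            ftol=1e-14, xtol=1e-14, gtol=1e-14)
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, tuple(perm), sol.x)

    assert best is not None
    rss, perm, x = best
    kd11 = 10.0 ** x[0]
    kd12 = 10.0 ** x[1] if two_step else math.inf
    model = BindingModel(kd_11=kd11, kd_12=kd12, label=label)
    predicted = _predicted_profiles(x, compositions, two_step)
    rms = math.sqrt(rss / (n_steps * n_sp)) * scale
    result = BindingFitResult(
        model=model, assignment=tuple(perm), predicted=predicted,
        residual_rms=rms / scale,
        warning_large_residual=(rms / scale) > 0.05,
    )
    if refine_with is None:
        return result
    if not isinstance(concentrations, CalibrationResult):
        raise InputError("refinement needs a CalibrationResult "
                         "(brightness and lifetime context)")
    calib = concentrations
    brightness0 = calib.brightness[list(perm)]
    # a component that received zero calibration weight has infinite nominal
    # brightness; start it at the brightest finite species instead
    finite = np.isfinite(brightness0)
    if not finite.all():
        fallback = brightness0[finite].max() if finite.any() else 1e5
        brightness0 = np.where(finite, brightness0, fallback)
    taus0 = calib.fit.lifetimes_us[list(perm)]
    return refine_binding_model(
        refine_with, compositions, x, brightness0, taus0,
        two_step=two_step, assignment=tuple(perm),
        kd_log10_bounds=kd_log10_bounds, label=label)


def refine_binding_model(data: TRLFSDataset,
                         compositions: list[MixtureComposition],
                         kd_log10: np.ndarray,
                         brightness0: np.ndarray,
                         taus0: np.ndarray,
                         two_step: bool = True,
                         assignment: tuple[int, ...] = (),
                         kd_log10_bounds: tuple[float, float] = (-10.0, -2.0),
                         label: str = "") -> BindingFitResult:
    """Equilibrium-constrained refinement of binding constants on the tensor.

    Hard-soft trilinear fit: the concentration mode is generated by the
    two-step (or one-step) binding model times per-species brightnesses,
    the temporal mode is exactly monoexponential, and the species spectra —
    conditionally linear — are profiled out by least squares at every
    evaluation (variable projection).  Parameters: log10 kd, log10
    brightness and log lifetime per species, started from the soft-model
    pipeline estimates.
    """
    n_sp = 3 if two_step else 2
    x = np.asarray(kd_log10, dtype=float)
    brightness0 = np.asarray(brightness0, dtype=float)
    taus0 = np.asarray(taus0, dtype=float)
    if brightness0.size != n_sp or taus0.size != n_sp:
        raise InputError("brightness/lifetime starts must have one entry per species")
    if not (np.all(brightness0 > 0) and np.all(np.isfinite(brightness0))
            and np.all(taus0 > 0) and np.all(np.isfinite(taus0))):
        raise InputError("brightness/lifetime starts must be positive and finite")

    t = data.delays
    n_kd = 2 if two_step else 1
    x_slabs = np.moveaxis(data.intensity, 1, 2).reshape(-1, data.wavelengths.size)
    x_norm = float(np.linalg.norm(x_slabs))

    def resid(p: np.ndarray) -> np.ndarray:
        conc = _predicted_profiles(p[:n_kd], compositions, two_step)
        amps = conc * 10.0 ** p[n_kd:n_kd + n_sp]
        decays = np.exp(-t[:, None] / np.exp(p[n_kd + n_sp:]))
        design = khatri_rao(amps, decays)            # (steps*delays, n_sp)
        spectra, *_ = np.linalg.lstsq(design, x_slabs, rcond=None)
        return (design @ spectra - x_slabs).ravel() / max(x_norm, 1e-300)

    lo, hi = kd_log10_bounds
    x0 = np.concatenate([x, np.log10(brightness0), np.log(taus0)])
    lower = np.array([lo] * n_kd + [-3.0] * n_sp + [0.0] * n_sp)
    upper = np.array([hi] * n_kd + [15.0] * n_sp + [math.log(1e5)] * n_sp)
    sol = least_squares(resid, x0=np.clip(x0, lower, upper),
                        bounds=(lower, upper), diff_step=1e-4)
    p = sol.x
    kd11 = 10.0 ** p[0]
    kd12 = 10.0 ** p[1] if two_step else math.inf
    model = BindingModel(kd_11=kd11, kd_12=kd12, label=label)
    predicted = _predicted_profiles(p[:n_kd], compositions, two_step)
    rel_resid = math.sqrt(2.0 * sol.cost)   # = |resid|/|X|
    return BindingFitResult(
        model=model, assignment=tuple(assignment), predicted=predicted,
        residual_rms=rel_resid,
        warning_large_residual=rel_resid > 0.2,
        refined=True,
        lifetimes_us=np.exp(p[n_kd + n_sp:]),
        brightness=10.0 ** p[n_kd:n_kd + n_sp],
    )


def competition_basis(data: TRLFSDataset,
                      binding: BindingFitResult) -> CalibrationResult:
    """Frozen projection basis from an equilibrium-refined titration fit.

    Rebuilds the species spectra by least squares at the refined
    concentrations/brightnesses/lifetimes, giving a basis whose factors are
    pinned to the binding model rather than to the rotational optimum of
    the blind decomposition.  Columns are ordered (aquo, 1:1[, 1:2]) to
    match the refinement; :func:`analyze_competition` locates the aquo
    component by its (shortest) lifetime either way.
    """
    if not binding.refined or binding.lifetimes_us is None:
        raise InputError("competition_basis needs a refined binding fit "
                         "(fit_binding_constants(..., refine_with=data))")
    conc = binding.predicted
    amps = conc * binding.brightness
    decays = np.exp(-data.delays[:, None] / binding.lifetimes_us[None, :])
    design = khatri_rao(amps, decays)
    x_slabs = np.moveaxis(data.intensity, 1, 2).reshape(-1, data.wavelengths.size)
    spectra, *_ = np.linalg.lstsq(design, x_slabs, rcond=None)
    b = np.clip(spectra.T, 0.0, None)
    resid = float(np.linalg.norm(design @ spectra - x_slabs))
    x_norm2 = float(np.sum(x_slabs**2))
    m_tot = np.array([c.m_tot for c in data.compositions])
    closure = np.abs(conc.sum(axis=1) - m_tot) / np.maximum(m_tot, 1e-30)
    fit = TrilinearFit(
        n_components=conc.shape[1],
        concentration_loadings=amps,
        spectral_loadings=b,
        temporal_loadings=decays,
        explained_variance=max(0.0, 1.0 - resid**2 / x_norm2),
        residual_tensor_norm=resid,
        lifetimes_us=binding.lifetimes_us,
        converged=True,
        wavelengths=data.wavelengths,
        delays=data.delays,
    )
    return CalibrationResult(concentrations=conc, brightness=binding.brightness,
                             closure_residuals=closure, fit=fit)


def project_onto_basis(tensor_2d: np.ndarray, fit: TrilinearFit) -> tuple[np.ndarray, float]:
    """Non-negative projection of one (wavelength x delay) slab onto fixed factors.

    Returns the per-component amplitudes (concentration-mode loadings for
    this single sample) and the relative projection residual.  Used by the
    competition analysis, where spectra and decays are frozen from the Eu
    titration basis and only the concentration mode is re-estimated.
    """
    design = khatri_rao(fit.spectral_loadings, fit.temporal_loadings)
    target = tensor_2d.ravel()
    amps, rnorm = nnls(design, target)
    denom = float(np.linalg.norm(target))
    rel = rnorm / denom if denom > 0 else 0.0
    return amps, rel
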