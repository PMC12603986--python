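# Methods

`lanthafit` infers the thermodynamics of short EF-hand-derived peptides
binding trivalent lanthanides from three kinds of measurement: time-resolved
laser-induced luminescence titrations (TRLFS), isothermal titration
calorimetry (ITC), and single-shot Eu/Ln competition mixtures.  This note
records the models, the estimators, the numerical choices, and what the
synthetic-data generator does and does not emulate.

## Chemical model

Binding is sequential and homometallic:

```
L + M  ⇌  LM      K_D(1:1) = [L][M]/[LM]
LM + M ⇌  LM₂     K_D(1:2) = [LM][M]/[LM₂]
```

with stepwise *dissociation* constants in molar units (smaller = tighter).
LM₂ is one peptide carrying two metal ions.  A competition mixture adds a
second metal N with its own two constants on the same peptide; mixed
L(M)(N) species are excluded from the model.  Consequences of that
exclusion are real: a competition mixture of two *identical* metals is
equivalent to a single-metal sample at doubled metal **only** for 1:1-only
binders — with a second step, the true identical-metal system would
populate the mixed 1:2 complex with a statistical factor of 2 that the
species set omits.  The test suite asserts the equivalence in the 1:1-only
case only.

Activity corrections are not applied (measurements are modelled at constant
ionic strength, 100 mM KCl); carboxylate protonation and buffer–metal side
reactions are outside the model.

### Equilibrium solver

For one metal, the free-ligand concentration follows in closed form from
the free metal `m`, leaving one scalar mass balance `g(m) = 0` that is
continuous and strictly increasing on `[0, m_tot]`.  It is solved by a
safeguarded Newton iteration with bisection fallback (absolute residual
tolerance 1e-12 relative to `m_tot`).  The two-metal problem nests this
kernel inside an outer bisection on the competitor balance.  Tests verify
agreement with independent brute-force oracles (1-D bisection; iterative
2-D grid refinement) to 1e-6 relative, mass conservation to 1e-8 relative
over random compositions, and the closed-form single-site quadratic in the
`K_D(1:2) → ∞` limit.

### Titration bookkeeping

Two mixing modes. "Additive": the cell volume grows, totals follow exact
conservation.  "Overflow" (perfusion calorimeter cell): each injection of
volume `v` expels an equal volume of partially mixed contents, modelled by
the trapezoidal displacement rule
`c → [c·(V − v/2) + c_syr·v]/(V + v/2)` — the standard first-order
`(1 − v/2V)` correction.  The same trapezoid gives the moles of each
species carried out per injection, which the heat model counts as formed
material.

## Luminescence titrations

### Forward model

Every luminescent Eu species contributes a fixed emission spectrum and a
monoexponential decay, so the noise-free titration tensor is exactly
trilinear:

```
I(step, λ, t) = Σ_k  brightness_k · conc_k(step) · spectrum_k(λ) · exp(−t/τ_k)
```

Species concentrations are counted on a metal-ion basis (the 1:2 complex
contributes `2·[LM₂]`), which makes total-Eu closure linear.  Gate-width
integration of the decay only rescales per-species brightness and is
absorbed there.

### Deconvolution

Non-negativity-constrained PARAFAC by alternating least squares on the
normal equations: the Gram of the Khatri-Rao design factorises into
Hadamard products of small per-mode Grams, and each block update is an
exact NNLS solved by enumerating active sets (rank ≤ 6) — so the squared
residual is non-increasing, a property the tests assert on the iteration
trace.  A line-search extrapolation step (accepted only when it lowers the
residual) cuts the long ALS tail by roughly an order of magnitude.
Defaults: 20 random restarts, best residual wins; plateau stop when the
per-iteration decrease falls below 1e-13 of the residual; 6000 iteration
cap; a non-converged best run is flagged on the result, never silent.

The component count is fixed a priori by the chemical model — 3 (aquo,
1:1, 1:2) or 2 for 1:1-only binders — never auto-selected.

Scaling/permutation indeterminacy is resolved by convention: spectra are
normalised to unit integral over the environment-insensitive ⁷F₁ band
(default window 585–600 nm, configurable), temporal modes to 1 at `t = 0`
via their fitted monoexponential amplitude, all magnitude is pushed into
the concentration loadings, and components are ordered by descending
lifetime.  Because non-negative loadings are truncated at zero — which
biases near-zero amplitudes upward by the half-normal mean — the fit also
carries an *unconstrained* re-estimate of the concentration mode at fixed
spectra/decays; calibration consumes that one.

### Calibration and binding constants

Metal closure anchors the absolute scale: with canonical loadings
`A[s,k] = brightness_k · conc_k(s)`, the inverse brightnesses solve
`A x = m_tot` by NNLS over all steps; a peptide-free step (pure aquo ion)
pins the scale.  Closure residuals beyond 15% of `m_tot` raise an error
with per-step diagnostics.

Dissociation constants are then fitted in two stages.  The profile-space
fit minimises the misfit between `solve_speciation` predictions and the
calibrated profiles over `(log10 K_D(1:1), log10 K_D(1:2))` from a coarse
grid start, trying every assignment of components to species (the lifetime
ordering is a convention, not chemistry).  This estimate then seeds an
**equilibrium-constrained refinement** (hard–soft trilinear fit): the
concentration mode is generated by the binding model times per-species
brightnesses, decays are exactly monoexponential, spectra are profiled out
linearly at every evaluation (variable projection), and
`(K_Ds, brightnesses, lifetimes)` are fitted directly against the tensor.

The refinement exists because the blind trilinear optimum has a near-flat
direction: a sub-1% error in the aquo lifetime trades against spectral
mixing at almost no cost in tensor residual, yet the resulting
proportional leak from the (large) aquo pool into the (small) complex
pools biases the dissociation constants severalfold.  Warm-starting the
ALS from the generating factors converges to the same optimum as cold
starts, so this is a property of the likelihood, not of the optimiser;
constraining the concentration mode to the equilibrium model removes the
flat direction.  Hard-modelling of concentration profiles is standard
practice in titration chemometrics.  On the default synthetic conditions
the refinement recovers the generating constants to a few percent where
the profile-space fit alone scatters by ±50%.

Lifetimes are extracted per component by monoexponential least squares
(log-linear start, then bounded refinement); a non-decaying mode is
returned flagged as unphysical rather than raising.

## Calorimetry

Integrated injection heats follow

```
q_i = ΔH₁·Δn_i(LM) + ΔH₂·Δn_i(LM₂) + q_dil
```

where `Δn_i` counts complex formed between consecutive equilibria in the
overflow cell *including* expelled material (heat is released when complex
forms; complex leaving the cell does not un-form).  Enthalpies are
injection-independent (no heat-capacity term); heats are already-integrated
per-injection values — raw power traces are instrument-software territory.
Noise-free, `Σ q_i` telescopes to `ΔH·(total moles formed)`, asserted as a
path-independence test.

The global fit shares `K_D(1:1), K_D(1:2), ΔH₁, ΔH₂` across replicates
measured at different cell peptide concentrations and keeps one
per-injection dilution heat per replicate, optimising dissociation
constants on a log10 scale with multi-start.  The first injection is
excluded by default (syringe-tip diffusion artefact).  Weighting is
uniform; `weighting="auto"` re-estimates per-replicate noise from
late-titration residuals and refits.  Derived quantities are never stored:
`ΔG° = RT·ln K_D` and `−TΔS° = ΔG° − ΔH°` are computed on demand, and the
studied peptides show the entropy-driven signature (ΔH > 0, ΔG < 0).

A second binding step the data cannot support is flagged: the fitted
`log K_D(1:2)` sits at a search bound, or — because an overparameterised
fit may instead invent a weak noise-absorbing step — the two-component fit
fails a nested-model comparison against the one-site fit (residual
reduction below 5%).

## Competition analysis

Competitor lanthanides are spectroscopically silent at 394 nm excitation;
only Eu species contribute.  Each single-shot sample is projected onto a
*frozen* spectral/temporal basis by NNLS on the concentration mode alone;
the basis is built from the same peptide's Eu titration, with factors
pinned to the refined equilibrium fit (a blind-PARAFAC basis carries the
rotational bias described above into every ratio).  The readout is
Eu-aquo / complexed-Eu (1:1 and 1:2 pooled), floored so an aquo-only
sample yields a large but finite, flagged ratio; a projection residual
above 20% (double the noise-only level) flags basis mismatch.

The ratio increases strictly with competitor affinity — a stronger
competitor displaces Eu into the aquo pool.  `rank_lanthanides` therefore
ranks the largest median ratios as highest affinity, and flags an
out-of-trend strong binder as a *quartile-significant* local maximum (its
lower quartile clears both neighbours' upper quartiles), so MC noise
wiggles are not reported as anomalies.  Samples are assumed equilibrated;
overnight-equilibration kinetics are not modelled.

## Uncertainty

All errors are parametric residual bootstraps: surrogate datasets are the
base fit's *fitted values* plus Gaussian noise scaled to the base-fit
residual distribution; each surrogate is refit starting from the base
estimate; medians and quartiles summarise the draws (study convention:
100 runs).  Drawing around the fitted values keeps each surrogate at the
measurement's own noise level, so the quartile interval is a genuine
central-50% interval — verified against the closed-form standard error on
a linear model and by a 200-replicate coverage study (observed coverage
0.50).  Re-noising the *observed* data instead would inflate every
interval by √2.  Warm-starting refits from the base estimate is a speed
choice that can understate multimodality; refits that fail to converge are
counted, and an ensemble with more than 50% failures raises.

## Synthetic-data generator

The generator emulates the statistical structure of the study's three
experiments; presets named after the studied peptides carry the published
dissociation constants and lifetimes as generating truth.  Values the
study does not print are fixed package choices:

- **Photophysics.** Gaussian-mixture mock spectra over 570–640 nm: the
  aquo ion has no ⁷F₀ band and a weak ⁷F₂/⁷F₁ ratio; complexation raises
  the hypersensitive ⁷F₂ band, with clearly different ⁷F₂ position and
  splitting for the 1:1 and 1:2 ligand fields (pairwise spectral cosines
  ≈ 0.45–0.66, as distinguishable as real deconvoluted Eu spectra — an
  accidental near-collinear choice would pose a harder problem than the
  experiment being emulated).  Shapes are synthetic, not digitised.
  Brightness ratio aquo : 1:1 : 1:2 = 1 : 2 : 2.5 — complexes brighten as
  quenching water leaves, and every species stays well above the noise
  floor, as in any usable measurement.  Eu-aquo lifetime 110 µs
  (configurable).
- **TRLFS design.** Two regimes: 15 peptide steps (0–50 µM, dense through
  the binding transition) at 10 µM Eu, then 10 Eu steps (12–80 µM) at
  10 µM peptide; 141 wavelengths (0.5 nm); 40 delay gates over 0–800 µs.
  Titrations resolve K_D from curvature across the transition, hence the
  dense sampling there.
- **Noise.** Additive Gaussian, σ = 1% of the clean tensor maximum by
  default — the statistics of background-corrected detector counts, which
  go negative in signal-free voxels.  Clipping at zero is available
  (`floor_at_zero=True`) but biases near-zero voxels upward by ~0.4σ,
  a structured baseline that a fixed-rank trilinear model can only absorb
  by distorting a real component; it is off by default.
- **ITC design.** Three replicates (cell peptide 30/45/60 µM), one 900 µM
  Eu syringe, 200 µL overflow cell, 40 × 1.25 µL injections (a schedule
  fine enough to sample the sharp transition at c ≈ 60), per-injection
  dilution heat 0.5 µJ, noise σ = 1% of the maximum absolute clean heat.
  Step enthalpies default to ΔH₁ = +15, ΔH₂ = +10 kJ/mol — typical
  endothermic Ln–carboxylate values consistent with the reported
  entropy-driven signature; the published data constrain their sign, not
  their magnitude.
- **Competition panel.** One equimolar sample per lanthanide
  (10 µM each of peptide, Eu, Ln); competitor constants scale Eu's by
  per-element factors forming a mid-series affinity peak (Nd strongest,
  then Sm, Eu), a smooth decline toward Lu, and an out-of-trend strong
  binder at Yb.
- The 1:2 dissociation constant of the highest-affinity mutant preset is
  set at ~20× its 1:1 constant, the ratio shown by the other reverse
  peptides; only the 1:1 constant is a published number.

What the generator does **not** emulate: instrument artefacts (gating
nonlinearity, laser drift, baseline curvature), shot-noise
heteroscedasticity, slow equilibration, peptide impurities, or model error
(the synthetic truth is exactly the fitted family).  Passing recovery
tests therefore demonstrates the correctness and calibration of the
estimators under the declared noise model — not robustness to
misspecification on real instruments.

## Problem sizes and seeds

Default analyses run in seconds to a few minutes on one core: the 25 × 141
× 40 titration tensor with 20 restarts fits in ~20–30 s; the refinement in
under a second; 100-run bootstraps in 5–20 s.  The test suite uses these
default sizes, with the bootstrap-coverage study at 200 replicates × 50
runs on the (cheap) profile-space fit.  Every stochastic stage takes an
explicit seed; identical seeds reproduce results bit-for-bit.

## Known limitations

- The aquo/1:2 lifetime pair (110 vs 134 µs) keeps the blind deconvolution
  ill-conditioned; the profile-space K_D fit alone is reliable only at
  very low noise, and the equilibrium-constrained refinement is the
  estimator of record.
- The competition ratio inherits ~10% systematic error from basis
  imperfection at 1% noise; rankings and anomaly detection are robust to
  it, absolute ratios less so.
- Heats are modelled per-injection with a single displacement rule;
  instrument-specific cell geometry corrections are not reproduced.
- MC ensembles restart from the base estimate and will not explore
  separated modes.
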