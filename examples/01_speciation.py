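"""Equilibrium speciation of a peptide binding Eu(III) in two steps.

Builds the EF1-R binding model (stepwise dissociation constants), solves the
mass-balance equilibria along both regimes of a titration and prints the
species distribution.  Fractions are of total Eu on a metal-ion basis.
"""

import lanthafit as lf
from lanthafit.reporting import species_distribution_table

uM = 1e-6

model = lf.BindingModel(kd_11=0.50 * uM, kd_12=1.1 * uM, label="EF1-R")

# regime 1: raise peptide at 10 µM Eu; regime 2: raise Eu at 10 µM peptide
comps = [lf.MixtureComposition(l_tot=l * uM, m_tot=10 * uM)
         for l in (0, 2, 5, 10, 20, 50)]
comps += [lf.MixtureComposition(l_tot=10 * uM, m_tot=m * uM)
          for m in (20, 40, 80)]

table = species_distribution_table(model, comps)
print(table.round(3).to_string(index=False))
print()

state = lf.solve_speciation(comps[3], model)
print(f"at 10 µM peptide / 10 µM Eu: free Eu = {state.free_m * 1e6:.2f} µM, "
      f"[1:1] = {state.c_lm * 1e6:.2f} µM, [1:2] = {state.c_lm2 * 1e6:.2f} µM")
print("Raising the peptide converts the aquo ion into the 1:1 complex; "
      "excess Eu instead drives the peptide into the two-metal 1:2 complex.")
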