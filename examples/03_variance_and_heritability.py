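"""Crossed variance decomposition and entry-mean heritability.

Decomposes grain yield into genotype, location, year, their interactions,
block and plot error; expresses the genetic part as shares of the total
genetic variance; and plugs the components into the harmonic-mean
heritability formula that handles funnel-unbalanced data.
"""

import metstab as ms
from metstab.quantgen import heritability, incidence_counts, variance_proportions

cfg = ms.SimulationConfig(seed=7)   # 50 genotypes x 2 locations x 5 years x 3 reps
plots, _ = ms.simulate_met(cfg)

vc = ms.estimate_variance_components(plots, "yield_kg_ha")
print("variance components (kg/ha)^2:")
for term, value in vc.as_dict().items():
    flag = "  <- at zero bound" if term in vc.clamped else ""
    print(f"  {term:9s} {value:12.0f}{flag}")

shares = variance_proportions(vc)
print("\nshares of total genetic variance (G + GL + GA + GLA):")
for k, v in shares.items():
    print(f"  {k:4s} {100 * v:5.1f}%")
# A large G share means genotype rankings transfer across environments; a
# large GLA share means rankings reshuffle every location-year.

h2 = heritability(vc, incidence_counts(plots, "yield_kg_ha"))
print(f"\nentry-mean heritability H2 = {h2.H2:.3f}")
print(f"harmonic-mean divisors: years {h2.n_years:.1f}, locations "
      f"{h2.n_locations:.1f}, env {h2.n_envs:.1f}, plots {h2.n_plots:.1f}")
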