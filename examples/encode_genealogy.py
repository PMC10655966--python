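"""Encode the genealogy at a focal site as stacked F/W/R matrices.

Simulates a small neutral region, takes the marginal tree at the
segregating site nearest the centre, and prints the three lower-triangular
channels: F counts the branches spanning each inter-coalescent window
(topology), W holds the window spans in generations (branch lengths), and R
repeats the F count restricted to branches carrying the derived allele.
"""

import numpy as np

from popdann import encode_genealogy, extract_focal_genealogy, simulate_region
from popdann.demography import equilibrium
from popdann.genealogy import nearest_segregating_site

ts = simulate_region(
    demography=equilibrium(10_000),
    L=50_000,
    mu=1.25e-8,
    rho=1.25e-8,
    n_samples=8,
    seed=11,
)
site = nearest_segregating_site(ts, 25_000.0)
g = extract_focal_genealogy(ts, site.position)
enc = encode_genealogy(g)

np.set_printoptions(precision=0, suppress=True, linewidth=120)
print(f"focal site at {site.position:.0f} bp, "
      f"{len(g.derived_leaves)}/{g.n} samples carry the derived allele")
print(f"TMRCA: {g.tmrca:.0f} generations\n")
print("F (branches spanning each window; diagonal k+1 by construction):")
print(enc.F)
print("\nW (window spans, generations; diagonal sums to the TMRCA):")
print(enc.W)
print("\nR (the same counts, derived-carrying branches only; R <= F):")
print(enc.R)
print(f"\nstacked input tensor shape: {enc.stacked().shape}"
      f"  (n={g.n} taxa -> {g.n-1}x{g.n-1}x3)")
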