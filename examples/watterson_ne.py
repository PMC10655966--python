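"""Watterson-implied equilibrium Ne of European-demography data.

Simulates 100 neutral 300-kb regions of 32 haploid samples under the
packaged European out-of-Africa model (mutation rate per region from
U[1.875e-8, 3.125e-8]) and prints mean theta_W / (4 * mean mu) — the
constant-size Ne a practitioner would plug into mis-specified equilibrium
training simulations. The value (~6,000) is far below the present-day
European census-scale Ne because the bottleneck still dominates diversity.
"""

import numpy as np

from popdann.demography import european_demography
from popdann.simulate import equilibrium_ne, simulate_relernn_example, watterson_theta

L, n = 300_000.0, 32
demog = european_demography()
thetas = []
for i in range(100):
    ex = simulate_relernn_example(demog, seed=1_000 + i, L=L, n_samples=n)
    thetas.append(watterson_theta(ex.num_sites, n, L))

theta_bar = float(np.mean(thetas))
ne = equilibrium_ne(theta_bar, 2.5e-8)
print(f"mean per-bp Watterson theta over 100 regions: {theta_bar:.3e}")
print(f"implied equilibrium Ne = theta_W / (4 mu_bar)  = {ne:,.0f}")
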