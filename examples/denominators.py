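"""Separable factorization of MP2 energy denominators.

Factorizing 1/(e_a + e_b - e_i - e_j) = sum_w g_w(e_a - e_i) g_w(e_b - e_j)
lets amplitudes be built with one occupied index in the localized basis,
without iterative equations.  Both the pivoted-Cholesky and the Laplace
quadrature routes are shown on a random spectrum.
"""

import numpy as np

from rolmp2 import factorize_denominators

rng = np.random.default_rng(5)
occ = -rng.uniform(0.3, 2.0, 12)
virt = rng.uniform(0.05, 3.0, 30)
gaps = np.unique(np.subtract.outer(virt, occ).ravel())

for method in ("cholesky", "laplace"):
    fac = factorize_denominators([occ], [virt], method, tol=1e-4)
    err = fac.max_error(gaps)
    print(f"{method:9s}  terms {fac.n_terms:3d}   max |1/D - sum_w g g| ="
          f" {err:.2e}   gap range [{gaps.min():.2f}, {gaps.max():.2f}] E_h")
print()
print("A handful of separable terms reproduces every denominator of the")
print("spin-merged range to the requested 1e-4, which is what makes the")
print("redundancy-free per-domain amplitude evaluation possible.")
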