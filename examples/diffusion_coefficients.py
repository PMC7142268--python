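"""Drift and infinitesimal variance of the lethal-allele chain.

Prints F(x) and V(x) on a frequency grid together with their small-x
approximations.  V(x) is not an asymptotic quantity here: it equals the
chain's one-generation variance exactly, and at low frequency it matches
the noise of a neutral population of effective size N / (1 - h).
"""

import numpy as np

import lethalwf as lw

params = lw.PopulationParams(u=1e-5, h=-0.01, N=1000)
tbl = lw.coefficient_table(params, x_grid=np.array(
    [0.0, 1e-4, 1e-3, 1e-2, 0.1, 0.25, 0.5]
))
print(f"{'x':>8} {'F(x)':>12} {'V(x)':>12} {'F small-x':>12} "
      f"{'V small-x':>12}")
for row in tbl:
    print(f"{row['x']:>8.4f} {row['drift']:>12.3e} "
          f"{row['variance']:>12.3e} {row['drift_small_x']:>12.3e} "
          f"{row['variance_small_x']:>12.3e}")

x = 1e-3
v = lw.infinitesimal_variance(x, params)
print(f"\nAt x = {x}: V(x) * 2N / x = {v * 2 * params.N / x:.4f} "
      f"~= 1 - h = {1 - params.h}")
print("so a rare lethal allele drifts like a neutral allele in a")
print("population of size N / (1 - h).")
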