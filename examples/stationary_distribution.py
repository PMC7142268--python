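"""Stationary distribution of the lethal-allele chain in a finite population.

Builds the modified Wright-Fisher kernel (carrier adults drawn as
Binomial(N, 2x + 2F(x))), solves W pi = pi, and prints the stationary
mean frequency for a grid of (u, N) at full recessivity, alongside the
infinite-population equilibrium.
"""

import math

import lethalwf as lw

tbl = lw.stationary_table(
    u_list=[1e-8, 1e-5], N_list=[500, 1000, 2000, "inf"], h_list=[0.0]
)
print(f"{'u':>8} {'N':>6} {'log10 E_stat[X]':>16} {'E_stat[X]/u':>12}")
for row in tbl.itertuples():
    n_lbl = "inf" if math.isinf(row.N) else int(row.N)
    print(f"{row.u:>8.0e} {n_lbl:>6} {row.log10_mean:>16.3f} "
          f"{row.mean_over_u:>12.3e}")

print()
print("Drift pulls the long-run mean frequency well below the")
print("infinite-population equilibrium (two orders of magnitude at")
print("u=1e-8, N=500), because with Nu << 1 the allele is usually absent")
print("and only transiently reintroduced by mutation.")
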