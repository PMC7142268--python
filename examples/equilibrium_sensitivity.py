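"""How sensitive is a lethal allele's equilibrium frequency to dominance?

Evaluates the exact infinite-population equilibrium across a small window
of dominance coefficients around h = 0 for two mutation rates.  For h > 0
the equilibrium is mutation-limited (proportional to u); at h = 0 it is
sqrt(u)-like; for h < 0 (overdominance) it is nearly independent of u —
so a tiny fitness edge for carriers inflates the frequency enormously.
"""

import lethalwf as lw

print(f"{'h':>8} {'x_hat (u=1e-8)':>16} {'x_hat (u=1e-5)':>16}")
for h in (0.01, 0.001, 0.0, -0.001, -0.01):
    row = [
        lw.equilibrium_exact(lw.PopulationParams(u=u, h=h)).x_hat
        for u in (1e-8, 1e-5)
    ]
    print(f"{h:>8} {row[0]:>16.3e} {row[1]:>16.3e}")

print()
print("Moving h from +0.01 to -0.01 (a ~2% fitness change for carriers)")
x_rec = lw.equilibrium_exact(lw.PopulationParams(u=1e-5, h=0.01)).x_hat
x_ovd = lw.equilibrium_exact(lw.PopulationParams(u=1e-5, h=-0.01)).x_hat
print(f"multiplies the u=1e-5 equilibrium by {x_ovd / x_rec:.0f}x "
      f"({x_rec:.2e} -> {x_ovd:.2e}).")
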