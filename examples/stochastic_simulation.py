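"""One stochastic path of the chain, checked against its stationary law.

Simulates 200k generations of a small population with a high mutation
rate, then compares the fraction of time spent at each allele count with
the stationary distribution: the time average matches the ensemble
average.
"""

import numpy as np

import lethalwf as lw

N, u, T = 50, 1e-2, 200_000
counts = lw.sample_trajectory(
    0.0, lw.DominanceSchedule.constant(0.0), u, N, T, seed=42
)
pi = lw.stationary_distribution(lw.PopulationParams(u=u, h=0.0, N=N))
occupancy = np.bincount(counts, minlength=N + 1) / counts.size

print(f"{'count n':>8} {'freq x':>8} {'time fraction':>14} "
      f"{'stationary pi_n':>16}")
for n in range(0, 13):
    print(f"{n:>8} {n / (2 * N):>8.2f} {occupancy[n]:>14.4f} "
          f"{pi[n]:>16.4f}")

mean_time = counts.mean() / (2 * N)
mean_stat = float(pi @ lw.state_frequencies(N))
print(f"\ntime-average frequency  {mean_time:.5f}")
print(f"stationary mean         {mean_stat:.5f}")
print("The long-run time average of a single population equals the")
print("stationary mean over the ensemble (ergodicity of the chain).")
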