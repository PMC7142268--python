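# Methods

## Model and assumptions

The package models a single autosomal biallelic locus in a randomly
mating, discrete-generation population with equal sex ratio and no
inbreeding.  The disease-causing allele *a* is lethal when homozygous
(selection coefficient fixed at s = 1; the constructor rejects anything
else), heterozygote fitness is 1 − h with h ≤ 1, and mutation is one-way
*A* → *a* at probability u per allele copy per generation, acting on
gametes before zygote formation.  The lifecycle is: adults at frequency
x → gametes at y = u + (1 − u)x → zygotes in Hardy–Weinberg proportions
→ viability selection with fitnesses (0, 1 − h, 1) → adults of the next
generation at

    x' = (1 − h) y / (1 + (1 − 2h) y).

The force F(x) = x' − x expands to the rational form quoted in the
README; both the numerator expansion and the discriminant identity
b² + 4ac = h²(1+u)² + 4(1−2h)u used by the equilibrium solver were
verified symbolically with sympy during development.

Lethality of one homozygote bounds the adult frequency at ½ by gene
counting, independent of the model's details.  The finite-population
chain encodes this structurally: the next generation's carrier count is
Binomial(N, 2x + 2F(x)) on states n = 0..N (frequency n/(2N)), since
2x + 2F(x) = 2x' ≤ 1 analytically.  States above N would have
probability zero and are not represented.

## Parameters

| parameter | meaning | units | typical values here |
|---|---|---|---|
| u | one-way mutation probability A→a | per copy per generation | 10⁻⁸ (realistic), 10⁻⁵ (illustrative upper end) |
| h | dominance coefficient; carrier fitness 1 − h | dimensionless | −0.01 … 0.01 around full recessivity |
| N | adult census size | individuals | 500–2000 finite; `INFINITE` for the deterministic limit |
| t_f | duration of the altered-dominance epoch | generations | 2000 |

The dominance schedule is piecewise constant; h(t) governs the
transition from generation t to t + 1, so a jump "at t = 0" changes the
very first transition.

## Numerical choices

**Equilibrium.**  F(x) = 0 reduces to a x² + b x − c = 0 with
a = (1−2h)(1−u), b = h + (2−3h)u, c = (1−h)u.  For b ≥ 0 the root is
evaluated as 2c/(b + √disc), for b < 0 (overdominance) as
(−b + √disc)/(2a); each branch adds quantities of one sign, so no
catastrophic cancellation occurs anywhere in −∞ < h ≤ 1, 0 ≤ u ≤ 1
(naive evaluation of the b < 0 case loses ~8 digits at u = 10⁻⁸,
h = −0.01).  a = 0 (h = ½ or u = 1) collapses to the linear root c/b.
The single degenerate corner h = 1, u = 1 (all zygotes carry the lethal
genotype, mean fitness zero) defines x' = 0.

**Structural bound.**  Every force evaluation asserts
x + F(x) ∈ [−10⁻¹², ½ + 10⁻¹²] and clamps into [0, ½]; larger excursions
raise an internal-consistency error rather than being silently clipped.
The same 10⁻¹² tolerance guards the binomial success probability.

**Stationary distribution.**  Wπ = π is solved densely: (W − I) with the
last row replaced by the normalization Σπ = 1, LU-solved, followed by one
iterative-refinement sweep; the residual ‖Wπ − π‖∞ must be below 10⁻¹²
or the solver errors out.  Dense solves are exact-to-roundoff and fast
at the sizes used here (N + 1 ≤ 2001 states); the kernel cap defaults to
N = 10 000.  With u = 0 the chain is absorbing at n = 0 and the
degenerate point mass is returned with a warning, since uniqueness of π
presumes u > 0.

**Half-times.**  T_1/2 is the time for the (mean) frequency to cover half
the distance from its initial to its final equilibrium/stationary value,
with the midpoint taken arithmetically.  Two bookkeeping conventions are
used, matching how each quantity is naturally computed:

* *Deterministic (infinite N):* the recursion shadows the continuous-time
  solution closely, so the crossing time is linearly interpolated between
  the bracketing generations and rounded to the nearest integer.  This
  yields 461 / 114 / 100 / 59 for the u ∈ {10⁻⁸, 10⁻⁵}, h: 0 ↔ −0.01
  jumps.
* *Finite N:* the count is the generation index at which the propagated
  mean has first reached or passed the midpoint, counting the generation
  in which the environment changes (the census taken immediately after
  the change still reflects the old environment).  This discrete
  convention is one generation longer than the infinite-population one;
  with it the chain reproduces the full published grid of finite
  half-times (37/60/103, 27/37/49 at u = 10⁻⁸; 36/56/88, 27/36/46 at
  u = 10⁻⁵).

Degenerate jumps (equal start and target) raise instead of returning 0.

**Closed-form half-time approximations.**  For the onset of
overdominance, T_1/2 ≈ ln([|h*|/(1+2|h*|)]/√u) / ln(1+|h*|) (geometric
growth at rate 1+|h*| from √u to the overdominant plateau); for the
relaxation back, T_1/2 ≈ ln(1 + 2√u/|h*| − 2u/h*²) / (2√u).  Both are
validated against exact iteration (within 2% and 5% respectively at the
parameter values above).

**Diffusion coefficients.**  V(x) = [x+F(x)][1−(2x+2F(x))]/(2N) is the
chain's exact one-step variance (binomial moment identity), exposed with
its small-x forms F ≈ u(1−h) − hx, V ≈ (1−h)(x+u)/(2N).  No PDE solver
is included: the chain itself is exact and cheap at these scales, so the
diffusion serves intuition (e.g. the effective size N/(1−h) felt by a
rare lethal allele), not computation.

## Known discrepancies in the published reference values

The published stationary-frequency table is internally inconsistent for
h ≠ 0: its infinite-population rows match the exact equilibrium formula
evaluated at ten times the listed h, and our recomputation shows the
finite-N rows share the same shift (e.g. the chain's stationary mean at
u = 10⁻⁸, N = 500, h = −0.01 is 8.375×10⁻⁷, which is exactly the value
printed in the h = −0.001 row).  The equilibrium formula and the
transient results are mutually consistent and are treated as
authoritative; `stationary_table` recomputes and reports all rows, but
only the h = 0 rows are asserted in tests.  The published finite
half-time grid is reproduced in full, which corroborates the recomputed
(not the printed) h ≠ 0 stationary means.

## Problem sizes

The test suite and the acceptance script run the chain at the published
parameter sizes themselves (N up to 2000, dense 2001-state kernels;
deterministic recursions over ≤ a few thousand generations), so nothing
is scaled down.  The Monte-Carlo ergodicity check uses N = 50,
u = 10⁻², 10⁶ generations, comparing per-state occupancy with the
stationary distribution using batch-means standard errors (20 batches)
to absorb autocorrelation.

## Limitations

* The model is specific to a lethal homozygote (s = 1); it does not
  generalize to arbitrary selection coefficients.
* One-way mutation only; back-mutation a → A is ignored (justified when
  u is small and the target of loss-of-function mutation is large).
* Non-overlapping generations, no population structure, no selfing, no
  sex differences; offspring numbers are binomial (no overdispersion).
* The deterministic scenario machinery assumes the pre-jump state is the
  exact equilibrium/stationary state; real populations disturbed more
  recently than a few multiples of T_1/2 will differ.
* Tests exercise the model against its own exact small-system oracles
  and published desk-scale values; they do not validate the biological
  adequacy of the binomial-resampling approximation for any real
  population.
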