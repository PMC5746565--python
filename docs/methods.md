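# Methods

## Model

### The autocatalytic family

The worked network family is the cyclic autocatalytic system on `n ≥ 2`
species: `X_{i−1} + X_i → 2 X_i` (mass-action rate `r`), constant inflow
`∅ → X_i` (rate `α`) and linear outflow `X_i → ∅` (rate `β`), with cyclic
index identification. Rates are uniform across species. The mean-field
concentration equations are

```
dx_i/dt = r x_i (x_{i−1} − x_{i+1}) + α − β x_i ,
```

with the unique uniform steady state `x* = α/β`. The Jacobian there is the
circulant `J = −β I + r x* (C − Cᵀ)` (`C` the cyclic shift): its
eigenvalues are `−β + 2 i r x* sin(2πk/n)`, so the steady state is stable
for every positive parameter choice and the deterministic system never
sustains oscillation. All oscillation in this family is noise-driven,
which is what makes it the canonical quasi-cycle testbed (`n = 3` is
rock–paper–scissors). For `n = 2` the two neighbour couplings coincide and
cancel, leaving `J = −β I` (no oscillation of any kind) — the degenerate
family member is supported but uninteresting.

Arbitrary user Jacobians are accepted directly. Stability is checked and a
warning (not an error) issued when violated, since the analysis presumes a
stable fixed point. If the graph of `J` is disconnected, each weakly
connected component is analysed separately (`component_submatrices`); the
mode count of a reducible system is not the plain union of component
critical points, so per-component reporting is the honest output.

### Fluctuations and resonant modes

About the stable fixed point, fluctuations follow the linear Langevin
equation `dx/dt = J x + η` with white noise of covariance `B`. The
spectrum of species `k` is `P_k(ω) = Q_k(ω²) / R(ω²)` where

```
R(ω²) = |det(−iω I − J)|² = det(J² + ω² I),
```

a degree-`n` polynomial in `x = ω²` equal to the characteristic polynomial
of `J²` under `x = −λ`. A **resonant mode** is a local minimum of `R` on
`x > 0`; its frequency is `ω_R = √x`. Because `R(0) = det(J)² ≥ 0` and
`R → +∞`, minima and maxima alternate and the largest positive critical
point, when one exists, is a minimum. The numerator polynomials `Q_k`
depend on `B` and can in principle suppress a peak; we assume the generic
case in which they do not, so the mode count is a property of `J²` alone.
At most `⌊n/2⌋` modes are possible (one per conjugate eigenvalue pair of
`J`); this bound is asserted on every result.

## Exact mode counting

1. `R(x) = det(xI + J²)`. Float matrices go through numpy's
   eigenvalue-based characteristic polynomial; integer/Fraction matrices
   through an in-package Faddeev–LeVerrier recursion over
   `fractions.Fraction`, so the entire pipeline below is exact for
   rational inputs (decimal-literal parameters such as `0.1` are read at
   their printed decimal value).
2. The canonical Sturm chain of `R'`: `p₀ = R'`, `p₁ = R''`,
   `p_{i+1} = −rem(p_{i−1}, p_i)`, stopping at a zero remainder. For
   inputs with repeated roots the chain ends at the gcd and the count is
   of *distinct* roots, which is what classification needs.
3. The number of distinct positive roots of `R'` is
   `σ(0) − σ(∞)`: sign changes of the chain's constant terms minus sign
   changes of its leading coefficients, zeros skipped. A root of `R'` at
   the origin is divided out first and not counted.
4. Each root is isolated by bisection on the Sturm count over
   `(0, CauchyBound]`, refined to relative width `1e−10`, and classified
   by the sign of `R'` sampled *between* consecutive isolating intervals
   (where the sign is provably constant); right of the largest root the
   sign is that of the leading coefficient. A critical point where `R'`
   does not change sign (even multiplicity) is an inflection of `R`:
   excluded from the mode count with a warning.
5. Modes = minima; `ω_R = √x` at each minimum.

Descartes' rule of signs is provided as the fast upper bound (always
`≥` the Sturm count, same parity when `p(0) ≠ 0`).

**Floating-point policy.** Sign decisions are the method's only fragile
step: when a Sturm coefficient is tiny, rounding can flip it. Float
coefficients below `1e−12` of the polynomial's largest coefficient are
treated as exact zeros, and point evaluations are zeroed below
`1e−12 · Σ|c_i| · max(1,|x|)^deg` (a conservative bound on accumulated
Horner error). Since zeros are *skipped* in sign-change counts, an
over-wide zero classification degrades gracefully. The classification
step deliberately avoids this tolerance by sampling away from all roots.
Rational inputs bypass the issue entirely.

### The three-species closed form

For `n = 3`, `R = x³ + a₁x² + a₂x + a₃` and `R' = 3x² + 2a₁x + a₂`; the
chain of `R'` is `(3x² + 2a₁x + a₂, 6x + 2a₁, a₁²/3 − a₂)`. Resonance
holds iff `σ(0) − σ(∞) ∈ {1, 2}`: one critical point means the minimum
branch alone crosses zero; two means a maximum/minimum pair, and the
larger critical point is always the minimum. `n3_resonance_condition`
evaluates this directly from `(a₁, a₂)` and is cross-checked against the
full classification pipeline on coefficient grids and on random stable
Jacobians.

## Graph-theoretic coefficients

`J²` is read as the adjacency matrix of a weighted digraph: edge `i → j`
iff `(J²)_{ji} ≠ 0` (note the index order), self-loops whenever a diagonal
entry is nonzero (diagonal entries of a squared matrix carry no fixed
sign, so they cannot be dropped by sign convention; the sign lives in the
weight). The coefficient of `x^{n−k}` in `det(xI + A)` is

```
a_k = Σ over degree-k factors f of (−1)^{k−|f|} Π_{c∈f} w(c),
```

a factor being a set of pairwise vertex-disjoint simple cycles covering
exactly `k` vertices and `|f|` its number of cycles. The sign convention
follows from the permutation expansion of the principal minors (a
`k`-permutation with `m` cycles has sign `(−1)^{k−m}`) and is pinned by a
mandatory test against direct determinant expansion — the test, not the
derivation, is authoritative. `a₁ = Tr(A)` and `a_n = det(A)` fall out as
special cases.

Cycle enumeration delegates to `networkx.simple_cycles` (self-loops
included); factor enumeration recurses over cycles in a fixed order,
which guarantees each factor is produced exactly once. Since `J²` is
generically dense, the graph is essentially complete and enumeration is
exponential: practical up to `n ≈ 8`, with factor finding the bottleneck.
Float zero-tolerance for edge existence is `1e−12` relative to the
largest entry; exact matrices use exact zero.

## Phase diagrams

The swept slice is `α = β` (so `x* = 1` and the effective coupling is
`r`) versus `r`. Default window: `α = β ∈ [10⁻³, 1]`, `r ∈ [10⁻¹, 10]`,
log-spaced, 200×200 — wide enough to contain both printed operating
points, (0.1, 1) for `n = 3` and (0.01, 4) for `n = 5`, and all phases of
both families; fully configurable. Each cell builds the closed-form
Jacobian and runs the float Sturm pipeline (~1 ms/cell). Connected
regions of equal mode count are labelled by flood fill with 4-neighbour
(edge) connectivity — the conservative choice, since 8-connectivity can
merge regions touching only at a corner. Region-count stability is
checked by doubling the resolution. Unstable cells (impossible for this
family, which is provably stable) would be flagged and excluded from
labelling.

The eigenvalue comparator counts conjugate pairs of `J` with
`Im(λ)² − Re(λ)² > 0` (pairs identified as eigenvalues with
`Im λ > 10⁻⁹` relative). It examines one quadratic factor of `R` at a
time, so it over-predicts: on the five-species sweep every Sturm-positive
cell satisfies the eigenvalue criterion, while roughly a fifth of the
cells are eigenvalue-positive but Sturm-negative (false positives). The
comparison table reports both counts per cell.

## Simulation and spectra

**Noise model.** The covariances `B` of the reduced Langevin equation are
exactly what this method avoids computing; generically they do not affect
the *number or location* of spectral peaks, only their shapes and
relative intensities. The default is therefore demographic-noise scaling
`B = (1/Ω) I` with system size `Ω`; a user-supplied `B` is accepted when
faithful spectral shapes are wanted.

**Integration.** Euler–Maruyama:
`x_{t+dt} = x_t + J x_t dt + L √dt ξ_t` with `L Lᵀ = B` (PSD-safe
eigenvalue square root) and `ξ` standard normal; all repetitions run
vectorized from one seeded generator. The explicit scheme amplifies
weakly damped rotation unless `dt · Im(λ)² / 2 < |Re(λ)|`; a warning is
emitted whenever `max|1 + dt λ| ≥ 1`. The defaults used for the two
worked regimes follow from this rule: `dt = 0.01` for the three-species
network (`λ ≈ −0.1 ± 1.73i`), `dt = 2·10⁻⁴` with every-250th-step
recording for the five-species network (`λ ≈ −0.01 ± 7.61i`). Decimated
recording aliases high-frequency noise into a slightly raised flat floor,
which is irrelevant to peak detection. Trajectories start at the fixed
point (zero fluctuation); the first 10% of each record is discarded as
transient.

**Spectra.** Per-species periodograms of the post-transient segment
(constant detrend), averaged over repetitions, reported on the angular
frequency grid `ω = 2πf` and normalized to unit area by the trapezoid
rule, matching the convention used for the analytic curves. The analytic
spectrum is computed from complex linear solves
`P_k(ω) = [(iωI − J)⁻¹ B (iωI − J)⁻ᴴ]_{kk}` — no symbolic adjugates, so
it scales to any `n`.

**Peak detection.** The spectrum (species mean by default) is smoothed by
a 5-bin reflect-padded moving average; peaks are interior local maxima
with prominence at least 5% of the smoothed spectrum's range and height
at least twice its median. The range-relative prominence rejects noise
wiggles riding on spectral flanks; the median-relative height rejects the
wiggles of a genuinely flat spectrum. Detections are refined to the raw
spectrum's argmax within the smoothing window. There is no canonical
criterion here; the thresholds are deliberately coarse and configurable,
and the validated quantities are peak *count* and *location* (within two
frequency bins of the analytic peaks), not curve shape — reproducing
exact spectral shapes would require the true `B`.

Run sizes used by the validation suite and acceptance script: `n = 3` at
`Ω = 5000`, 200 repetitions of 200 time units; `n = 5` at `Ω = 10⁴`, 100
repetitions of 400 time units. These resolve the relevant peaks with
frequency-bin widths of ~0.035 and ~0.017 rad/time respectively.

## What the synthetic setup does and does not show

The generator *is* the study system: the autocatalytic family plus seeded
random stable matrices (left-shifted Ginibre draws) for property tests.
Passing tests demonstrate exactness of the root counting and coefficient
assembly for real matrices, and agreement of simulated spectra with the
linear-noise prediction *of the linear model*. They do not probe: the
quality of the linear-noise approximation itself at small `Ω` (no
master-equation/Gillespie simulation is performed), species-specific
rates, mode suppression by non-generic numerators `Q_k`, or networks
large enough (`n ≳ 8`) for factor enumeration to become infeasible.

## Known limitations

* Factor/cycle enumeration is exponential; `n ≲ 8` in practice.
* Float Sturm counts can misjudge polynomials engineered with
  near-degenerate critical points; rational mode exists precisely for
  such cases.
* The `α = β` slice is the only built-in sweep (matching the reported
  phase diagrams); other slices require user code over the library.
* Peak detection thresholds are heuristic; pathological spectra (e.g.
  shoulder peaks far below 5% prominence) need hand-tuned parameters.
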