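# Methods

## Model class

`citsens` works with well-stirred, constant-volume biochemical reaction
networks: N species, M reaction channels, integer copy-number state
X(t) ∈ ℕ^N. Channel j has a stoichiometric change vector ν_j and a
propensity a_j(x); a_j(x)dt is the probability that channel j fires once
in [t, t+dt). The probability law of X(t) obeys the chemical master
equation (CME). Supported propensity forms are stochastic mass action up
to third order (combinatorial counting: c·x, c·x(x−1)/2, c·x_i x_j, and
falling factorials divided by multiplicity factorials at third order) and
a Hill repression form scale·c/(1 + x_r^β) for repressor-controlled
transcription. Restricting to these forms keeps the Newton Jacobians of
the implicit solvers exact and analytic.

The quantity of interest is the local parametric sensitivity of an
expected observable, approximated by the forward finite difference

    S_h(t) = [E f(X^{c+h}(t)) − E f(X^c(t))] / h,

where c is one channel's stochastic rate constant, h a small
perturbation, and f a linear observable (species count or linear
combination). All estimators in the package are Monte Carlo estimators of
S_h; they differ in how paths are generated and how the two ensembles are
coupled.

## Estimators

**CFD (exact coupling, baseline).** Each reaction channel is split into a
shared channel with rate m_j = min(a_j^c(X^c), a_j^{c+h}(X^{c+h})) that
fires in both legs, and two residual channels that fire in one leg each.
The 3M channels are simulated exactly with the modified next-reaction
method over internal times of unit-rate Poisson processes; all rates are
refreshed after every firing (exact; refresh frequency is not prescribed
by the coupling itself). Each leg is marginally an exact CME sample, and
because the shared channel carries almost all the rate when h is small,
the per-path difference Z(t) = (f(X^{c+h}) − f(X^c))/h has far smaller
variance than a difference of independent ensembles.

**CIT (coupled implicit tau-leaping).** Paths advance by adaptive
implicit leaps. Per step, with both legs' propensities in hand:

1. *Partial equilibrium.* A reversible pair is flagged in equilibrium
   when |a⁺ − a⁻| ≤ δ·min(a⁺, a⁻). Flags are computed from the nominal
   leg and applied to both (a per-leg flag could differ only in boundary
   states; a shared partition is required for the shared leap).
   Flagged pairs are exempt from the step-size constraint.
2. *Criticality.* For each remaining active channel (positive propensity
   on either leg), L_j = min_i ⌊x_i/|ν_ij|⌋ over consumed species,
   minimised over the two legs; channels with L_j < n_c are critical and
   advance by exact single firings. Channels consuming nothing are never
   critical. A pair flagged in equilibrium is excluded before
   criticality is applied.
3. *Non-critical candidate τ₁* bounds each reactant's expected change and
   variance over the step by max{εx_i/g_i, 1}, where μ̂ and σ̂² sum
   ν_ij a_j and ν_ij² a_j over non-critical, non-equilibrium channels and
   g_i encodes the highest order at which species i reacts within that
   set (with the homo-reactant corrections 2 + 1/(x−1),
   (3/2)(2 + 1/(x−1)), 3 + 1/(x−1) + 2/(x−2); a divisor ≤ 0 falls back to
   g_i equal to the order, where the bound is clamped at 1 anyway).
   Species considered are the reactants of that same channel set.
4. *Critical candidate τ₂* is exponential with rate equal to the critical
   propensity sum, drawn per leg with its own uniform.
5. *Branching.* τ is the smallest of the four candidates. A critical
   reaction fires only when a τ₂ attains the minimum — on the nominal
   leg, the perturbed leg, or (exact tie) both, selected by cumulative
   search with one shared uniform. The printed branch logic compares the
   two legs conjunctively and leaves the mixed case open; taking the
   global minimum covers it and is degenerate for small h.
6. *Coupled leap.* Over non-critical channels, shared/residual Poisson
   counts P1 ~ Poi(m_j τ), P2 ~ Poi((a_j^c − m_j)τ),
   P3 ~ Poi((a_j^{c+h} − m_j)τ) are drawn; each leg solves its
   semi-implicit update (the mean part of each Poisson term evaluated at
   the end-of-step state) by damped Newton with the analytic Jacobian,
   warm-started at the current state. Critical firings are applied on
   top. Failures (Newton stall, negative populations) halve τ, cancel
   the no-longer-reached critical firing, redraw and retry; a path that
   exhausts its retry budget is excluded and counted.

The sensitivity sample Z(t) is recorded on the output grid. Leap steps
are clamped so they land exactly on requested output times: the state of
a leap method is only defined at step boundaries, and with partial
equilibrium active a single leap can otherwise span the whole horizon,
leaving interior grid points with arbitrarily stale values. Clamping is
harmless — a shorter implicit leap is strictly more accurate, and an
interrupted critical exponential clock restarts without bias by
memorylessness. (The exact simulators record by carry-forward, which is
exact for jump processes.)

**Uncoupled baselines.** `implicit-fd` and `ssa-fd` build the finite
difference from independent ensembles at c and c + h (adaptive implicit
single paths and exact SSA paths respectively); they are the variance
reference the coupling is measured against.

## Rounding of implicit solutions

The implicit update has a continuous solution; states must return to the
integer lattice. For *single-path* simulation the solution is rounded
componentwise to the nearest integer and clamped at zero, as in the
implicit tau-leaping literature.

For the *coupled* leap this choice is measurably wrong: the difference
between the legs is typically far below one molecule, and the fractional
parts being rounded are driven by the same shared Poisson draws on both
legs, so deterministic rounding injects a systematic quantisation error
into exactly the signal the estimator divides by h. On the pure-decay
benchmark (closed-form sensitivity −303.3) deterministic per-leg rounding
gave −312.7 ± 2.7 across 3×10⁴ paths, while a continuous-state diagnostic
run gave −295 ± 4.6. The coupled leap therefore uses stochastic rounding
with one shared uniform per species: round up with probability equal to
the fractional part. This makes the rounded state unbiased
(E[round(U)] = U) regardless of correlations, acts as a common random
number for the quantisation, preserves the h = 0 bitwise identity, and
left the coupled estimator's variance unchanged on the stiff
decay-dimerisation benchmark (30.7 vs 29.0 at R = 400).

## Numerical choices

- Newton convergence: infinity norm of the update < TOL (default 0.01);
  step halving (up to 16×) when the residual norm increases; iteration
  cap 50. Propensities are evaluated at max(U, 0) inside the solver so
  transiently negative iterates cannot raise.
- Defaults ε = 0.05, δ = 0.05, TOL = 0.01, n_c = 10 (n_c = 5 for the
  toggle switch) — the published settings of the benchmark studies.
- Step retries: 12 halvings before a path aborts; ensembles fail hard if
  more than 1% of paths abort.
- Ties between next-reaction channels break toward the lowest channel
  index (measure-zero; keeps seeds reproducible).
- Degenerate steps: when no channel can fire the state freezes to T;
  when only equilibrium-exempt channels remain (no finite candidate) the
  leap extends to the horizon.
- Reproducibility: every ensemble derives per-path generators from one
  master seed via `SeedSequence(seed, spawn_key=(path, ...))`; identical
  seeds reproduce every path bitwise.

## The truncated-CME oracle

For validation the master equation is solved directly on an axis-aligned
box: the truncated generator (columns summing to ≤ 0; probability leaks
only through the boundary) is exponentiated with sparse
`expm_multiply`, and 1 − Σp bounds the truncation error. Boxes are either
supplied explicitly or doubled adaptively until the retained mass reaches
1 − 10⁻⁶. This is tractable to roughly 10⁵ states, i.e. for the toy and
reduced models only. `cme_sensitivity` differences two deterministic
solves at c and c + h — the exact value of S_h that every stochastic
estimator with the same h must approach.

## Benchmark models and reduced variants

The packaged stiff models are the decay-dimerisation chain
(C = (0.05, 50, 10⁶, 0.05), x0 = (400, 800, 0), reversible pair R2/R3),
the genetic positive feedback loop
(C = (5000, 10⁶, 5000, 10⁶, 10, 20, 1, 0.8, 7), x0 = (10, 20, 10, 40, 0),
pairs R1/R2 and R3/R4) and the Collins toggle switch (α = 28.98,
β = γ = 4, other constants 0.23, x0 = (76, 75, 60, 60), stiffness scale k
on transcription/mRNA-degradation channels R1, R2, R5, R6). For the
toggle switch the state convention is (X1..X4) = (p1, p2, m1, m2): the
mRNA degradation propensities reference X3/X4 while repression is carried
by the protein indices — inferred from the published initial condition
and output labelling, and worth flagging because the reaction list is
written in transcript order.

Validation models: pure decay (closed-form mean and sensitivity),
two-state isomerisation (binomial law), and two reduced variants defined
in code because the full state spaces are far beyond any direct CME
solve:

- `decay_dimer_reduced`: C = (0.05, 0.5, 30, 0.05), x0 = (100, 20, 0).
  Started off the fast-pair equilibrium so a run exercises relaxation,
  equilibrium detection and large leaps; the conservation relation
  X1 + 2X2 + 2X3 bounds the state space (box (124, 62, 16) retains
  > 1 − 10⁻⁶ mass at T = 1).
- `feedback_loop_reduced`: C = (0.03, 0.6, 0.06, 4.3, 2, 4, 1, 0.8, 3.5),
  x0 = (52, 66, 26, 24, 42), near its quasi-steady state. Same topology,
  rates brought to a common time-scale so exact coupled simulation over
  the full horizon is affordable.

**Why the reduced variants look the way they do.** The
partial-equilibrium exemption is self-sustaining only when the implicit
leap re-damps a pair inside one step: after a leap of size τ the pair's
propensity imbalance has residual magnitude ≈ √(2a_pair/τ), so
|a⁺ − a⁻| ≤ δ·a requires a_pair·τ ≳ 2/δ² = 800. The published stiff
models satisfy this by orders of magnitude (a_pair ~ 10⁷–10⁸ against
slow-species steps τ ~ 0.5); any variant cheap enough for exact coupled
simulation cannot, and the adaptive scheme then falls back to SSA-scale
steps around the fast pair. The reduced decay-dimerisation sits just
inside the self-sustaining regime; the reduced feedback loop is
deliberately non-stiff and is used only where stiffness is not the
property under test (estimator consistency). In addition, the
equilibrium test resolves a pair's balance only when copy numbers exceed
≈ 2/δ = 40 (one firing must move the imbalance by less than δ·a), which
sets the copy-number floor of both variants.

## What the tests show — and what they do not

The validation suite checks: exact coupling degeneracy at h = 0 (bitwise,
all three stiff fixtures); recovery of the closed-form pure-decay
sensitivity by both estimators; agreement of the CIT estimate with the
deterministic CME finite difference on the reduced decay-dimerisation
model; total-variation agreement of SSA and both CFD legs with the CME
law; stiff stability (the adaptive implicit method crosses the
decay-dimerisation problem in < 10³ leaps where a fixed explicit leap of
the same average size immediately goes negative); variance reduction of
the coupling against the uncoupled implicit-tau difference at 99%
bootstrap confidence; nominal-leg mean fidelity against SSA; and CIT–CFD
consistency on the feedback topology.

Ensemble sizes (10³–10⁵ paths by check), horizons and the reduced-variant
parameterisations are the package's own choices, sized so the whole suite
runs on one core in minutes; every comparison is a 3-standard-error or
bootstrap-confidence test whose validity does not depend on ensemble
size. What passing does *not* show: accuracy of CIT on models whose fast
pairs live at low copy numbers (the flicker regime above — the method
runs but loses its efficiency edge); behaviour for nonlinear observables
f; the wall-clock speed-ups of the original studies (hardware-dependent;
reported informationally by the CLI metadata, never asserted); and
automatic selection of h, which remains the user's responsibility (small
enough for locality, large enough that the difference signal beats the
Monte Carlo floor).

## Known limitations

- Perturbations address one reaction's rate constant; shared constants
  across channels are out of scope.
- The implicit leap damps fast-variable fluctuations within a step by
  design; distributional (not mean) statistics of fast species on
  sub-relaxation time-scales should be read from the exact simulators.
- The CME oracle certifies only retained probability mass, not a full
  finite-state-projection error bound.
- Propensity forms are fixed to mass action (≤ 3rd order) and Hill
  repression; arbitrary rate laws would break the exact-Jacobian Newton
  solves and are deliberately unsupported.
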