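# Methods

## The model

`tcellfate` models the decision circuit of a pair of lineage-defining
master regulators (X, Y) — e.g. T-bet/GATA3, T-bet/RORγt or Foxp3/RORγt in
CD4⁺ T helper cells — as a soft-threshold influence network.  Each protein
activity `X_i ∈ [0, 1]` obeys

    dX_i/dt = γ_i ( F(σ_i W_i) − X_i ),      F(u) = 1 / (1 + e^(−u)),
    W_i = ω_{i0} + Σ_j ω_{j→i} X_j + Σ_s ω_{s→i} S_s,

where `ω_{j→i}` are dimensionless influence weights (negative for the
mutual inhibition between the regulators, positive for auto-activation),
`ω_{i0}` basal weights, `σ_i > 0` the sigmoid steepness, `γ_i > 0`
relaxation rates, and `S_s ≥ 0` the exogenous signal levels: a primary
signal S1 driving both regulators and two polarizing signals S2/S3 each
favoring one of them.  All quantities are phenomenological and
dimensionless; one time unit corresponds to roughly 1.5 days of real
differentiation time.  Because `0 < F < 1`, the unit box is forward
invariant and every attractor is a stable fixed point; the circuit is
gradient-like and has no oscillations, so the analysis machinery is built
entirely around steady states and their bifurcations.

A cell's phenotype is read off its resting state with a strict expression
threshold of 0.5: naive (neither regulator above threshold), X- or
Y-single-positive (XSP/YSP), or double positive (DP).  A state exactly at
0.5 counts as not expressed.

An optional per-signal Michaelis–Menten transform `s → s_max·s/(K+s)` is
available for saturating primary signals.  It is off by default and its
functional form is an implementation choice, not part of the core model.

## Steady states and continuation

`find_steady_states` refines a multistart grid over `[0,1]^N` (default
5 points per dimension; diagram grids use 7) with a damped Newton
iteration on `F(σW) − x = 0`, merges roots within `1e−5` (max-norm),
rejects anything with rate residual above `1e−8`, classifies stability by
the eigenvalues of the analytic Jacobian

    J_ij = γ_i σ_i F'(σ_i W_i) ω_{j→i} − γ_i δ_ij,

and returns the list sorted lexicographically so outputs are reproducible.
Eigenvalues with `|Re| < 1e−9` are treated as marginal and the state is
conservatively labelled unstable with a warning.  For stability maps over
signal grids all grid points share the network, so every Newton start of
every grid point runs in one vectorized batch with closed-form 2×2 solves
(`batch_fixed_points`); this is what keeps a 101×101×2 bidirectional
diagram in the tens of seconds.

Branches are traced by pseudo-arclength continuation: SVD tangent,
tangent-constrained Newton corrector, adaptive step (initial 1e−2, halved
on corrector failure, capped at 5e−2).  Folds are flagged by a sign change
of the parameter component of the branch tangent and refined on the
extended system `[g; Jv; |v|²−1] = 0`.  On mirror-symmetric branches of
symmetric networks the swap-antisymmetric eigenvalue (exact for the
two-node mirror) is monitored; its zero crossing marks a pitchfork, which
is refined by bisection to 1e−6 in the parameter.

Pitchfork criticality is decided from the emergent asymmetric branches:
the bifurcation point is first re-solved to machine precision (the d²
branch offsets below would otherwise be swamped by the 1e−6 detection
tolerance), then the asymmetric fixed point is solved at prescribed
amplitudes d and 2d along the anti-invariant direction, the quadratic
coefficient of `p(d) − p*` is Richardson-extrapolated, and its sign is
compared with the side on which the symmetric state destabilizes:
same side and stable branches → supercritical; opposite side →
subcritical; a vanishing coefficient → "indeterminate", never a guess.
The classifier works on any Z2-equivariant vector field
(`PitchforkProblem`), so the textbook normal forms serve as unit tests.

Two-parameter loci are traced by stepping the second parameter and
re-solving the fold system in `(x, v, param1)`.  The pair of folds born at
the two pitchforks of a symmetric model bounds the bistable arch; both are
continued upward with a step size slaved to their separation, and the
coalescence ordinate (the cusp that closes the region) is extrapolated
from the `separation^(2/3)` power law once the loci approach within 1e−4.
Asymmetric models show no pitchforks on the branch through the naive
state; their broken pitchforks are represented as the fold pairs of the
disconnected branch, which is what the detection machinery reports.

## Calibrated models

Exact parameter tables for the published generic and prototype models were
not available, so every registry model carries `provenance = "calibrated"`
and its parameters are produced by documented calibration against the
published bifurcation landmarks:

* **Generic Model 1** (symmetric core, no auto-activation).  With σ fixed
  at 3 by design, γ = 5, and the S1 weight normalized to 1, the pitchfork
  condition on the symmetric branch is analytic:
  `x(1−x) = 1/(σw)` with `S1 = logit(x)/σ − ω0 + w·x`.  The
  mutual-inhibition weight `w` is solved from the pitchfork spacing
  (2.396 − 0.704) by 1-D root finding, ω0 from the lower pitchfork
  position, and the polarizing weight scales the fold-coalescence
  ordinate (computed with the locus tracer in the raw-drive coordinate)
  onto the cusp value 0.357.  Result: `w = 1.8136495`,
  `ω0 = −0.6431752`, polarizing weight `0.4893048`.  The three landmark
  targets determine exactly three free scalars; fixing σ is the package's
  normalization choice and any σ in a window around 3 would give an
  equivalent model with rescaled weights.
* **Generic Model 2** (asymmetric variant): Model 1 with the S1→Y weight
  raised to 1.08.  The primary signal then upregulates the two regulators
  at different thresholds, the axis shows folds instead of pitchforks, and
  the bistable region tilts so its two cusps sit on opposite sides of the
  S1 axis — the qualitative signature of the broken-symmetry case.
* **Generic Model 3** (symmetric core plus shared auto-activation weight
  ω, exposed as the `auto_weight` override, default 1.5).  The pitchfork
  positions are again analytic (`x(1−x) = 1/(σ(ω+w))`), and the
  supercritical→subcritical transition weight depends only on (w, σ), so
  (w, σ) are solved as a 2×2 root problem from {transition at ω = 1.8,
  pitchfork spacing 0.7 at ω = 1.5} and ω0 places the lower pitchfork at
  1.7.  Result: `w = 1.1251090`, `σ = 1.7273751`, `ω0 = −2.2374455`,
  satisfying `σw < 4`: the mutual inhibition alone cannot create
  bistability, exactly the regime the model is meant to illustrate.  The
  polarizing weight (0.5) is a presentation choice that puts the cusp
  structure inside the default S2/S3 ∈ [0, 1] window.

At ω = 3.2 the calibrated Model 3 splits the bidirectional plane into the
expected 11 stability signatures (4 monostable, 5 bistable, 2 tristable),
and at ω = 4.5 a tetra-stable region (naive + XSP + YSP + DP) appears —
both emergent properties, not calibration targets.

The three prototype models map the motif onto real lineages (T_H1/T_H2,
T_H1/T_H17, iT_reg/T_H17).  Their weights were hand-calibrated, starting
from the Generic Model 3 core, until the population simulator reproduced
each model's qualitative outcome table (polarizing signals alone induce
nothing; antigen-dose control of the T_H1/T_H2 spectrum; the T-bet⁺RORγt⁻
plus double-positive mix under IL-23/IL-1; the tri-phenotype iT_reg/T_H17
mixture at intermediate drive; the knockout behaviors).  Two anchor values
are fixed rather than tuned: the T-bet basal weight of Prototype 2 is
−1.7, and its knockout sets it to ten times that value (−17); the GATA3
auto-activation knockdown multiplies the corresponding weight by 0.1.
Hand-calibration targeted only the categorical outcomes; the specific
signal doses stored in each bundle's `default_conditions` are the
conditions under which those outcomes are asserted in the test suite.

## Population simulation

A population of `n_cells` (default 200) shares the basal network's
topology; every nonzero parameter of every cell is drawn independently
from `Normal(mean = basal, sd = cv·|basal|)` with `cv = 0.05` by default.
Zero weights encode absent edges and are never perturbed; σ and γ are
redrawn while nonpositive (more than 100 redraws is an error).  Cells
first relax from small initial values (0.01) with all signals off; every
cell must land in a naive state, otherwise the model is reported as having
no naive state.  Stimulus protocols are ordered stages of signal levels;
each stage runs to rest (max |dX/dt| < 1e−9, cap 1000 time units) rather
than for a fixed duration, and states carry over between stages.  In
sequential protocols every stage specifies the full signal vector, so a
"polarizing then primary" protocol keeps the polarizing signal present in
the second stage.

The whole population is integrated as one stacked ODE system (RK45,
rtol 1e−8) in growing time chunks; once the global rate falls below 1e−5
a batched per-cell Newton polish lands each cell exactly on its nearby
fixed point (plain time stepping stalls at the ODE solver's error floor
above such tight rate tolerances; the polish refuses steps larger than
0.05 so it cannot jump basins).  Composition grids spawn one fresh
population per grid point with child seeds derived deterministically from
the master seed (`resample_per_point=False` reuses a single population
everywhere); identical master seeds therefore give bit-identical grids.
A failing grid point is logged and left empty; the grid completes.

The heterogeneity score of a composition over phenotypes of interest
P_1…P_n (2 ≤ n ≤ 4) is

    S_H = Σ_{i<j} ( C_i + C_j − 2|C_i − C_j| ) / ((n−1) N) ∈ [−1, 1],

≈1 for comparable counts, ≈−1 under single-phenotype dominance, ≈0 when
the phenotypes of interest are rare.  The absolute-value placement is the
unique reading consistent with those three limits, which the test suite
checks explicitly alongside a brute-force double-loop oracle.

## What the generator emulates — and what it does not

Parametric variability stands in for slow cell-to-cell differences
(expression capacity, receptor numbers) frozen over the few-day
differentiation window.  It deliberately omits intrinsic molecular noise
during the transient, cell division and death, and all cell-to-cell
communication (paracrine cytokine feedback), and it treats exogenous
signals as constants per stage.  Passing tests therefore certify the
deterministic multistability structure and the basin-splitting mechanism
of heterogeneous differentiation — not quantitative composition
predictions for real cultures, where communication and division bias the
outcome.  One consequence visible in the tests: with CV = 0.05 a minority
of sampled cells are asymmetric enough to be monostable where the average
cell is bistable, so "every cell flips irreversibly" statements hold only
for the cells that actually possess the bistable switch.

## Numerical choices and degenerate cases

* Logistic evaluated in a branch-stable form; inputs must be finite.
* Steady-state dedup 1e−5, residual bound 1e−8, marginal-eigenvalue band
  1e−9; deterministic lexicographic ordering.
* Continuation: initial step 1e−2, minimum 1e−6; special points refined to
  1e−6; duplicate special points within 1e−6 merged.
* The cusp ordinate is extrapolated once the fold separation is below
  1e−4; against an independent dense attractor-count scan the Generic
  Model 1 value is bracketed within ±1e−3.
* Grid points lying numerically on a locus take whatever signature
  `find_steady_states` returns there; no smoothing across cells.
* Populations: Newton polish threshold 1e−5, basin-escape guard 0.05;
  grid child seeds are the first 31 bits of spawned `SeedSequence` states.
* Problem sizes in the shipped tests (diagram grids up to 101×101, 20×20
  composition grids with 50 cells, 200-cell populations for the
  seed-symmetry check) were chosen to exercise the published settings or
  a documented reduction of them while keeping the default suite quick.

## Known limitations

* Pitchfork detection requires the exact two-node mirror symmetry; in
  asymmetric models only folds are reported (the broken pitchfork appears
  as the fold pair of the disconnected branch).
* Criticality classification is implemented for a one-dimensional
  anti-invariant subspace (simple pitchforks), which covers all shipped
  models.
* No Hopf/limit-cycle machinery: the motif is gradient-like by
  construction.
* The calibrated parameter sets are one consistent solution matching the
  published landmarks, not a reconstruction of the original tables; all
  downstream numbers that depend on them inherit that caveat, and the
  `provenance` field says so on every bundle.
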