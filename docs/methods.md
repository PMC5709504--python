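# Methods

## The model

Measured cell-cycle times (CCTs) are far less variable than an
exponential distribution with the same mean: a newly born cell must
traverse G1, S, G2 and M before it can divide, so the probability of an
immediate re-division is essentially zero, whereas the exponential
density is maximal at zero. Stochastic population models that represent
division as a single first-order "reaction" (so they can be simulated
with the Gillespie algorithm) therefore misrepresent proliferation — not
only its variance but, less obviously, its *mean*.

`stagecycle` restores a realistic CCT distribution without leaving the
Markovian world the Gillespie algorithm requires. The cell cycle of mean
length `C` is split into `k` fictitious sequential stages,

    X_1 --λ_1--> X_2 --λ_2--> ... --λ_k--> X_k --> 2 X_1,

each residence time exponential with rate `λ_i`. The total CCT is then
hypoexponential with mean `Σ 1/λ_i` and variance `Σ 1/λ_i²`. Two
identifiable special cases are used throughout:

* **Erlang**: all rates equal, `λ = k/C`. Variance `C²/k` can be made
  arbitrarily small by raising `k` at fixed `C`.
* **Exponentially modified Erlang (EME)**: `k` equal-rate stages at
  `λ_1` plus one final stage at `λ_2`. Its closed-form density
  `λ_2 e^{-λ_2 t} (λ_1/L)^k P(k, Lt)` (with `L = λ_1 - λ_2` and `P` the
  regularized lower incomplete gamma function) is valid on the branch
  `λ_1 > λ_2`; the other branch would put a negative argument into the
  incomplete gamma function, so it is served by direct numerical
  convolution of the Erlang and exponential densities instead. The
  regularized form is used deliberately: the naive bracket
  `1 - Γ(k, Lt)/(k-1)!` cancels catastrophically at large `k`.
  Both stages are ordinary exponentials, so EME CCTs also simulate
  exactly in a Gillespie loop — that is the whole point.

The stages are a mathematical device: they need not map onto the
biological phases one-to-one.

## Analytic mean dynamics

The mean stage counts `M_j` of the pure-birth chain obey the linear
cyclic system `dM_1/dt = 2 λ_k M_k - λ_1 M_1`,
`dM_j/dt = λ_{j-1} M_{j-1} - λ_j M_j`. With equal rates it diagonalises
over the k-th roots of unity `z^r = e^{2πir/k}`, giving the exact series
implemented in `exact_stage_mean` / `exact_total_mean` (initial
condition: one cell in stage 1). `z` is taken with the positive sign of
the exponent; conjugate symmetry makes the real part independent of that
choice. Terms are summed in ascending magnitude and the imaginary
residual is asserted below `1e-9` (relative for large values).

Consequences exposed as functions, each verified against at least one
independent route in the tests:

* long-time law `M(t) ≈ [2^{1/k}/(2α_k)] e^{α_k t/C}` with
  `α_k = k(2^{1/k}-1)`; `α_k ↓ ln 2` and the prefactor → `1/(2 ln 2) ≈
  0.721` — so a multi-stage population always lags the naive `k=1`
  model, even in the limit of deterministic (synchronous) division;
* all subdominant modes decay exactly for `k ≤ 28`
  (`subdominant_decay_threshold`, brute force over all modes);
* infinite-k limits `2^{⌊t/C⌋}` (non-integer `t/C`) and `(3/4)·2^{t/C}`
  at integer `t/C`. The series approaches the integer-time limit like
  `k^{-1/2}` (measured: errors 0.0133/0.0042/0.0013 at k=10²/10³/10⁴),
  so `extrapolated_total_mean_limit` Richardson-extrapolates with
  exponent ½ over the two largest k supplied;
* steady-state stage proportions `M̂_j = 2^{(k-j)/k}(2^{1/k}-1)`:
  geometrically *decreasing* along the cycle, first/last ratio
  `2^{(k-1)/k} → 2`. Stage occupancy is therefore **not** proportional
  to stage duration — which undermines label-based estimates of phase
  lengths that assume it is. For unequal rates the stationary
  occupancy is computed as the leading eigenvector of the mean matrix
  (`stationary_proportions`).

## Simulation engines

`ssa` implements the direct method: exponential waiting time from the
total propensity, then linear event selection; two uniforms per event,
no tau-leaping (exactness is the point). Propensities are updated
incrementally in O(1) per event with a periodic full refresh to shed
floating-point drift; selection is O(k). State is recorded at fixed
record times with last-event-before semantics so ensembles align.
Division outcomes are drawn from a fate table of
`(probability, new stage-1 cells, progenitors)` triples, which covers
the plain chain (`2 stage-1 cells w.p. 1`), the EME chain (extra final
stage), and the stem-cell fates. First passage of a population threshold
is tracked at event resolution (running maximum), not from snapshots;
the alternative "currently ≥ threshold" reading is reported alongside.

Ensembles derive per-replicate seeds from a root seed through
`numpy.random.SeedSequence` (counter-based, order-independent); each
replicate runs its own `random.Random` stream, so trajectories are
bit-for-bit reproducible. Throughput is roughly 1.5 million events per
second per core, which sets the problem sizes below.

The lattice engine is a separate loop over a periodic `Lx × Ly` grid
with at-most-one-cell-per-site exclusion. Every cell carries the same
total rate `Pm + Pp·k` regardless of stage, so exact simulation reduces
to uniform cell choice after an exponential step from `N(Pm + Pp·k)`.
Movement picks one of the four von Neumann neighbours uniformly and
aborts silently into occupied sites. A stage event increments the stage,
or — in stage `k` — attempts division into a uniform neighbour: on
success parent and daughter both restart at stage 1; on failure the
`reset` rule returns the parent to stage 1 (preserving the mean attempt
rate of the `k=1` model) while the `hold` rule leaves it in stage `k`
(closer to a cell held at a checkpoint). The two rules coincide at
`k=1`. All cells start in stage 1 by default (the natural post-seeding
state); `initial_stages="uniform"` is available because early-time
densities are sensitive to this choice. Time is reported rescaled,
`t̄ = P_p t` (plain `t` when `P_p = 0`).

## Stem-cell model

Stem cells divide at rate `ρ_s` (mean CCT `1/ρ_s`, Erlang with `k`
stages at per-stage rate `ρ_s k`); the fate — symmetric division
(`r_1`), asymmetric self-renewal (`r_2 = 1-r_1-r_3`), symmetric
differentiation (`r_3`) — is drawn at the division instant, not
pre-assigned at birth. Progenitors are inert counters (flag-gated, so
fuller progenitor dynamics could be added without API change). With
`r_1 > r_3` the mean field law `S_0 e^{ρ_s(r_1-r_3)t}` solves the exact
mean equation at `k = 1`; for `k > 1` it *overestimates* the true mean
(the function warns rather than extrapolating silently). Defaults
`ρ_s = 1, r_1 = 0.2, r_3 = 0.15, S_0 = 1` are the reference study
conditions for the tumour-regrowth scenario; the offspring distribution gives extinction probability
0.75 independent of `k`, so ensemble summaries are dominated by the 25%
of surviving lineages and are heavy-tailed.

## Fitting

`fit_cctd` minimises the unweighted sum of squared residuals between a
candidate density at the histogram bin centres and the density bar
heights, the procedure commonly applied to measured CCT histograms
(bin-averaged residuals are available as `residual_mode="integrated"`;
the choice alters the SSR slightly and is documented, not resolved).
The integer shape is scanned exhaustively (default 1..60) with the
continuous rates optimised per candidate from moment-based multi-starts;
the EME scan is additionally seeded from the Erlang winner with a
nearly-massless final stage, which guarantees the nested-family ordering
`SSR(EME) ≤ SSR(Erlang) ≤ SSR(exponential)` up to optimizer tolerance.
EME rates are parametrised as `(λ_2, L)` in logs so the supported branch
`λ_1 > λ_2` is maintained by construction.

`generate_synthetic_histogram` draws CCTs through the stage-sum sampler
and bins them to density heights over `[0, max]`. It emulates the
*format* and sampling noise of measured CCT histograms, not their
measurement artefacts (detection-window censoring, lineage correlation,
unequal bins), so fitting tests demonstrate parameter recovery under
clean sampling, not robustness to experimental bias.

## Problem sizes and statistical design of the tests

Monte-Carlo tests use fixed seeds and 3-standard-error windows unless
stated. Sizes were chosen for statistical power at desk-scale runtimes:

* chain-vs-analytic means: 10⁴ replicates, `k ∈ {1,4}`, `C = 10`,
  `t ≤ 30`;
* stem-cell orderings: the ordering of the *exact* means (computed from
  the linear mean ODEs) is asserted across `k ∈ {1,2,5,10}`, with SSA
  agreement to those means at 4×10³ replicates; the full-scale reference
  design (`t = 100`, threshold 1000, 10⁴ replicates) is run on the
  extreme pair `k = 1` vs `k = 10`, where mean, variance and `p₁₀₀₀`
  separate at ≈3.7, 3.7 and 5.1 standard errors. Adjacent-pair
  separations (e.g. the exact-mean gap of 1.9 between `k = 5` and
  `k = 10` at `t = 100` against a difference-SE of ≈5 at 10⁴
  replicates) are below Monte-Carlo resolution at any affordable
  ensemble size, which is why the adjacent ordering is carried by the
  analytic route;
* first-passage thresholds must stay large relative to the mean
  (threshold ≈ 6.7× mean at `t_end`, the reference geometry): small
  thresholds saturate toward the k-independent survival probability
  0.25 and the ordering inverts;
* lattice orderings: 50×50 grid (scaled from 100×100), 1% seeding, 40
  replicates; the `reset` ordering is asserted mid-growth (`t̄ = 5`)
  and the `hold` ordering near confluence (`t̄ = 10`), where the
  respective adjacent separations are sharpest — `reset` terminal
  densities for `k = 10` and `k = 100` genuinely converge at `t̄ = 10`.

## Numerical choices and edge cases

* Densities validate `t ≥ 0` and raise on negative times rather than
  returning 0.
* `EMEParams` forbids `λ_1 = λ_2` (degenerate: an Erlang with `k+1`
  stages — use `ErlangParams`); the closed form raises
  `UnsupportedBranchError` on `λ_1 < λ_2`, pointing at the convolution
  fallback.
* Proportion ODE input must lie on the simplex to `1e-9`; the
  right-hand side sums to zero to machine precision.
* Histogram validation requires area within `[0.9, 1.1]` — loose enough
  for coarse binnings, tight enough to reject count histograms.
* Seeds derived for replicates come from `SeedSequence.generate_state`,
  i.e. 32-bit integers, so nested seeding stays well below 2³¹.

## Known limitations

* CCTs are i.i.d. across cells: heritable mother–daughter CCT
  correlation (documented in fibroblasts) is not represented.
* Progenitor dynamics (division, death) are not modelled; progenitors
  only count.
* The lattice model has no cell death and unbiased migration only.
* The general hypoexponential density has no closed form here (only
  moments and sampling); the library deliberately exposes the Erlang
  and EME special cases that keep parameters identifiable.
* Fitting is least squares on binned densities, matching the histogram-bar
  procedure above, not maximum likelihood on raw times; standard errors of
  fitted parameters are not reported.
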