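# Methods

## The process being simulated

A reaction network with species copy-number state **x** ∈ ℕⁿ and reactions
R₁…R_m defines a continuous-time Markov jump process: reaction j fires in
[t, t+dt) with probability a_j(x)·dt, where a_j is the propensity, and
shifts the state by the net stoichiometric vector ν_j = products −
reactants. The probability P(x, t) obeys the chemical master equation
(CME); exact SSA trajectories are samples from the same law.

Propensities use the stochastic mass-action convention with the
combinatorial factor ∏ᵢ C(xᵢ, mᵢ) for reactant multiplicity mᵢ — in
particular c·n(n−1)/2 for dimerization, the convention exact SSAs assume.
Arbitrary rate laws are arithmetic expressions over copy numbers and
parameters, evaluated by a whitelisted AST interpreter (operators
`+ - * / ^`, `min`/`max`/`exp`/`log`; no attribute access, subscripts, or
general code execution, for safety and portability). A negative expression
value is clipped to 0 with a warning. Species declared with a `$` prefix
are fixed (buffered): they enter propensities but are never updated —
this provides the zero-order source/sink notation and clamped substrates.
All state is integer copy numbers, never concentrations; SBML import
therefore rejects compartments with volume ≠ 1 unless copy-number
reinterpretation is explicitly requested, since no unit-conversion
semantics are defined here.

## Solvers

**Direct.** At state x: a₀ = Σ a_j, waiting time τ ~ Exp(a₀), channel
chosen with probability a_j/a₀ (inverse-CDF on the cumulative propensity;
index ties at the representable edge resolve to the last channel). a₀ = 0
halts the run with an absorbing flag.

**First reaction.** One candidate time τ_j ~ Exp(a_j) per channel; the
minimum fires. Ties (measure zero) resolve to the lowest reaction index.
Statistically identical to the direct method.

**Next reaction (Gibson–Bruck).** Absolute putative firing times are kept
in an indexed binary min-heap. After channel μ fires, only channels in the
dependency graph of μ are touched: the fired channel redraws a fresh
exponential; a channel whose propensity changed a_old → a_new > 0 rescales
its pending time as t + (a_old/a_new)(t_j − t); a channel re-activated from
zero propensity draws a fresh clock, so it can never fire while disabled.
The dependency graph sets j ∈ depends(i) iff the species changed by i
intersect the species read by j's rate law (reactants for mass action, all
species identifiers in the expression otherwise); every reaction depends
on itself.

**Tau-leaping.** Adaptive explicit leaping with the standard step-size
control: τ is the largest step for which each species' expected and
standard-deviation change stays below max(ε·xᵢ/gᵢ, 1), with gᵢ from the
highest order of reaction consuming i (expression-law reads count as order
1). Channels within n_c firings of exhausting a reactant are *critical*
and fire at most one event per leap, sampled exactly. If the selected τ is
smaller than 10/a₀ the solver falls back to batches of exact SSA steps.
Firing counts per non-critical channel are Poisson(a_j·τ); a draw that
would drive any copy number negative is rejected and τ halved, so negative
populations are impossible by construction. Leap rows carry the
firing-count vector; the trajectory is flagged non-exact and waiting-time
analysis refuses it (waiting times are undefined for aggregated leaps).
Defaults ε = 0.03, n_c = 10, exposed in `SolverSettings`.

**Output contract.** Row 0 holds the initial state and its propensities
(fired index −1). In time mode the run records the last event at t ≤ t_end
and appends a terminal non-event row at exactly t_end (fired index −2)
carrying the final state, so holding-time weights cover the full interval
without bias. Steps mode records exactly `end` events. Identical (model,
settings, seed) reruns are bit-identical; ensemble member k uses an
independent RNG stream spawned from (seed, k) via numpy's `SeedSequence`,
giving reproducible, uncorrelated ensembles.

## Estimators

**Stationary distributions and moments are holding-time weighted**: the
probability of value v is the total time the process holds v divided by
the total observed time. This is the estimator consistent with the CME's
stationary measure; per-event weighting would overweight fast-switching
states. Moments are computed from the same weighted distribution (a single
code path, so distribution mean ≡ moment mean to machine precision). The
Fano factor is flagged undefined (None) when the mean is 0. Burn-in
defaults to 0 and must be requested explicitly — no silent data deletion;
stationary analyses in the tests drop the first 10% of simulated time.

**Event waiting times** for a channel are the differences between its
consecutive firing times. The span from t = 0 to the first firing is
excluded: a waiting time requires a preceding event of the same channel.

**Autocorrelation** resamples the trajectory to a uniform grid by
zero-order hold (default spacing: mean inter-event time) and evaluates the
standard biased ACF estimator at the requested physical-time lags;
ACF(0) = 1. A warning is issued when the duration is below 10× the largest
lag.

**Fixed-interval regridding** samples the state at equally spaced times
(zero-order hold), reproducing what snapshot-based simulators store. The
test suite uses it to show that at one sample per event the fixed-interval
distribution estimate is strictly less accurate (larger total-variation
distance to the CME solution) than the explicit-output estimate.

## Oracles

**Truncated CME.** The state space is enumerated by breadth-first
reachability from the initial state under per-species caps (full product
enumeration can include unreachable configurations, making the generator
reducible and the stationary solve singular). Transitions that would leave
the truncated space are dropped (reflecting truncation); the stationary
vector solves Qᵀp = 0 with one balance row replaced by normalization,
via sparse LU. The probability on states with a dropped outgoing edge is
the *boundary mass*; above 10⁻⁶ a warning is issued and above 10⁻⁴ the
truncation is rejected. A cap that equals a species' hard maximum (a gene
copy) drops no edges and is therefore not counted as truncation.

**Phase-type waiting times.** For a monitored channel, the generator
restricted to the transient states of the inter-firing cycle gives the
waiting-time density f(t) = α·e^{tS}·s with exit rates s = −S·1, evaluated
through the eigendecomposition of S (states are few). Shipped
constructions: the single-enzyme turnover cycle (transient states E, ES;
α puts all mass on E because each product release frees the enzyme) and
the telegraph-gene synthesis cycle (transient states ON, OFF; α on ON).
For bursty parameters the latter density shows two log-slope regimes —
fast within-burst decay ≈ −(k_syn + k_off), slow between-burst decay at
the gene-switching scale.

**Closed forms.** The linear birth–death (immigration-death) process has
stationary law Poisson(k_syn/k_d) and stationary autocorrelation
exp(−k_d·τ).

## Case-study fixtures

Shipped as MDL files in the package data directory; all rates in min⁻¹.

- `immigration_death` — k_syn = 10, k_d = 0.2 (published values);
  stationary Poisson(50).
- `two_state_gene` — telegraph gene; *bursty* set k_on = k_off = 0.01,
  k_syn = 1, k_d = 0.05 (long ON/OFF dwell times → transcription bursts,
  bimodal mRNA law, two-timescale synthesis waiting times) and *non-bursty*
  set k_on = k_off = 1. Package defaults, overridable.
- `single_enzyme` — E + S ⇌ ES → E + P with one enzyme copy;
  clamped-substrate variant (k₁·S = 1, k₋₁ = 0.5, k₂ = 1; `$S` buffered)
  for the waiting-time oracle, and a consumable-substrate variant for
  product time courses. Package defaults.
- `tx_tl_division` — nine reactions: TF synthesis/degradation,
  activation/deactivation, active-TF degradation, saturating (Hill n = 1)
  transcription — the one non-mass-action law —, mRNA decay, translation,
  protein decay. The protein is stable (k_dp = 0.001, half-life ≈ 700 min
  ≫ the 60 min generation time), so protein loss is dominated by dilution
  or partitioning: under explicit division the protein shows large
  sawtooth variation while the implicit-dilution run sits near a smooth
  steady state — the qualitative contrast this fixture exists to exhibit.
  There is no explicit gene species (transcription-factor synthesis is
  constitutive), so no gene-duplication choice arises at division.

## Cell division

Explicit division follows a single lineage: run the network to the next
division time (Gamma(shape 1.0, scale 60.0) minutes by default), then send
each molecule of every partitioning species to the tracked daughter with
probability p = 0.5 (Binomial(n, p); the discarded daughter receives
n − k, so copy numbers are conserved exactly), and continue. Interrupting
the SSA at the division time is exact for the direct method: exponential
clocks are memoryless, so discarding the pending event and redrawing from
the post-partition state samples the correct law. Species can be flagged
non-partitioning (each daughter keeps the copy — gene/DNA semantics);
the default partitions everything. Fixed generation times and
deterministic halving (floor/ceil alternating) are available as flags for
comparison with the older convention. Implicit division adds one
first-order loss reaction per dilutable species at the population growth
rate (ln 2 / mean generation time for balanced growth). At division-time
CV → 0 (gamma shape 50) the two formulations' long-run means agree within
a few percent, which the tests check as a bridge between them.

The explicit-vs-implicit comparison statistic is the per-generation
holding-time-weighted mean protein copy number (200 generations) against
holding-time-weighted means over 200 equal time windows of the implicit
run — the same estimator on both sides — compared by a two-sample
Kolmogorov–Smirnov test.

## Problem sizes and numerical choices

The test suite validates stationarity, solver equivalence and waiting-time
laws on runs of 10⁵–10⁶ events (a 10⁶-event immigration-death run takes
~10 s in pure Python/numpy); ensembles use 100 × 10⁴ events; division
comparisons use 200 generations (~12 000 min of simulated time). The CME
oracle uses cap 200 for the immigration-death model (boundary mass
~10⁻¹⁷) and caps (1, 1, 100) for the telegraph gene. Statistical
assertions use fixed seeds and pre-stated tolerances: 3-standard-error
bands for means and histogram bins, α = 0.001 for Kolmogorov–Smirnov
tests, total-variation thresholds as stated per test. Distribution
normalization is enforced to 10⁻⁹; degenerate inputs (zero-duration
trajectories, empty interval lists, burn-in removing all data) raise
typed errors rather than returning NaNs.

## Known limitations

- Expression rate laws are evaluated per event in Python; models dominated
  by expression-law channels simulate several-fold slower than pure
  mass-action ones.
- The SBML reader covers the documented Level 2 subset only (no events,
  rules, function definitions, or reversible reactions; local parameters
  are hoisted to globals and must not shadow).
- Tau-leap trajectories support distribution/moment analysis but not
  waiting times; the g-factor table covers reactant orders up to 3.
- Population-level division (following both daughters), age-structured
  models, delay SSAs, and hybrid ODE/SSA schemes are out of scope.
- Time-weighted estimates from a single trajectory carry autocorrelated
  Monte-Carlo error; standard errors quoted in the tests account for the
  correlation time where it matters.
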