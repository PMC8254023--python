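# Methods

## Model

Individuals explore a two-shelter arena independently; sociality enters only
through shelter *retention*.  Per one-second step, an outside individual
joins the odorous shelter (PS) with probability `J_ps = θ·μ_ps` and the
control shelter (CS) with `J_cs = θ·μ_cs` (`μ_ps + μ_cs = 1`); a sheltered
individual leaves with probability `Q = ρ·e^(−ς(X−1))` where `X` is the
shelter's occupancy at the start of the step.  Assumptions built into this
form:

* joining is independent of the sheltered population (no recruitment
  feedback on entry; the attraction feedback acts only on leaving);
* `ρ` and `ς` are identical across shelters and behavioural types — the
  minimal assumption compatible with the observation that consensus
  strength does not depend on group composition;
* in mixed groups the retention depends on the *pooled* occupancy of a
  shelter (both types count equally as conspecifics): this is the only
  coupling between types;
* per-second probabilities are treated as Bernoulli probabilities of a
  synchronous discrete-time chain; validation rejects `θ` or `ρ` outside
  [0, 1].

### Parameters

| symbol | meaning | unit | naive | conditioned |
|---|---|---|---|---|
| `θ` | probability of finding a shelter while exploring | s⁻¹ | 1×10⁻³ | 3.703×10⁻⁴ |
| `μ_ps` | relative response to the odorous shelter | — | 0.63 | 0.445 |
| `ρ` | leaving probability when alone | s⁻¹ | 0.002 | 0.002 |
| `ς` | social strength (retention per conspecific) | — | 1.19 | 1.19 |

These retained values are the package's defaults (`NAIVE_PARAMS`,
`CONDITIONED_PARAMS`).  `μ_cs` is always stored as `1 − μ_ps`.  Each type
carries its own copy of `ρ` and `ς`, so the shared-sociality assumption is
relaxable without code changes.

## Simulation

The update is synchronous: all leave/join decisions of a step are drawn
from the state at the step's start, individuals are exchangeable, and an
individual cannot leave and rejoin within one second.  The within-step
ordering of joins and leaves is not observable in this scheme; synchronous
start-of-step updating is this package's documented choice for resolving
that ambiguity.

Because events are rare (probabilities of order 10⁻³ per second, and
retention suppresses leaving by `e^{−ς(X−1)}` once aggregates form), the
kernel skips quiet intervals exactly: conditional on the current state, the
number of steps until the next step with at least one action is geometric
in the per-step no-event probability `q = ∏(1−p_k)^{n_k}`, and the acting
step's joint outcome is sampled conditioned on at least one change
(sequentially over transition channels, with truncated binomials).  This is
a lossless acceleration of the same discrete-time chain — *not* a
continuous-time (Gillespie) approximation — and is cross-validated in the
test suite against (a) a literal per-second stepper and (b) the
master-equation law (chi-square goodness of fit at 20,000 realizations).
It simulates 10,000 24-hour realizations of a 10-individual group in about
a second.

Randomness: a master seed spawns one stream per realization
(`numpy.random.SeedSequence`), so an ensemble is bitwise the concatenation
of its individual trials and every artifact is reproducible from its
recorded seed.

Recording mirrors the experiment: occupancy per type every 10 minutes for
3 hours plus a 24-hour snapshot; a custom grid (including dense per-minute
recording) is available for diagnostics.

## Master equation

For homogeneous groups the pooled state `(i, j)` (occupants of PS and CS)
is a birth–death process on the `(N+1)(N+2)/2` states with rates

* `(i−1,j) → (i,j)`: `(N−(i−1)−j)·θμ_ps` (likewise for CS with `μ_cs`),
* `(i+1,j) → (i,j)`: `(i+1)·ρ·e^{−ςi}` (likewise for CS).

Transient distributions come from a stiff BDF integration of
`dP/dt = G·P` with the generator as exact Jacobian (`rtol = 1×10⁻⁸`,
`atol = 1×10⁻¹⁰`); output is clipped at −1×10⁻¹² and renormalized.  The
generator is dense; the state space is capped at N = 200.

The chain satisfies detailed balance; the exact stationary law is the
product form

`P(i,j) ∝ N!/(i!·j!·(N−i−j)!)·(θ/ρ)^{i+j}·μ_ps^i·μ_cs^j·e^{ς[i(i−1)+j(j−1)]/2}`

computed in log-space (`gammaln` + `logsumexp`).  The social exponent is
derived here from detailed balance of the transition rates and verified
numerically both against the generator's null space (sup-norm < 10⁻⁹) and
against long-time integration; the nonsocial outside-probability is
`ρ/(θ+ρ)` (forced by normalization, since the two sheltered cells sum to
`θ/(θ+ρ)`).
At `ς = 0` the law is multinomial with cells
`(θμ_ps/(θ+ρ), θμ_cs/(θ+ρ), ρ/(θ+ρ))`; `ρ = 0` is handled as the limit
concentrated on fully-sheltered states.

Caveat on stationarity: with `ς ≈ 1.2` the two consensus modes `(N,0)` and
`(0,N)` exchange probability astronomically slowly, so the *ratio* of the
modes at 24 h reflects the transient dynamics, not the `t → ∞` law.  All
24-hour quantities in this package therefore come from transient
integration (or simulation), never from the stationary formula;
closed-form-vs-integration agreement is tested at moderate `ς` where the
horizon covers the slowest relaxation.

Mixed compositions are handled by simulation only; the master-equation
module is deliberately homogeneous (a coupled two-type equation would have
O(N⁴) states and is not needed for any reported quantity).

## Calibration

* **θ floor** — with exits neglected (`ρ = 0`) the mean total sheltered
  population follows `N(1−e^{−θt})`; nonlinear least squares on the
  10-minute grid gives a lower bound for `θ` (leaving only slows the rise;
  the floor property is tested on exact master-equation means).  Fits whose
  rise is ≥99% complete at the earliest positive recording time are flagged
  `boundary` — such data only bound `θ` from below.
* **Logistic selection** — `P_ps = expit(α − β·n_conditioned)` fitted per
  time step by least squares on trial-level proportions (matching the
  original analysis; a binomial-likelihood fit would weight trials
  differently and is deliberately not the default).  Degenerate steps are
  flagged, not raised.
* **Criteria scan** — a grid over `(θ, μ_ps, ρ, ς)` (defaults bracket the
  published admissible limits, rates log-spaced) integrates the master
  equation to 24 h and keeps points satisfying: (1) mean sheltered fraction
  ≥ 0.99; (2) probability mass on "united" states (one shelter empty,
  ≥99% sheltered) ≥ 0.8 — the source gives no numeric cutoff for "100% of
  the sheltered population in the same shelter", so the 0.8 mass threshold
  is this package's documented operationalization and a reported config
  knob; (3) the focal shelter's strict-majority probability within ±0.05 of
  the target (0.8 naive / 0.4 conditioned; tolerance likewise a documented
  default, none being published).  Reproducing the published min/max table
  exactly is not expected — its tolerances are unstated — but the retained
  parameter point must pass, and tightening any tolerance can only shrink
  the pass set (tested).
* **Resampling agreement** — per time step, sets of `n_replicates`
  realizations are drawn with replacement from a simulated ensemble; each
  set's pooled focal-shelter proportion of the sheltered population forms
  the reference distribution in which the experimental proportion receives
  a two-sided percentile p-value.  Runs where the replicate count reaches
  the ensemble size are flagged `saturated`.

The published limits table lists two θ minima per condition without
explanation; this package reports a single floor per dataset.

## Trial-level statistics

All tests operate on the long-format trial table, use 10,000 iterations by
default, are deterministic given a seed and invariant to trial order.

* **Condition comparison (resampling)** — per time step, the across-trial
  mean total sheltered count of condition A is located within the
  distribution of means of `n_A` trials resampled with replacement from
  condition B (two-sided, central 95%).  This reproduces the source
  procedure exactly, and that procedure is *anti-conservative* under the
  null "A and B are independent samples of one process": the reference
  distribution omits B's own mean uncertainty, giving a type-I rate of
  about `2Φ(−1.96/√(1+n_A/n_B))` ≈ 0.14 at 15 vs 19 trials (measured
  0.14 over 500 simulated null pairs).  It is exactly calibrated for the
  narrower null "A's trials are draws from B's trials", under which the
  package's calibration tests run.  Borderline significances from this test
  should be read with that in mind.
* **Sociality (binomial variance) test** — the null is independent shelter
  choice: per trial, the focal-shelter count is Binomial(sheltered total,
  pooled p̂).  Rejection is one-sided when the observed across-trial
  variance exceeds the 95th percentile of the parametric-bootstrap variance
  distribution — overdispersion is the signature of social aggregation.
  The published description mentions weighting iterations "based on the
  variance" without specifying the scheme; this variance-comparison reading
  is the package's interpretation.
* **PS/CS permutation test** — each trial's `(n_ps, n_cs)` pair is swapped
  with probability ½ per iteration; the pooled focal proportion of the
  sheltered population is compared two-sidedly against the central 95% of
  the permutation distribution.
* **Consensus metrics** — winner = shelter with the larger pooled occupancy
  at the final recorded time (tie → none); `T_w` = earliest recorded time
  from which the winner stays strictly most occupied through the end
  (censored when absent; resolved on the 10-minute grid, the data's
  resolution); consensus = ≥90% (inclusive) of the basis population in one
  shelter.  The basis defaults to *sheltered* for experiment-shaped tables
  and *total* for group-size scans, and is always recorded in the output.
  Censored `T_w` tables and integer-binned `N_ps − N_cs` histograms are
  emitted as ready inputs for external survival-analysis and bimodality
  routines (log-rank/Peto–Peto, excess-mass/Cramér–von Mises), which this
  package does not reimplement; likewise the 180-min ↔ 24-h association is
  a plain correlation on `consensus_table` output (`scipy.stats.pearsonr`
  or `spearmanr` — both are used in the source literature).

Measured operating characteristics (500–1000 simulated null datasets per
test): all three tests are *valid* at the 5% level and mildly conservative
— sociality ≈ 0.03 (the plug-in p̂ costs a degree of freedom), permutation
≈ 0.04, condition-resampling ≈ 0.03 under its bootstrap null.  The test
suite asserts validity (rate ≤ 0.05 + 2 SE) and non-degeneracy rather than
exact 5% attainment, which discrete resampling tests do not achieve.
Power at the experimental design: the permutation test detects the naive
odour preference at 180 min in ≈84% of 15-trial datasets; the sociality
test rejects at ≥95% of datasets from 120 min on.

## Synthetic data

`generate_experiment` emulates the original design — naive 10/0 × 15
trials, conditioned 0/10 × 19, mixed 4/6 × 35 (types individually resolved,
as the pronotum marking allows), 10-minute grid plus 24 h — with dynamics
from the model itself and a ground-truth manifest (parameters, per-trial
seeds, final states) written alongside.  Null variants set `ς = 0`
(nonsocial) and/or `μ_ps = 0.5` (no odour preference) for type-I
calibration.  What the generator does **not** emulate: video-tracking noise
and miscounts, individual identity and movement within the arena, any
drift of behavioural parameters over 24 h (e.g. memory decay of the
conditioning), and between-group heterogeneity beyond the two discrete
types.  Green tests on synthetic data therefore certify the inference
machinery and the model's internal consistency — not that real cockroaches
follow the model; the model-vs-data comparison lives in the resampling
agreement test applied to real tables.

A known model-vs-experiment gap worth flagging: simulated settling times
`T_w` are substantially longer than the experimental means (the model's
winner identity keeps flipping longer than in real groups, where the 3-h
leader almost always wins at 24 h).  The model was selected to match
sheltered-population proportions per time step, not `T_w` distributions.

## Problem sizes and numerical choices

Headline quantities use the master equation where the setup is homogeneous
(exact, milliseconds) and simulation elsewhere: 10,000 realizations for
single-composition ensembles, 10,000–20,000 per point for group-size scans
(N = 1..30), 10,000 per composition for the 0..10 naive-count scan.  The
group-size argmax check uses 20,000 realizations because the consensus
curve is flat near its maximum (exact values 0.997/0.999/0.989 at
N = 9/10/11) and the argmax must be resolved through Monte-Carlo noise.
Statistical calibration suites use 500 replicate datasets with 1,000
test iterations each.  Chi-square goodness-of-fit tests pool cells with
expected count < 5.  Degenerate inputs (zero sheltered, all-zero data,
saturated fits, empty scan lists) are either flagged in the output or
raised with the offending row named, as documented per function.

## Limitations

* The master equation covers homogeneous groups only; mixed-group theory is
  available solely through simulation.
* Joining is independent of occupancy by design; systems with entry
  recruitment need a different hazard.
* The admissible-region criteria thresholds (consensus mass 0.8, selection
  tolerance ±0.05) are package defaults standing in for unpublished values;
  conclusions about the *shape* of the admissible region are insensitive to
  them, its exact extent is not.
* The condition-comparison resampling test inherits the anti-conservatism
  of the source procedure (see above); for a strictly level-α comparison
  use a permutation test on pooled trials instead.
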