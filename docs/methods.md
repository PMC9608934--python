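# Methods

## Model and decision algorithm

Counts of responses and non-toxicities are modelled as independent
binomials within each stage, endpoint and subgroup: stage-1 counts
`X_{R1}, X_{T1} ~ B(N1, p_R), B(N1, p_T)` per subgroup, second-stage
counts on the path actually taken (`N2⁻ = N⁻ − N1⁻` and
`N2⁺ = N⁺ − N1⁺` on the unselected path, `N2e⁺ = Ne⁺ − N1⁺` on the
enrichment path).  The two co-primary endpoints are assumed independent,
and the two subgroups are independent samples.  "Pass" is always
`count ≥ boundary`; "stop" is `count < boundary`.

The trial algorithm (see README for the narrative version) yields three
disjoint go-pathways whose probabilities factorise:

* `P(S1) = J(N1⁻, N2⁻, k_R1⁻, k_R⁻; p_R⁻) · J(N1⁻, N2⁻, k_T1⁻, k_T⁻; p_T⁻)`
  where `J(n1, n2, k1, k; p) = P(X1 ≥ k1 and X1 + X2 ≥ k)` is the
  two-stage joint pass probability.  It depends on the negative
  subgroup only: a go in the unselected population is driven by the
  stratum in which the hierarchy assumption makes success hardest.
* `P(S2) = P(X_R⁺ ≥ k_R⁺) · P(X_T⁺ ≥ k_T⁺) · [P(neg passes stage 1) − P(S1)]`.
  The bracket is the probability that the negative subgroup continues
  but misses a final bar on at least one endpoint; subtracting `P(S1)`
  from the stage-1 pass probability is exact under endpoint
  independence (the enumeration oracle validates the identity).  The
  positive totals are unconditional `B(N⁺, ·)` variables because the
  unselected path never gates on positive stage-1 counts: the sum of
  the positive stage-1 and stage-2 counts is then itself binomial.
* `P(S3) = J(N1⁺, N2e⁺, k_R1⁺, k_Re⁺; p_R⁺) · J(N1⁺, N2e⁺, k_T1⁺, k_Te⁺; p_T⁺)
  · [1 − P(neg passes stage 1)]`.

Attained error rates evaluate `P(S1) + P(S2) + P(S3)` at the corner
states: α at H00 (all rates null), α_R at H01 (null response,
acceptable non-toxicity, in both subgroups with subgroup-specific
acceptable rates), α_T at H10.  Power is
`min{P(S1 | H11⁻), P(S2) + P(S3) at (p_R0⁻, p_T0⁻, p_R1⁺, p_T1⁺)}` —
the unselected-population power and the power to rescue a positive
subgroup when the negative one is truly null.  A consequence of the
`min` definition: a design whose negative subgroup can never fail
(all boundaries 0) has zero power through the subgroup pathway, which
automatically excludes such degenerate designs from any search.

ESS and PET use only stage-1 pass probabilities:

```
ESS = N1⁻ + N1⁺ + (N2⁻ + N2⁺)·P(neg passes) + N2e⁺·P(pos passes)·P(neg fails)
PET = P(neg fails stage 1) · P(pos fails stage 1)
```

Design ranking uses `max{ESS(H01), ESS(H10)}` and
`min{PET(H01), PET(H10)}`, the conventional summaries over the mixed
states where stopping behaviour matters most.

## Numerical choices

Binomial tails are evaluated with `scipy.stats.binom.sf` (survival
function) rather than `1 − cdf`, avoiding cancellation at extreme
rates.  Joint pass probabilities sum the stage-1 pmf against the
second-stage tail; at the sample sizes of interest (N ≤ ~100) double
precision is ample and no log-space accumulation is needed.  Boundary
values above the reachable counts are legal inputs with pass
probability 0 — design searches iterate through them.  Search
tie-breaks on equal objective (within 1e-9): smaller total sample size,
then smaller stage-1 size, then the lexicographically smallest boundary
tuple; all searches are deterministic and enumeration-order invariant.

## Design searches

**BD search.**  For each `(N1, N)` the four joint-pass tables (two
endpoints × null/alternative rates) are pre-tabulated over all boundary
pairs; stage-1 pairs are scanned in increasing max-ESS order, which is
valid because the objective depends only on `(N1, N, k_R1, k_T1)`, and
final boundaries are then checked for feasibility
(`α_R ≤` target, `α_T ≤` target, power `≥ 1 − β`; overall α is reported
but not constrained).  Stage-1 pairs whose pass probabilities at the
acceptable rates already cap power below `1 − β` are pruned, since
raising any boundary never raises power.  The default search cap is
twice the smallest single-stage bivariate sample size meeting the
constraints — two-stage optima in this family sit well inside that
range.  A `minimax` criterion (smallest `N`, then smallest max-ESS) is
also available.

**Reduced SABD search.**  The 15-parameter space is reduced by fixing
the whole negative-subgroup design and the positive stage-1 triple from
two BD searches at `(α_R/2, α_T/2, β)` — the halving adjusts for the
multiplicity of the two rejection targets (unselected population,
positive subgroup).  The remaining six parameters
`(N⁺, k_R⁺, k_T⁺, Ne⁺, k_Re⁺, k_Te⁺)` are enumerated with both totals
capped at `cap_multiplier × N⁻` (default 2; the cap is applied to each
positive-subgroup total individually, the only reading that bounds the
free parameters).  `N⁺ = N1⁺` (no second-stage positive accrual on the
unselected path) is excluded by default but can be enabled.  Because
`P(S1)` and all stage-1 probabilities are fixed, each constraint splits
into a fixed offset plus terms linear in positive-subgroup pass
probabilities, and the objective depends on the free parameters only
through `(N⁺, Ne⁺)`; size pairs are therefore visited in increasing
objective order and the first pair admitting feasible boundaries is
optimal.  Every returned design is re-validated through the full exact
operating-characteristics calculus.  Case-study-sized searches complete
in seconds on one CPU.

A finding worth noting: for the shipped case studies 1 and 2 this
search returns feasible designs with *smaller* max-ESS than the
reference 15-parameter designs bundled in the fixtures (case 2:
24.3 vs 25.7 patients), while case 3 is recovered exactly.  The
reference designs' own operating characteristics are reproduced exactly
by the calculus, and the search's better candidates were cross-checked
by large-replicate simulation; the bundled designs are therefore
feasible but not optimal within this search space.  The fixtures keep
the reference parameterisations because their operating characteristics
are the documented benchmarks.

## Monte Carlo simulator

`simulate_sabd` draws all stage counts for all replicates vectorised
(10 binomial arrays per run, fixed order) from a single
`numpy.random.Generator` seeded once, applies the decision algorithm by
boolean masking, and reports pathway frequencies with binomial standard
errors plus mean enrolment.  Reproducibility is bit-exact for a given
seed and specification because there is no worker partitioning to
reorder draws; the cost of 100 000 replicates is well under a second,
so parallelism would buy nothing.  Replicates on untaken paths are
drawn and discarded — simpler, and harmless to correctness since every
replicate consumes the same number of draws.

`simulate_parallel_bd` runs two independent BD trials, one per
subgroup; in the benchmark comparison each arm is designed at
`(α_R/2, α_T/2, β/2)` so the pair controls the overall error rates
while either arm alone retains high power.  Heterogeneity detection is
operationalised as "negative stops at stage 1 AND positive continues"
for both designs (for the stratified design this is exactly the
enrichment trigger); "rejecting H0⁻ or H0⁺" is the union of the arms'
rejections for the parallel pair and any go-pathway for the stratified
design.

The simulator emulates the binomial trial model exactly — it shares its
distributional assumptions (endpoint independence, subgroup
independence, constant rates over time) with the exact calculus.
Agreement between the two therefore validates the implementation of the
decision algebra, not the model's fit to any real trial: correlated
endpoints, accrual drift, or misclassified strata are outside what
passing tests demonstrate.

## Scenario benchmarks

The four benchmark scenarios map to rate states as: 1A = H01 in both
subgroups, 1B = H10 in both, 2 = negative subgroup at its null with the
positive at its alternative (the heterogeneity case), 3 = H11 in both;
subgroup-specific acceptable rates are used throughout (this matters
for case 3, where the acceptable non-toxicity rate is 0.80 in the
negative and 0.90 in the positive subgroup).  At 100 000 replicates the
binomial standard error of a frequency near 0.8 is ≈ 0.0013, so
exact-vs-simulated comparisons in the tests use a 4-standard-error
band.

## Parameters that matter

| Parameter | Units | Default | Why |
|---|---|---|---|
| `alpha_r`, `alpha_t` | probability | 0.10 (case studies) | one-sided type I error per mixed null state |
| `beta` | probability | 0.20 | type II error at H11; power 0.80 |
| `cap_multiplier` | — | 2 | bounds `N⁺`, `Ne⁺` at `2 N⁻`; doubling the negative arm is the natural outer limit for a subgroup rescue |
| `n_reps` | replicates | 100 000 | frequencies stable to ±0.003 at 4 SE |
| `bd_n_max` | patients | 2 × single-stage N | see BD search above |

## Known limitations

* Endpoint independence is assumed throughout; correlated co-primary
  endpoints (bivariate binomial with within-patient association) are
  not modelled.
* The hierarchy assumption is taken as given; the design has no
  protection against a positive subgroup that is truly worse than the
  negative one.
* The search is the reduced 6-parameter enumeration; a global search
  over all 15 parameters jointly is out of scope.
* No inference after the trial (point estimates, confidence intervals
  adjusted for adaptive stopping).
* The enumeration oracle is restricted to stage sizes ≤ 12 by design;
  it is a test reference, not a production path.
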