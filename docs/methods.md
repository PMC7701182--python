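# Methods

This note records the model definitions, estimator conventions, numerical
choices and known limitations behind `crdtiming`. Everything stated here is
computed by the package and exercised by its test suite; no empirical claim
below goes beyond what the code produces.

## Game mechanics and the timing law

The collective risk dilemma is played by `N` players with endowment `E`,
per-round actions from a finite set containing 0 (default `{0, 2, 4}` EMU),
collective target `τ`, and risk `r` of losing the remaining endowment on
collective failure. The ending round is parameterized by `(m0, w)`: rounds
`1..m0` are always played, then after round `m0` and after each later round
the game stops with probability `w`,

    P(M = m0 + k) = w (1 − w)^k ,   E[M] = m0 + (1 − w)/w .

**Convention.** The termination check is taken to occur *after* round `m0`
(so `P(M = m0) = w`), which is the reading under which both uncertainty
presets (`m0 = 8, w = 1/3` and `m0 = 6, w = 1/5`) have a mean length of
exactly 10 rounds, matching the fixed-length control. The alternative
reading (first check before round `m0`) would give mean 9 and is not used.

**Payoffs.** At ending round M, player i receives `E − C_i(M)` if the
cumulative pool reached τ by round M, else `(1 − r)(E − C_i(M))`. The
failure loss is applied in expectation rather than sampled: the evolutionary
model consumes expected payoffs, so nothing is lost.

**Exact tail handling.** All five model strategies are deterministic with
one-round memory, so every group trace is eventually constant: either the
target is reached (all rules emit 0 thereafter) or two consecutive all-zero
rounds occur, which is a fixed point for one-round-memory rules with
unchanged endowments. The first such round, `static_round`, bounds the
support that must be enumerated; the geometric mass beyond it,
`(1 − w)^{M* − m0}`, multiplies the frozen state. Expectations over the
unbounded ending-round distribution are therefore exact, never truncated at
an epsilon.

**Endowment clipping.** A rule requesting more than the remaining endowment
contributes the largest feasible action ≤ the remainder. With the default
parameters (E = 40 divisible by every action) this only matters for games
longer than 10 rounds (possible under LU/HU) and for nonstandard configs.

## The five strategies

Unconditional rules give 0, 2 or 4 every round. The conditional rules react
to x, the sum of the other `N − 1` players' previous-round contributions,
with threshold `θ`:

* **reciprocal** — round 1: `first_action` (default 4, an optimistic
  opener); later: `high_action` (4) if `x ≥ θ`, else `low_action` (0).
* **compensator** — `high_action` (4) if `x < θ`, else `low_action` (0);
  round 1 counts as "no previous contribution", so it opens with 4.

Every rule emits 0 once the target has been reached.

**Defaults.** `θ = 2(N − 1) = 10` EMU — the others averaged at least the low
positive action in the previous round. This threshold is a design choice,
not an empirical estimate: the conditional rules are specified only
qualitatively by the behavioral observations they abstract. With these
defaults an all-reciprocal group reproduces the all-always-4 trace (success
in round 5) and an all-compensator group alternates 24, 0, 24, … and
succeeds in round 9 of a 10-round game. All parameters are overridable per
profile, and results should be read as conditional on this parameterization.

## Evolutionary dynamics

A well-mixed population of `Z` individuals (default 50), each committed to
one strategy. The payoff of a strategy when `k` individuals play A against
`Z − k` playing B is the hypergeometric mixture over the `N − 1` co-players
drawn without replacement, each composition scored by the exact game
expectation. Imitation follows the pairwise-comparison (Fermi) rule with
selection strength `β` (default 0.004, in 1/EMU).

**Fixation.** For one A-mutant among B-residents the birth–death chain gives
the closed form

    ρ = [ 1 + Σ_{i=1}^{Z−1} Π_{j=1}^{i} exp(−β (π_A(j) − π_B(j))) ]^{−1},

evaluated in log-space (log-sum-exp) so large `Z β Δπ` products cannot
overflow. β = 0 or equal payoffs give exactly 1/Z.

**Small-mutation limit.** Mutations are rare enough that the population is
monomorphic between invasion attempts; dynamics reduce to an embedded chain
over the five pure states with transitions `ρ(s′|s)/(n − 1)`. The stationary
vector solves the left null space of `T − I` with the normalization row
appended (least squares; entries clipped at 0 and renormalized to absorb
roundoff, with a hard failure if the system is rank deficient). The analytic
chain contains no exploration term; the full imitation-plus-rare-mutation
process exists only as a Monte-Carlo test oracle at small Z.

**Model metrics.**

* *Polarization* = `1 − P(|C − F| ≤ tol)` with `tol = 0` EMU by default,
  estimated over groups (default 10⁴, seeded) whose members are drawn
  multinomially from the stationary mixture and whose lengths are drawn from
  the termination distribution. Traces are deterministic per (composition,
  length), so they are cached and the estimate is cheap. The metric is a
  deviation-from-fair-share mass; a variance-based alternative can be
  computed from the same sampled contributions.
* *η (group achievement)* is, by default, the success fraction of those same
  sampled groups, so that η and polarization describe a single population
  state. A closed-form alternative — stationary-weighted success of
  monomorphic groups — is available (`eta_estimator="monomorphic"`); it
  swings much more strongly across treatments because an all-always-2 group
  succeeds with certainty only in the fixed-length game, and strict
  small-mutation-limit reasoning would indeed make real groups monomorphic.
  The mixture estimator was chosen as this package's definition; the choice
  is consequential and is reported with every result.
* *Reciprocal prevalence* = stationary mass of reciprocal divided by the
  total mass of the four contributing strategies (undefined, reported as
  NaN, if that mass is zero).

With the default parameterization, reciprocal prevalence and polarization
both increase from NU through LU to HU while η varies less in relative
terms — the qualitative pattern the model is meant to exhibit. Exact metric
values depend on the θ/opener defaults above and on the estimator choices,
and should not be read as calibrated point predictions.

## Analysis pipeline

Operates on a validated long-format decision table
(`treatment, group_id, player_id, round, action`); validation rejects
non-action values, per-player totals above E, non-contiguous rounds and
players disagreeing on their group's realized length, naming the offending
rows.

Conventions, chosen where the underlying experimental write-ups leave the
construction open and exposed as parameters:

* Per-round means: mean over groups of the group's round total, with a
  t-interval across groups (95% default). A single group yields a mean with
  a flagged-undefined CI.
* Success fractions: a group is successful iff its cumulative contribution
  reaches τ by its realized final round; Clopper–Pearson (exact binomial)
  intervals.
* Fairness: fractions of players with total contribution C below / at /
  above `F = E/2`, by default within successful groups.
* Half-splits: first half is rounds `1..m0/2` (5, 4, 3 rounds for NU, LU,
  HU), second half runs to the realized end; players are compared to `F/2`.
  Groups shorter than the first half are excluded and counted.
* Conditional response: for each observed others'-previous-round total x,
  the mean focal contribution, count and action frequencies; the regression
  of bin means on x is weighted least squares with bin counts as weights,
  and the slope sign separates reciprocal (positive) from compensatory
  (negative) response. Rounds after the target is reached can be excluded
  (`pre_success_only`), since every strategy then plays 0 and the
  observations carry no information about the rule.
* Constant-contributor counts: players choosing one action in every round.

**Profile classification.** The default method replays each of the five
decision rules on the player's *observed* context (others' previous totals,
previous cumulative totals, own remaining endowment) and assigns the
best-matching rule, requiring a match fraction of at least 0.8 and breaking
perfect-match ties in favor of the unconditional rule (parsimony). A simpler
sign-of-own-slope rule (cutoff 0.05 EMU/EMU) is available as
`method="slope"`; it fails on a structural case — a reciprocal player whose
group collapses emits 4, 0, 0, … against varying x, giving slope 0 — which
is why rule replay is the default. Only pre-target rounds are used; players
with fewer than two informative rounds are labeled `other` and flagged.

**Identifiability.** A conditional player whose context never crosses θ
emits exactly an unconditional action sequence (including clipping when the
endowment runs out) and is *behaviorally indistinguishable* from the
corresponding unconditional rule within that game. No classifier can do
better. The synthetic generator therefore records, besides the assigned
strategy, the **effective profile** — the assigned rule as expressed in the
observed game, downgraded to unconditional when never exercised — and
recovery is judged against it: on noise-free cohorts the template classifier
matches effective profiles exactly, and unconditional assignments are always
recovered.

## Synthetic-data generator

Emulates the experiment's structure: one realized length per group (a single
dice sequence per group, not per player) drawn from the treatment's
termination distribution; six players per group with strategies drawn
independently from a configurable mixture; trembling-hand noise replacing an
intended action with a uniform draw from the action set (then clipped), with
probability `noise_eps` per decision. Identical seeds give byte-identical
output.

What it does *not* emulate: learning or drift within and across games,
round-timing effects beyond the one-round-memory rules, payoff-sensitive
deviations, demographic heterogeneity, or the session structure of a
laboratory experiment. Passing recovery tests on generator output therefore
shows that the pipeline's estimators are correct on data that follow the
five-strategy model with independent noise — not that real participants
follow that model.

## Problem sizes and numerical tolerances

Termination masses are checked to sum to 1 within 1e−12 and the numeric mean
to match the closed form within 1e−9. Fixation probabilities are verified
against a tridiagonal absorbing-chain solve at `Z = 12` to 1e−10; the
stationary distribution against a jump-chain Monte-Carlo simulation (9,000
embedded transitions, batch-mean standard errors, 3-SE criterion) at
`Z = 12, β = 0.01`, where every state carries visitable mass. Game-outcome
expectations are verified against 10⁵-sample Monte-Carlo replays (3 SE).
Model metrics default to 10⁴ sampled groups per treatment; pipeline-recovery
checks use cohorts of 40–120 groups, with exact composition-enumeration
oracles for the fixed-length treatment. These sizes make the full suite run
in seconds while keeping every stochastic comparison inside explicit
standard-error bounds.

## Known limitations

* The five-strategy space is minimal by design; richer rule families (longer
  memory, graded responses, mixed strategies) are out of scope.
* The small-mutation limit ignores polymorphic transients; the analytic
  chain is only validated against the full process at small Z.
* θ, the conditional opener, and the polarization/η estimator definitions
  are documented design choices; conclusions about metric *levels* (as
  opposed to cross-treatment trends) are sensitive to them.
* The Dryad schema map is a validated template: column names are checked on
  load against the actual deposit, which is not redistributed here.
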