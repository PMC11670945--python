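# Methods

## The model

The package simulates the Iterated Prisoner's Dilemma (IPD): two players
simultaneously choose to cooperate (C) or defect (D) each turn and are paid
from the stage-game matrix

|        | C      | D      |
|--------|--------|--------|
| **C**  | R, R   | S, T   |
| **D**  | T, S   | P, P   |

with T > R > P > S and 2R > T + S enforced, and defaults R = 3, S = 0,
T = 5, P = 1 (the values standard in the IPD literature).  A *match* is an
iterated game between two strategies; a *tournament* is a round robin over N
strategies repeated k times; a *trial* runs four tournament variants on one
randomly drawn player set:

* **standard** — fixed length n, no noise;
* **noisy** — fixed length n, each player's action independently flipped
  with probability p_n per turn;
* **probabilistic ending** — match length geometric with per-turn ending
  probability p_e, P(L = l) = (1 − p_e)^(l−1) p_e;
* **noisy probabilistic ending** — both p_n and p_e.

### Engine conventions

* Strategies observe the *realized* (post-noise) history, including their
  own flipped actions.  This is the standard noisy-IPD convention and the
  only reading under which a flipped action affects the shared history.
* Geometric match lengths are sampled up-front per match; this is equal in
  distribution to per-round stopping and simpler to log.  A `length_cap`
  (default 10,000) guards against tiny p_e; since p_e is drawn from (0, 1]
  (never exactly 0), every match terminates.
* Noise applies uniformly to every move, including the first; there is no
  basis for exempting the opening move.
* RNG contract: each match derives three independent child streams (length
  draw, player A, player B) from a seed that is itself derived from the
  tournament seed and the (repetition, pair) index, so tournaments are
  bit-reproducible and independent of iteration order.  Degenerate
  memory-one probabilities (exactly 0 or 1) are resolved without consuming
  the RNG stream, so deterministic rules stay deterministic.

### Scoring and ranking

Per repetition, a player's score is its mean per-turn payoff averaged over
its matches against the other N − 1 players.  The ranking statistic is the
*median* of these per-repetition means over the k repetitions (a `mean`
option exists).  Ranks 0..N−1 are assigned by descending score with
lexicographic-name tie-breaks, so they are always a deterministic
permutation.  Self-pairs are played and contribute to the behavioral
statistics (matching the convention of the upstream tournament libraries)
but are excluded from scoring and ranking; both choices sit behind config
flags because the two conventions coexist in the literature.

Behavioral statistics pool raw counts over all rounds, matches and
repetitions rather than averaging per-match rates: matches of geometric
length carry unequal weight and pooling matches the "rate" semantics.  A
conditional cooperation rate whose previous-state count is zero is reported
missing (NaN), never 0.

## Strategy catalog

Twenty-two canonical strategies are registered, each with classifier
metadata (stochastic, makes-use-of-game, makes-use-of-length, memory size):
Cooperator, Defector, Alternator, Random(0.5), Tit For Tat, Suspicious TFT,
Tit For 2 Tats, Two Tits For Tat, Generous TFT, Grudger, Spiteful TFT, Fool
Me Once, Pavlov (Win-Stay-Lose-Shift), Gradual, Adaptive TFT, Omega TFT,
Prober, BackStabber, ZD-Extort-2, ZD-GTFT-2, and Meta Majority / Meta
Winner ensembles over a six-member deterministic team.  Generic families
(memory-one vectors, finite-state machines, lookup tables, meta ensembles)
can express further published rules; a validating YAML loader accepts
user-supplied definitions.  Trained strategies whose weights are not
publicly restated (evolved FSM/HMM/ANN players, particle-swarm gamblers and
the like) are deliberately not imitated; the generic classes are the
mechanism for loading such rules when a user has them.

Choices where the literature is ambiguous:

* **Generous TFT** forgives a defection with probability
  g = min(1 − (T − R)/(R − S), (R − P)/(T − P)), the standard generosity
  level; g = 1/3 at the default payoffs.  It reads g from the match's
  payoff matrix, hence `makes_use_of_game = True`.
* **Gradual** punishes the opponent's k-th defection with k consecutive
  defections — the punishment length is the opponent's *total* defection
  count at trigger time — then cooperates twice to calm the interaction.
  Variants that count punishments differently exist; this one follows the
  verbal description the package is built around.
* **Adaptive TFT** smooths the opponent's cooperation indicator with
  θ = 0.5 (configurable) from a neutral prior w₀ = 0.5 and cooperates iff
  w ≥ 0.5.
* **Omega TFT** uses a deadlock counter (threshold 3) that breaks CD/DC
  alternation cycles with a cooperation, and a randomness counter
  (threshold 8) that switches it to permanent defection against apparently
  random opponents; both thresholds are configurable and the exact counting
  rule is documented in the class docstring — the golden-trace tests were
  derived by hand from that rule.
* **Meta Winner** scores each member's proposals hypothetically against the
  opponent's realized actions and plays the current leader's proposal, ties
  to the earliest member.  Team members observe the ensemble's realized
  history as their own, so stateful members stay synchronized.

## Features

For each (trial, tournament type, strategy) the feature stage computes the
normalized rank r = R/(N − 1) (0 = winner, 1 = last), the cooperation
rating C_r, the four conditional cooperation rates (CC→C, CD→C, DC→C,
DD→C), tournament-level cooperation aggregates C_max/C_min/C_mean/C_median
with the ratios C_r/C_max, C_min/C_r, C_r/C_median, C_r/C_mean (missing on
zero denominators), memory usage min(memory/n, 1) (1 for infinite memory;
undefined when n is unknown, i.e. for probabilistic-ending tournaments),
and the SSE distance from zero-determinant behavior.

### SSE-to-ZD

A memory-one strategy is summarized by its cooperation vector
p = (p_CC, p_CD, p_DC, p_DD); here p is taken from the strategy's *observed*
pooled conditional cooperation rates — its memory-one shadow.  With the
tilde transform p̃ = (p_CC − 1, p_CD − 1, p_DC, p_DD) and payoff vectors
S_x = (R, S, T, P), S_y = (R, T, S, P), a zero-determinant strategy
satisfies p̃ = φ[(S_x − P·1) − χ(S_y − P·1)].  The fit solves

    min_{a, b ≥ 0} ‖a·u − b·v − p̃‖²,   u = S_x − P·1,  v = S_y − P·1,

by nonnegative least squares, reporting φ = a, χ = b/a and the residual SSE.
SSE = 0 means exactly ZD-like behavior; the nonnegativity constraints
restrict the fit to the extortionate branch (an unconstrained OLS variant is
exposed).  The residual is not intrinsically bounded by 1, so the raw value
is reported alongside a clipped min(SSE, 1) convenience property.  Missing
conditional rates (unvisited states) are imputed with the neutral value 0.5
before fitting and the row is flagged `sse_imputed`.  Worked checks: TFT's
vector (1, 0, 1, 0) fits exactly with a = b = 0.2; the vector built from
(φ = 0.1, χ = 2) fits with SSE = 0 and recovers its parameters.

## Trial sampler and campaigns

A trial draws, from one seed: N uniformly on [3, 195] clipped to the
catalog size; N distinct strategies without replacement; k ∈ [10, 100];
n ∈ [1, 200]; p_n uniform on [0, 1]; p_e uniform on (0, 1].  These ranges
are the study conditions and are the sampler defaults.  Campaigns stream
trials.csv, features.csv and per-tournament summary CSVs with a JSON
manifest recording the seed, ranges and completed trial indices; per-trial
seeds derive from the master seed, so campaigns are deterministic and
resumable by trial index.

The drivers and tests run a *desk profile* (N ∈ [3, 12], k ∈ [4, 10],
n ∈ [1, 60], cap 500, tens of trials), chosen as the package's own
quick-inspection scale; the probability ranges are unchanged so filtering
on p_n ≤ 0.1 / p_e ≤ 0.1 retains its meaning.

## Analysis stage

Per tournament type: Spearman rank correlations (average ranks for ties —
the standard convention; verified against a rank-transform + Pearson brute
force) of each feature with the normalized rank and the median score, with
pairwise deletion of missing values and missing coefficients for constant
features; an OLS regression of the normalized rank on a per-type,
collinearity-pruned feature list (n and memory usage only where the length
is known; p_n only in noisy types; p_e only in ending types), with a
rank-deficiency error that names the collinear columns; and winner profiles
(distribution summaries of C_r, C_r/C_mean, SSE and the four conditional
rates over the rank-0 rows).  The same regression can target the median
score by changing the target column.

## Synthetic feature tables

`ipdlab.synthetic` generates feature tables with the schema and internal
consistency of real ones — tournament blocks share aggregates recomputed
from the generated C_r values, ratios recompute from their parts, integer
ranks follow the normalized-rank ordering — while the normalized rank is a
known linear function of selected features plus Normal(0, σ) noise, clipped
to [0, 1].  Rates are drawn from Beta(2, 2) (interior-concentrated, so
ratio denominators are never degenerate).  The default planted coefficients
are small enough that clipping affects < 1% of rows at σ = 0.05; clipping
is a deliberate mild misspecification and the recovery tests use σ where it
is rare.  The generator emulates the statistical structure the analysis
stage assumes, *not* the inter-strategy correlation structure of real
tournaments: passing recovery tests shows the analysis machinery is
correct, not that real tournament features satisfy a linear model.

## Numerical choices

* Tie-breaks: ranking ties by name; Meta Winner ties to the earliest
  member; Meta Majority ties to cooperation.
* C_mean is clipped into [C_min, C_max] to keep the aggregate ordering
  invariant exact under floating-point summation.
* The SSE test oracle is an exhaustive grid search over (a, b) ∈ [0, 5]²
  at step 0.01 with a 10⁻⁴-step local refinement, valid because the
  objective is a convex quadratic.
* Degenerate inputs: empty rank sets, zero-denominator ratios and
  unvisited-state conditional rates are missing values, never silent zeros;
  p_e = 0, σ < 0, invalid probability vectors and rank-deficient designs
  raise.

## Problem sizes

The shipped drivers use 40 desk-profile trials (≈ 8 s), the regression
coverage check 300 simulated tables of 40 tournaments per type, and the
sampler-distribution checks 10⁴–1.14×10⁴ draws; these sizes are the
package's chosen desk scale for routine verification.

## Known limitations

* The catalog is a representative, fully specified subset of the published
  strategy space; conclusions about *which* strategies win at desk scale do
  not transfer to larger corpora that include trained strategies.
* The memory-one shadow underlying the SSE is an approximation for
  longer-memory strategies; two-round statistics are not collected.
* The regression stage models a linear feature–rank relationship only.
* Campaign resumption is keyed on the manifest; a crash between a CSV
  append and the manifest update can duplicate one trial's rows.
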