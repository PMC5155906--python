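# Methods

## The game

A session is a group of 10 players. In the hierarchy treatments each player
holds a rank 1..10 (1 = top), either *earned* (players are ranked by
descending skill score, ties broken at random) or *random* (a uniform
permutation); the *control* has no ranks. Players meet every other group
member exactly once over 9 rounds (circle-method 1-factorization, round
order shuffled per session).

Each dyad-round has up to two stages:

1. **Cooperation.** Both players simultaneously contribute an integer
   number of their 20 ECUs to a common pot. If the sum reaches 20 the pot
   becomes 40 units; otherwise the contributions are lost and the trial
   ends. Players learn only success/failure, never the partner's amount.
2. **Splitting.** The higher-ranked player (a randomly assigned proposer in
   the control) offers an integer share of the 40 units; the lower-ranked
   player has stated a minimum acceptable offer and accepts any offer at or
   above it. On rejection a lottery gives the whole pot to the lower-ranked
   player with probability `p_low` and to the higher-ranked player
   otherwise.

Trial payoff: endowment − own contribution + pot share (pot share alone in
the splitting-only treatments, which start directly from a 40-unit pot). At
payout 15 units = 1 euro.

Rank differences d = 1..9 are grouped as k = 5 − ⌊d/2⌋ ∈ {1..5}, with k = 1
the largest gaps (d = 8, 9) and k = 5 adjacent ranks. The lottery rule is
`p_low = k/10` (0.5 in the control). The main text of the study states only
that the lottery is proportional to rank; k/10 is the unique
grouping-respecting rule consistent with the published equilibrium offer of
4k on the 40-unit pot, and it is exposed as a configurable quantity rather
than asserted as the original formula.

## Equilibrium

With risk-neutral players the responder's expected rejection value is
`p_low × 40`, so on the integer grid with acceptance at indifference the
equilibrium acceptance threshold and offer are both `ceil(p_low × 40)` = 4k
(20 without hierarchy). Integer strategy grids are used throughout: the
experiment's currency is discrete and all equilibrium quantities are
integers.

Folding these continuation values (cont_high, cont_low) back into the
contribution stage, payoffs are `E − c_i + cont_i` on success and `E − c_i`
on failure. All pure-strategy Nash profiles are found by brute force over
the 21×21 grid, breaking equilibrium only on *strictly* profitable
deviations (this matters at indifference points: (0, 0) is an equilibrium
under the symmetric 20/20 continuation because deviating to 20 gains exactly
nothing). The equilibria are the exactly-at-threshold profiles with
`c_i ≤ cont_i` for both players, plus (0, 0) whenever neither continuation
value exceeds the endowment. The published analysis characterizes only the
splitting phase; this contribution-stage closure is the package's own and is
labeled as such. For equilibrium play one profile is selected:
`c_low = min(cont_low, 10)`, `c_high = 20 − c_low` — the successful profile
with minimal exposure for the low player.

## Agents

* **nash** plays the selection-rule contribution, the equilibrium offer and
  the equilibrium threshold.
* **inequity_averse** best-responds under Fehr–Schmidt utility
  `U_i = x_i − α·max(x_j − x_i, 0) − β·max(x_i − x_j, 0)` with α ≥ β ≥ 0,
  maximizing expected utility over total trial payoffs on the integer grid.
  Ties prefer acceptance (splitting) and the cooperative selection-rule
  contribution, so α = β = 0 reproduces the nash agent exactly. Two
  consequences worth noting: because rejection triggers an all-or-nothing
  lottery — the most unequal outcome available — a strongly α-averse
  responder *lowers* their acceptance threshold; and a proposer with
  β > 1/2 offers the even split.
* **empirical** is a calibration device (not a fit — the original
  trial-level data are not deposited) reproducing the study's qualitative
  patterns. Contributions: control mean 11; hierarchy low-rank
  `10 + 1.0·k − 0.5·t_c`, high-rank `10 − 0.5·k + 0.5·t_c` with `t_c` the
  mean-centered round. Offers: equilibrium anchor + `max(0, 8 − 1.5k)`
  (hierarchy) or −5 (control); thresholds sit 5 units above the offer
  shift, which puts control offers 25% below control thresholds (15 vs 20).
  Gaussian noise with σ = 3 units, rounded and clipped to the legal grids.

## Synthetic studies

`StudyDesign` defaults to the published scale: 6 groups each of
control/earned/random and 3 each of the splitting-only arms → 24 sessions,
240 participants, 180 in cooperation treatments, between-subjects. Seeding
is hierarchical (master seed → per-session seeds → per-stage streams for
hierarchy, schedule, agent decisions and lotteries), so reruns are
byte-identical and any stage is independently reproducible.

What the generator does **not** emulate: learning or reputation dynamics
within a session (decisions depend on round only through the fixed linear
trend), demographic covariates, the actual ranking tasks (abstract standard
normal skill scores stand in), and any dependence of splitting behavior on
the cooperation history (offers are generated independently of success
counts). Passing tests therefore certify the mechanics, the equilibrium and
the statistical pipeline on data with known structure — not behavioral
claims about humans.

A known wrinkle of the default calibration: it yields lower-ranked members
contributing slightly *more* on average than higher-ranked ones, while
still reproducing the k-trend, the round-trend and the
control-over-hierarchy success surplus. The recovery tests accordingly
assert that the models recover the sign of the *generated* gap.

## Statistical pipeline

Treatments are contrast coded with the orthogonal set h1 = (+2, −1, −1) for
control/random/earned and h2 = (0, −1, +1); round is mean-centered. Four
model families: success (logistic; h1, h2, round, h1×round; dyads as
grouping units), contributions on the ±1 rank code (with rank×round),
contributions on the continuous signed rank difference (negative = focal
player higher-ranked; the top- and bottom-ranked individuals are excluded
because their role never varies), and offers/thresholds on
cooperation-phase presence (±1), role (+1 receiver), |d| and round
(hierarchy treatments only, since |d| is undefined in the control).

Inference is a nonparametric cluster bootstrap: grouping units are resampled
with replacement; within each sampled dyad one member is additionally
selected at random where member-level covariates enter; a fixed-effects GLM
(logit or OLS via statsmodels) is fit per replicate; 95% CIs are the
2.5/97.5 percentiles over 100 replicates. A mixed-model estimator per
replicate is deliberately not reproduced — the contract is the
coverage/recovery behavior of the bootstrap CIs, which the calibration
tests check directly (null generators: the h1 interval covers zero at
roughly the nominal rate; effect-injected generators: the interval excludes
zero with the correct sign). Non-convergent replicates are dropped with the
run failing above a 20% drop fraction; complete-separation fits (e.g.,
all-success data under rational agents) return boundary estimates rather
than crashing and are visible in the report.

Calibration checks run 10 deterministic pipeline repetitions of 18 sessions
× 100 bootstrap replicates each; the analytic and rule-level checks are
instantaneous. Problem sizes were chosen so the full suite runs in a few
tens of seconds on one CPU while leaving the binomial gates (≥8/10
coverage, ≥9/10 detection) well inside Monte-Carlo slack.

## Degenerate inputs and numerical choices

Offers/thresholds/contributions are validated as integers on their grids;
out-of-range values raise. `resolve_split` requires a seeded generator
whenever rejection is possible. The rank–earnings Spearman correlation
returns NaN when earnings or ranks are constant. Acceptance at indifference
(offer ≥ threshold accepts) is required for equilibrium existence on the
integer grid. Rounding uses Python's round-half-to-even; all stochastic
behavior flows from numpy `SeedSequence`-derived generators.
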