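# Methods

`exitchoice` studies how individuals choose between two exit routes during a
simulated crowd evacuation, and specifically whether they rely on
time-independent information (exit width, visible route length) or
time-dependent information (queue lengths and how fast queues move). The
package contains a complete generative twin of such an experiment — an
environment simulator, a scripted crowd, a per-time-step choice model for
the participant — together with the two analysis layers applied to the
resulting data: outcome-level binomial GLMs and per-time-step Bayesian model
selection over a 16-member family of choice models.

## The environment and the scripted crowd (`envsim`)

The environment is a rectangular central room (default 10 m x 10 m, origin
at the centre) with two exits on its right wall at `y = +-2.5` m. The top
exit feeds the longer of two corridors, the bottom exit the shorter one, so
"choosing the shortest route" always means using the bottom exit. Three
treatments modify the environment or the session:

- **S** — the global layout is visible, so participants can see which route
  is shorter (a signed indicator; the geometry itself is unchanged),
- **W** — the top exit is widened to 1.5x the bottom width,
- **M** — a motivational time-pressure message is active (it changes
  participant behaviour, not the geometry).

The scripted crowd (default 40 pedestrians) splits evenly between the exits,
walks straight to its assigned exit at 1.3 m/s, and queues in ordered slots
spaced 0.5 m along the queue axis. Each exit services its queue with a
deterministic fractional accumulator at `c * width` persons/s with
`c = 1.9` persons/(m s), a standard bottleneck-capacity magnitude. This
makes "the wider exit's queue drains faster" an exact property rather than a
statistical tendency, and keeps the whole simulation deterministic given a
seed. There is deliberately no collision avoidance or social-force dynamics:
the crowd is a background stimulus whose only analysed outputs are queue
lengths and their drain rates.

Queue length at an exit is measured as the number of non-exited pedestrians
assigned to it within a capture radius `R = 5` m of the exit centre — a
simple observable proxy, configurable. Queue *flow* at time `t` is the
backward finite difference of queue length over a window (default 2 s),
positive when the queue shrinks; before one full window of history exists
the flow feature is defined as 0.

## Decision features (`features`)

A participant trajectory coupled to a simulated evacuation is sampled at a
fixed interval (default 0.5 s) from the tick at which an initial preference
is established — operationalised as the first tick whose displacement
reduces the distance to one exit by at least 0.05 m — until the participant
passes an exit. Each sample yields, from the top exit's point of view:

| feature | meaning | units |
|---|---|---|
| `q_adv` | queue-length advantage, `q_bottom - q_top` | persons |
| `f_adv` | flow advantage, `flow_top - flow_bottom` | persons/s |
| `w_adv` | width advantage, `w_top - w_bottom` | m |
| `s_vis` | signed shortest-route visibility (0 unless S active) | {-1,0,+1} |
| `d_adv` | distance advantage, `dist_bottom - dist_top` | m |
| `jam`   | signed blocked-in-queue indicator | {-1,0,+1} |

`jam` is nonzero only when the participant stands in the queue zone of one
exit and at least one pedestrian disc (radius 0.25 m) intersects the
straight segment from the participant to the near edge of the *opposite*
exit's opening. Queue membership is taken from the preference at the
*previous* sampling tick — the queue the participant already walked into —
so the jam feature is predetermined at the moment the current choice is
made. Computing membership from the current tick's preference instead would
make `jam` mechanically identical to the choice it is supposed to predict
and visibly biases every coefficient; this alignment matters for any data
fed to the models, not only simulated data.

**Change of mind.** A participant changes their mind if they walk at least
one-fifth of the room height towards one exit and ultimately exit through
the other. Because both exits sit on the same wall, moving towards either
exit usually also reduces the distance to the other one, so raw distance
reduction cannot be the criterion (a committed straight walk to the top exit
reduces the distance to the bottom exit by well over H/5). Each movement
segment is therefore attributed to the exit whose distance it reduces
*most*, and progress is accumulated over maximal runs of segments attributed
to one exit. This makes the detector monotone in the threshold and
classifies a straight committed walk as "no change".

## The choice-model family (`choicemodels`)

At every sampled tick the probability of preferring the top exit is
logistic in an additive combination of the features:

    eta = p1 + [S] p2 s_vis + [W] p3 w_adv + [Q] p4 q_adv + [F] p6 f_adv
          + p8 d_adv 1[|d_adv| >= p9] + p10 jam
    P(top) = 1 / (1 + exp(-eta))

Four components — Q (queue length), F (queue flow), W (width), S (route
length) — are switched on or off, one model per subset: 16 models. Three
components are always present: the constant bias `p1`, the
threshold-gated proximity term (`p8`, `p9 >= 0`), and the jam term `p10`.
Coefficients of excluded components are *absent* from the parameter space,
not fixed at zero, so marginal likelihoods penalise dimension. Features are
kept in physical units (persons, metres, persons/s) with no data-dependent
standardisation, so coefficients are comparable across cohorts and priors
can be stated on physical scales. Rows are treated as conditionally
independent given their features; persistence enters through `d_adv` and
`jam`, not an explicit lag term.

The same family doubles as the generative participant: at each tick it
computes its feature row against the simulated crowd, draws a preference
from the model, and walks one interval towards the preferred exit at
1.3 m/s. While its preferred queue is non-empty it hovers one slot behind
the scripted tail, offset 0.5 m to the outside of the queue line — so queued
pedestrians can genuinely block its cross-path, giving the jam feature
realistic prevalence (about 20% of rows at the defaults) — and it passes
through the exit once that queue has drained.

## Marginal likelihood and model comparison (`evidence`)

The evidence of model X is `P(D|X) = ∫ L(D|θ) π(θ) dθ` over independent
bounded-uniform priors (defaults: `p1, p2, p3, p10 ∈ [-10, 10]`,
`p4 ∈ [-2, 2]` per person, `p6, p8 ∈ [-5, 5]`, `p9 ∈ [0, room height]`).
It is estimated by stepping-stone sampling over a power-law temperature
ladder `β_k = (k/K)^(1/0.3)` (K = 32 rungs by default; the power schedule
concentrates rungs near β = 0 where the integrand changes fastest — a
strictly geometric ladder could not include the β = 0 prior rung the
stepping-stone identity requires). Each rung is sampled by random-walk
Metropolis (400 steps, 30% burn-in) whose proposal scale is adapted towards
30% acceptance during burn-in and whose proposal spread is carried from the
previous rung's posterior spread. Each rung's chain is warm-started at the
previous rung's highest-likelihood sample so the chain tracks the
concentrating posterior; without this, chains occasionally strand on
low-likelihood plateaus and produce evidence estimates hundreds of log units
too low. Acceptance rates outside [0.05, 0.98] flag the estimate with a
warning — never a silent return.

The estimator is validated against a conjugate oracle: 7 successes in 10
Bernoulli trials under a uniform prior on the success probability has
evidence `B(8,4)`, i.e. log evidence -7.1854, reproduced to within
Monte-Carlo error at the default ladder.

Evidence is replicated (5 independent seeds, `base_seed + replicate`) and
reported as mean ± sd. Models are compared by `2 log BF` on the
conventional scale — 0–6 weak-to-positive, 6–10 strong, >10 decisive, with
boundary values assigned to the lower band so categorisation is
deterministic. Rankings follow the block layout: models sharing a Q/F
inclusion pattern form a block (Q&F, Q-only, F-only, neither), and adjacent
blocks are compared worst-of-left against best-of-right, so a positive value
supports the left block even in the worst case.

**Known limitation.** Wherever `p9` exceeds the largest observed `|d_adv|`
the gated proximity term vanishes and `p8` decouples from the likelihood — a
flat plateau. Posterior summaries therefore pool several independent
Metropolis chains from dispersed starts (`posterior_samples`, 6 chains by
default); single chains can linger on one side of the ridge.

## Outcome-level statistics (`glmstats`)

P(shortest route) and P(change) are analysed with logit-link binomial GLMs
(statsmodels IRLS) on S + W + M + age + gender, age centred at the sample
median, gender coded {0, 1}. Single-parameter effects use two-sided Wald
z-tests; age-by-treatment interactions use likelihood-ratio tests of the
main-effects fit against the fit with one interaction added (three separate
tests, age:M, age:S, age:W); a single condition's shortest-route count is
tested against chance with the two-sided exact binomial test
(minimum-likelihood method, scipy). Separation — including the degenerate
constant-outcome case — and IRLS non-convergence raise explicit errors
rather than returning an unconverged fit.

## The synthetic cohort (`cohort`)

A cohort emulates the full study design: 8 conditions (control, S, W, M and
their combinations) x 58 participants = 464, each participant experiencing
an independently simulated crowd (fresh seed) and generating choices from a
known model. Ages follow a shifted log-normal, `16 + LogNormal(log 7,
0.607)`, giving a median of 23 years with about 5% of draws above 35; gender
is balanced Bernoulli.

Generating-truth defaults are the package's declared study conditions,
chosen once to reproduce the qualitative behavioural profile of such
experiments: the time-dependent model (Q, F) with `p4 = 0.4` per person,
`p6 = 1.0` per person/s, `p1 = 0`, proximity `p8 = 2` per m, no threshold
(`p9 = 0`), and a decisive jam effect `p10 = 5`. Under treatment M the
proximity and jam effects are doubled (`p8 = 4`, `p10 = 10`), modelling
reduced willingness to revise a decision rather than any mechanism claim.
At these defaults a cohort realises roughly 20–22 feature rows per
participant at the 0.5 s sampling interval, ~5–10% of participants changing
their mind (fewer under M), ~20% of rows jammed, and a control
shortest-route proportion statistically indistinguishable from one half.

The generating truth is stored in a separate, schema-tagged truth file;
trajectory, decision and outcome CSVs carry no truth fields, so analysis
stages are blind to it and recovery tests must read the truth report.

**What the generator does not emulate:** response-time differences,
learning across trials, between-participant heterogeneity in coefficients
(exposed as a design knob, defaulting to none), first-person perception, or
initial queue-formation dynamics (queues are established before the
participant decides). Passing recovery tests therefore demonstrates that
the pipeline identifies the information participants used *given this
generative family*, not that human data would be equally clean.

## Problem sizes used by the test suite and acceptance script

Chosen as the package's validated working points: parameter recovery uses a
216-participant cohort and pooled 6-chain posteriors of 6,000 steps each;
model recovery uses 240-participant cohorts over three seeds with a 12-rung,
200-step evidence ladder and 2 replicates; the acceptance script runs the
full 464-participant design with 5 replicates per model and stratum at the
same reduced ladder. The conjugate-oracle check and all analytic
recomputations run in seconds. Replicate standard deviations shrink as the
ladder grows (checked at two settings); the reduced ladder trades some
replicate variance for speed, which the replicate sd columns report
honestly.

## Numerical conventions

- Logistic probabilities are computed via `tanh`/`logaddexp` forms; no
  overflow for any finite log-odds.
- The service accumulator saturates: no service credit accrues at an empty
  queue.
- Evidence-band boundaries (6 and 10) belong to the lower band.
- All randomness flows through `numpy.random.Generator` seeded from
  explicit integers; cohorts spawn per-participant seeds via
  `SeedSequence`, so any participant is reproducible from the design alone.
- Degenerate inputs raise typed errors (`ConfigurationError`,
  `CapacityError`, `TrajectoryError`, `SpecificationError`,
  `SeparationError`, `StrataMismatchError`) naming the offending field.
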