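# Methods

## Network model

The simulator is an interactive-activation ("GRAIN"-style) network of
five layers: colour, word and emotional-semantic hidden layers (three
logistic units each), a task-control layer (colour naming, word
reading, emotional processing) and a two-unit response layer.  All
between-layer pathways are bidirectional and excitatory; every
within-layer unit pair is connected with a uniform inhibitory weight,
implementing competition.  Dynamics are synchronous and fully
deterministic: per cycle, each unclamped unit blends its instantaneous
net input into an accumulator at rate τ and emits the logistic (gain
*k*, bias *x₀*) of that accumulator.

Two readings of "running-average" dynamics are possible: integrate the
net input and squash the accumulator (the canonical cascade form), or
integrate the squashed activation itself.  The accumulator form is the
default (`integration_mode: net_input`); the alternative is available
as `integration_mode: activation` for sensitivity checks.  With τ = 1
the update is memoryless; as τ → 0 activity freezes — both limits are
exercised in the tests.

### Default configuration

No reference parameterisation of the extended architecture is
published, so the shipped defaults (`data/default_network.yaml`)
follow the classic interactive Stroop parameterisation and were then
verified against the qualitative behaviour the model must show:

* word↔response 2.6, colour↔response 2.0 — the word pathway is
  stronger (more automatic), producing interference;
* task↔colour and task↔word 4.0, symmetric — strong top-down goal
  support is what lets colour naming win on incongruent trials;
* task↔emotion 2.0 both directions — positive bottom-up emotion→task
  weights let induced emotional activity compete with the colour goal;
* emotion↔response 0.1 — the emotional pathway alone cannot trigger a
  response;
* lateral inhibition −2 in all layers except the response layer (−1);
* hidden biases x₀ = 4 (units rest near zero activation and need goal
  support plus stimulus input to activate), task-control x₀ = 0,
  response x₀ = 1.4; all gains 1, all τ = 0.1;
* threshold 0.55, 50 settling cycles, response deadline 1000 cycles
  (with K ≈ 4 ms/cycle and I ≈ 650 ms this mirrors the behavioural 2-s
  response window).

Under these defaults congruent/incongruent trials take 36/82 cycles at
baseline and 42/98 under the induction context; the congruency effect
is monotonically non-decreasing in task-control gain over the frozen
grid {1.0, 1.25, 1.5, 2.0}.  All values live in the YAML config and
round-trip losslessly; nothing is hard-coded.

### Trial protocol

A trial settles 50 cycles under the context clamp pattern.  Baseline
clamps only the colour-naming goal to 1 (all other task and emotion
units to 0); the induction context additionally clamps the
negative-valence and emotional-processing units to 1.  After settling,
clamps are lifted: task goals are converted into a persistent external
input of 1 (goal maintenance — a goal clamped only during preparation
would otherwise decay during the response phase), while emotion units
keep their induced state in the accumulator and decay freely.  Released
units get the accumulator value whose logistic output equals the clamp
value, clipped to [0.001, 0.999] so they re-equilibrate on the τ
timescale instead of being pinned at ±∞.  Stimulus units then receive
external input 1 and the network runs until a response unit crosses
threshold; simultaneous crossings go to the more active unit, exact
ties deterministically to the first response label (logged).

Which context applies to which participant during fitting follows the
counterbalancing group: group 1 performed the standard Stroop
immediately after the rumination induction (induction context), group
2 performed it later (baseline).  Emotional-Stroop simulation is
implemented but excluded from fitting, which uses standard-task means
only.

## Evolutionary fitting

Free parameters by variant: *base* = pathway weights (colour/word ↔
response, task ↔ colour/word) plus the RT scaling K and I (scaling must
be per-participant to map cycles onto that participant's millisecond
scale); *weights* adds task↔emotion weights (fitted separately per
direction); *neuron* adds layer-level gain, bias and τ for the
task-control and emotion layers; *full* has all 13.  Bounds: weights
[0, 10], gains (0, 10], biases [−10, 10], τ (0.01, 1], K [0.5, 20]
ms/cycle, I [0, 800] ms — covering published interactive-activation
values and plausible human RT scales, all overridable.

The optimiser is a generational real-valued GA: population 50,
100 generations, tournament selection (size 2), blend crossover
(rate 0.9), per-gene Gaussian mutation (probability 0.25, SD 0.1 ×
range), elitism 1, bounds enforced by clipping.  Two deliberate
additions: the initial population contains the default parameter
vector (large regions of the uniform box produce overtime or
degenerate instant responses, so the search needs one member in the
viable regime), and the RT scaling is solved analytically per candidate
— given a candidate's simulated cycle counts, the (K, I) that exactly
reproduce the two data means solve a 2×2 linear system, and are
clipped to bounds (a Lamarckian repair that removes two search
dimensions).  With this solve, self-consistency refits of
model-generated participants are typically exact.  Overtime candidates
receive a fitness of 10⁶, which dominates any plausible squared
millisecond error.  Per-participant seeds derive from the master seed
by a CRC-32 mix with the participant ID, making cohort fits
order-independent.

## Model selection and recovery

Per-participant BIC is Gaussian-error over the two fitted condition
means: n·ln(SSE/n) + k·ln(n) with n = 2; the congruency-difference
fitness term is a linear combination of the two observations and is
not counted as a third.  k counts the variant's free parameters
(including K and I).  Global BIC sums over participants.  Dependence
diagnostics are computed across participants' fitted vectors: pairwise
Pearson r, and mutual information by equal-frequency binning (8 bins,
plug-in estimator, nats) — rank-based binning makes the MI exactly
invariant to monotone rescaling.  The selection rule: exclude variants
with any |r| ≥ 0.7 pair, take the lowest global BIC among survivors,
and fall back to the lowest mean |r| (with a warning) if all are
flagged.

Parameter recovery supports two designs.  The default *joint* design
draws ground-truth vectors uniformly within bounds (rejecting draws
with overtime, instant responses, or a non-positive congruency effect
— regimes no real participant the model describes would occupy),
simulates their condition means, refits, and correlates true with
recovered values per parameter; classes are |r| < 0.3 unrecoverable,
0.3–0.5 fair, 0.5–0.7 moderate, > 0.7 good.  A *partial* design varies
one parameter at a time around the reference configuration instead.

An honest caveat, established with a larger diagnostic run (n = 60
synthetic participants): under the joint design only the RT intercept
is stably recoverable — two condition means simply cannot constrain a
13-dimensional vector, so per-parameter recovery correlations at the
package's scaled-down study size (n = 20) are dominated by sampling
noise (SE(r) ≈ 0.23), and the ordering between task-control and
emotion-side parameters varies from seed to seed.  The committed
seeded study in the test suite documents this: the task-layer gain
recovers better than the emotion→task weight, but the aggregate
task-vs-emotion ordering does not reliably hold.  This global
degeneracy — many parameter sets, indistinguishable behaviour — is
itself the substantive conclusion a user should draw; single fitted
solutions are one point on a large equivalence set.  Under the partial
design the emotion-layer *bias* is genuinely recoverable here, because
the wide bias bounds let emotion units self-activate and shift the
response layer even without induction; narrower bias bounds would
change that.

## Synthetic cohorts

`gen_cohort` emulates the behavioural design: 151 participants (76/75
across the two counterbalancing groups), 4 blocks × 48 standard trials
(half congruent) and 4 blocks × 48 emotional trials (16 words per
valence category drawn without replacement per block), a 2-s response
window.  Trial RTs are gamma with fixed shape ν = 12 (CV ≈ 0.29, a
realistic right skew at ~800 ms means) and mean equal to the
identity-link linear predictor: intercept 800 ms; congruency 89.69 ms;
congruency × brooding 7.47; counterbalancing × congruency × brooding
−4.27 (the package's reference effect sizes, used as generative
defaults); brooding 2 ms/point, sex 10 ms, age 0.5 ms/yr, ESL −67.77
ms, valence slope 0 (the emotional
analysis found none); participant random intercept SD 70 ms; optional
random congruency slope.  With these defaults the marginal condition
means land near 805/960 ms.  Draws beyond 2000 ms become overtime
outcomes; correctness is simulated at 95 % (congruent) / 88 %
(incongruent) / 94 % (emotional) and is used only to exercise the
filters, never as evidence.  Brooding is a sum of five 1–4 Likert
items driven by a participant latent trait (integer scores 5–20).  The
word bank is a synthetic stand-in (the study's word/valence table
lives in its supplement): 16 negative and 16 positive personality
words — including the letter-confound words "greedy" and "rude" — and
16 neutral object words, with deterministic synthetic valence scores.

What the generator does not emulate: sequential RT dependencies,
practice/fatigue or block-position effects, four-colour responding
(the model abstracts to two), and any subjective effect of the
induction.  Green tests therefore certify the pipeline's statistical
machinery, not claims about real participants.

## Behavioural statistics

RT analyses use responded, correct trials within the 2-s window
(incorrect trials are excluded; accuracy is not modelled).  The gamma
identity-link mixed models are fitted by glmmTMB through an Rscript
bridge; because the identity-link gamma likelihood can send the
optimiser to a boundary (random-intercept variance collapsing to 0,
non-PD Hessian), the bridge tries lm-derived starting values first,
then the default start, then BFGS, accepting the first fit that
converges with a positive-definite Hessian; remaining non-convergence
raises (single fits) or is counted and excluded (power simulation).
Wald 95 % CIs are reported; the two task analyses use a Bonferroni α
of 0.025.  The Friedman statistic is computed from within-participant
ranks with tie correction (implemented directly — the SciPy routine
refuses the two-condition case needed for the standard task — and
cross-checked against SciPy at k = 3); pairwise Wilcoxon tests run
only after a significant Friedman result, Bonferroni-multiplied.
Friedman aggregation uses per-participant means (medians via
`aggregate="median"`).  The parameter model z-scores the fitted
parameters and brooding and fits OLS with the counterbalancing ×
task-τ × emotion-τ interaction at α 0.05; counterbalancing-stratified
refits drop the cb terms and use α 0.025.  A condition-number
collinearity warning is attached above 10⁴.  Power simulation
generates replicate cohorts per candidate n, fits them in one R
session, and reports rejection fractions with Wilson intervals.

## Problem sizes

The test suite runs its heavier studies at deliberately modest sizes
chosen as the package's own desk-scale defaults: 10 self-consistency
participants at the full GA budget, a 20-participant recovery study at
a reduced budget (population 40, 60 generations), 20 replicate
n = 150 cohorts for generative GLMM coverage, and 40 replicate n = 60
null cohorts for type-I calibration.  `scripts/acceptance.py` uses the
same scales.
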