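# Methods

`inferca` implements and analyses a hybrid model-based/model-free (MB/MF)
reinforcement-learning account of choice in a dual-outcome bandit task in
which outcome identities can be concealed and recovered by inference over a
learned cognitive map.  This note documents the model, the synthetic-data
generator, the estimation and comparison machinery, the numerical choices,
and the scaled-down study sizes used by the test suite and the acceptance
script.

## Task

Four persons are each associated with a unique (animal, vegetable) pair so
that every animal and every vegetable is favored by exactly two persons.
Structurally, the persons are the four cells of a 2x2 grid (animal x
vegetable): two persons share an outcome iff they agree on one coordinate,
which yields exactly 4 shareable person pairs (the valid choice pairs) and 2
pairs with nothing in common.  A session comprises 10 blocks of 36 trials;
within a block each valid pair is offered exactly 9 times in random order,
with random display sides.  After a choice the chosen person's two outcomes
appear sequentially in random order, each independently rewarded with a
per-block probability drawn iid uniform on [0.2, 0.8] (probabilities are
independent across outcomes and blocks and reset between blocks).  Outcomes
appear in one of three presentation formats, interleaved with equal
probability: standard (S; both outcomes visible), prospective inference (PI;
the second outcome hidden behind a curtain) and retrospective inference (RI;
the first outcome hidden).  Rewards are always visible, so the hidden
outcome's identity — inferable from the map — is what the formats
manipulate.

## Learning model

Three latent value sets, all reset to zero at each block start.  With
rewards signed as +1 (coin) / -1 (nothing):

* MF person values: `Q_MF(chosen) <- (1-f_MF) Q_MF(chosen) + c_MF (r1+r2)`,
  non-chosen persons decay by `(1-f_MF)`.
* MB outcome values: each of the chosen person's outcomes, by its own
  reward, `Q_MB(o_k) <- (1-f_MB) Q_MB(o_k) + c_MB[format, k] r_k`, where k
  is the outcome's temporal position; the two unrelated outcomes decay.
  At choice, a person's MB value is the sum of their two outcomes' values,
  which is what makes MB credit assignment generalize across persons who
  share an outcome.
* Perseveration: `PERS(p) <- (1-f_P) PERS(p) + pr 1[p = chosen]`.

Choice is a softmax over `Q_net = Q_MB + Q_MF + PERS` of the two offers,
with no inverse temperature (the scale lives in the gains; adding one would
make the model unidentifiable).  Credit-assignment gains may be negative;
the optimization box is [-5, 5] for gains and [0, 1] for forgetting rates
(the box is an implementation choice; fitted values sit well inside it).

The six `c_MB[format, position]` gains are the scientific payload: format x
position differences in MB credit assignment measure how inference demands
reshape value updating.  Model variants are linear constraint sets on the
canonical 13-entry parameter vector:

| spec | constraint | free params |
|---|---|---|
| full | cross gains = 0 | 11 |
| RI_cross_CA | none (adds cross gains) | 13 |
| pure_MB | c_MF = f_MF = 0 | 9 |
| pure_MF | all c_MB = f_MB = 0 | 4 |
| no_presentation_MBCA | all six c_MB equal | 6 |
| no_position_MBCA | c_MB equal across positions per format | 8 |
| no_format_MBCA | c_MB equal across formats per position | 7 |
| additive_MBCA | c_MB = c_format + c_pos2·1[pos=2] | 9 |
| flipped_functional | S1=PI1=RI2 and S2=PI2=RI1 | 7 |

The flipped-functional variant ties gains by *functional* order: on RI
trials credit assignment can only operate after the second outcome reveals
the first, so the temporally first outcome is functionally second.  Under
the RI-cross-CA variant, on RI trials each reward additionally reinforces
the other outcome through two cross gains (`c_RI,1->2`, `c_RI,2->1`),
capturing belief-state or working-memory accounts in which the first,
pre-resolution reward attaches to both candidate outcomes; the full model is
its cross-gains-zero restriction.

## Synthetic cohorts

The generator reproduces the experimental schedule exactly (counts,
probabilities, format interleaving, random outcome order, random display
sides — the side-assignment rule is not specified in the task description,
so uniform randomization is used).  A fresh person<->outcome map is drawn
per participant.  Choices are simulated from the model; generating
parameters are recorded for recovery studies.  Default plausible parameter
ranges, chosen once: `c_MF ~ U[0.2, 0.8]`, each `c_MB ~ U[0.05, 0.6]`,
`f_MF, f_MB ~ U[0.05, 0.4]`, `pr ~ U[0, 0.3]`, `f_P ~ U[0.1, 0.6]`.  These
give clearly reward-sensitive but noisy agents with MBCA magnitudes on the
scale of fitted participants.  Reaction times, when requested, come from a
mean-structure generator (new-pair trials slower than replicas, extra
slowing after RI trials, Gaussian noise, truncation); it emulates the mean
signature only, not RT distribution shape.  Missing responses are
representable (and tolerated by the session reader) but never generated.

What passing tests on these cohorts do *not* show: real participants differ
from the generator in every way the model family cannot express (lapses,
drifting attention, RT-choice coupling, asymmetric reward/non-reward
learning), so green checks here validate the pipeline's correctness and
power at the stated sizes, not the empirical conclusions; those require the
deposited participant data, which the session reader can ingest.

## Estimation

Per-participant maximum likelihood with multi-start box-constrained
optimization.  The likelihood and its exact gradient (forward
sensitivities: all state updates are affine in the state, so derivative
recursions cost another ~100 flops per trial) are numba-compiled, as is the
optimizer itself — a projected L-BFGS (memory 8, two-loop recursion, Armijo
backtracking onto the box, projected-gradient stopping rule at 1e-6).
Hand-rolling the optimizer is a deliberate choice: the bootstrap comparison
study below performs ~4x10^5 fits, and a Python optimizer's per-call
overhead would dominate total runtime by an order of magnitude.  The
compiled fitter's optima are cross-checked against scipy's L-BFGS-B in the
test suite.  Starts are uniform over the box plus one deterministic
"neutral" start (gains 0, forgetting 0.2); 200 starts is the full-scale
default, 10-20 the routine working depth (the multi-start stream is
prefix-stable, so the best likelihood is non-decreasing in the number of
starts under a fixed seed).  When a super-model is fitted alongside a nested
sub-model, the sub-model's solution is embedded as an extra warm start; this
both accelerates convergence and enforces likelihood dominance of the
super-model to tolerance.  Ties across starts break first-found.  Trials
with missing choices contribute nothing to the likelihood and trigger no
update.  Participants whose full-model fit has all 7 CA gains (c_MF plus six
c_MB) strictly negative are excluded as reward-insensitive.

## Model comparison (BGLRT)

The statistic 2(LL_full - LL_sub) has no usable asymptotic null here, so the
null is built by parametric bootstrap: simulate the fitted sub-model on
fresh plans drawn with the experimental schedule, refit both models to every
synthetic session with the *same* procedure used on the real session, and
take the proportion of bootstrap statistics at least as large as the
empirical one (no continuity correction).  Full-scale depth is 1001
bootstrap sessions per participant; group-level inference sums statistics
over participants and compares against 10,000 resampled sums of one
bootstrap draw per participant (rejection rule p <= alpha).  Bootstrap
refits use reduced multi-starts (default 20; the calibration study uses a
single neutral start plus the warm start) — calibration survives because
empirical and bootstrap sides run the identical procedure, and warm-starting
the full model from the embedded sub-model solution guarantees non-negative
statistics on both sides.  Negative statistics arising without warm starts
are clamped to zero with a warning.

Parameter recovery follows the standard protocol for fitted cognitive
models: recovery datasets are simulated from each participant's
*best-fitting* full-model parameters
(not from latent generating draws) and refitted; Pearson correlations
between generating and recovered values are computed per MBCA gain across
all participant x repetition datasets, and error trade-offs as pairwise
correlations of estimation errors.  The distinction matters at desk scale:
with 360 trials the per-gain ML error SD is ~0.24, comparable to the
plausible-range SD (0.16), so recovery from latent draws tops out near
r = 0.55 while the protocol's fitted-parameter spread yields r = 0.6-0.9.

## Signature analyses

Consecutive valid-choice trial pairs within a block partition into
repetition transitions (trial n+1 re-offers the trial-n choice; a common-
outcome reward effect on repetition isolates MF credit assignment, since
the shared outcome cancels from the MB comparison) and generalization
transitions (the previous choice is excluded; exactly one offered person
shares an outcome with it, and the shared outcome's reward effect on
choosing that person isolates MB credit assignment).  The full-transition
design regresses the chosen display side on an MB regressor built from the
trial-n outcome unique to one offered person, six format x position MF
reward regressors (zeroed when the previous choice is absent, sign-flipped
when it sits on the left) and a perseveration term.  The cross-CA selection
restricts generalization transitions to RI trials n with the common outcome
seen second; the hidden first reward's effect (NON_COMMON) is the footprint
of cross-credit assignment.  Reward regressors are +/-0.5; format indicators
are 0/1 dummies with S as reference (hence composite main effects such as
`(3b_COMMON + b_COMMON:PI + b_COMMON:RI)/3`); serial-position coding is
per-analysis (+0.5 = first in the repetition/generalization and parameter
analyses, -0.5 = first in the full-transition design), with temporal
position stored and codings applied at design-build time.

Mixed-effects models with participants as free-covariance random effects
are estimated by the two-stage summary-statistics method: the fixed-effects
design is fitted per participant (ridge-stabilized logistic regression for
binary responses — penalty 1/C with C = 100 — to keep coefficients finite
under separation; exact least squares for the linear designs), then
population estimates, Wald t and Hotelling-type F contrast tests are
computed across the per-participant coefficient vectors, whose sample
covariance is the unrestricted random-effects covariance.  No installed
package fits a joint-likelihood logistic GLMM with free random-effect
covariance, and for the linear analyses used here (one observation per
design cell per participant, saturated first stage) the two-stage estimator
coincides with the classical repeated-measures analysis.  Its t/F reference
distributions use between-participant degrees of freedom (n-1, or (q, n-q)
jointly), which is conservative relative to the large denominator df a
joint GLMM reports.  Bootstrap power over participants exploits the
two-stage structure: resampling participants is exactly resampling rows of
the first-stage coefficient matrix, so 1000-resample power estimates
(optionally up-sampled to a larger cohort) cost milliseconds.

The parameter-level analysis regresses the six fitted MBCA gains on format
dummies x position (and a functional-position variant with the two RI gains
swapped), and quantifies retrospective impairment per participant as the
S-minus-RI gain difference per position, with their Pearson correlation and
the regression of the position-2 impairment on the position-1 impairment
(a positive intercept is the baseline sparing of the hidden outcome).  The
RT analysis drops responses faster than 250 ms and the first trial of each
block, classifies trials as replica (same offered pair as the predecessor)
or new, and fits per-participant mean RT on TYPE (+/-0.5) x previous-trial
format.

## Earnings simulations

Earnings are standardized per session against a guessing agent (earns the
mean of the two offers' expected total reward) and an oracle (earns the
max): standardized = (agent - guessing)/(oracle - guessing).  Agent earnings
are realized coins; baselines are expectations — so the oracle *policy*
scores 1 and uniform choice 0 in expectation.  Yoked format agents copy a
fitted participant's MBCA gains from one format across all three (pure MB:
no MF learning, no perseveration; fitted f_MB), all agents playing the same
fresh sessions; the grid study sweeps total RI-MBCA t in 0.3..3 (step 0.3)
and inferred-outcome fraction p in 0..1 (step 0.05) with gains t/2 in the S
and PI slots, pt and (1-p)t in the RI slots, f_MB fixed at the cohort
average (0.15 when none is supplied).  Grid cells share session plans
(common random numbers), sharpening between-cell comparisons; the
tie-resolution rule for the argmax reports the median of the grid points
statistically tied with the maximum (within two combined — paired, where
raw per-session values are available — standard errors), which favours the
point whose neighbours are not significantly higher.  Full-scale depth is
10,000 sessions per cell.  The earnings regression uses iteratively
reweighted M-estimation (Huber weights) of standardized earnings on overall
MBCA level (mean of the six gains) and position asymmetry (mean over
formats of |first - second|).

## Scaled-down study sizes

Routine verification runs at reduced depth; sizes were fixed once:

* nesting dominance: 20 full-length sessions, 10 starts + warm starts;
* parameter recovery: 30 participants x 3 repetitions, 20 starts;
* BGLRT calibration: 200 cohorts of 10 participants x 4 blocks, 99
  bootstrap refits, single-start fits with warm-started full model;
* signature dissociation: 20 participants x 10 sessions per cohort;
* earnings surface: 1,000 sessions per cell at total 1.5; baselines:
  1,000 sessions.

The analysis drivers under `analysis/` use similar depths and state their
own in their headers.

## Known limitations

* The two-stage estimator underweights participants with few usable
  transitions relative to a joint GLMM and does not shrink extreme
  per-participant coefficients; with very small per-participant tables the
  ridge penalty biases first-stage coefficients toward zero.
* Degrees of freedom for contrast tests are between-participant; reported
  p values are therefore conservative at fixed effect size.
* The RT generator is a mean-structure stand-in; analyses of RT shape or
  skew are out of scope.
* Standardized earnings are heavy-tailed on short sessions (the
  oracle-guessing denominator can be small), so earnings checks use
  full-length sessions.
* The fitter's box bounds cap |gains| at 5; pathological sessions wanting
  larger values would sit on the boundary (flagged by the convergence
  diagnostics).
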