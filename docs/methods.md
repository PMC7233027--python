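# Methods

This note documents the models implemented in `gonogo`, the numerical
choices behind them, what the synthetic cohorts do and do not emulate,
and the known limits of the approach.

## Task model

The orthogonalized go/no-go task crosses action (go vs. no-go) with
outcome valence (win vs. avoid loss), giving four cued contexts — G2W,
G2AL, NG2W, NG2AL — interleaved in a uniformly shuffled order, 36 trials
per context (144 per session) by default. Feedback is probabilistic:
the action-appropriate outcome arrives with probability 0.8 (the
*feedback validity*), the other outcome otherwise. Win contexts emit
outcomes in {+1, 0} and loss contexts in {0, −1}; the unit returns stand
in for the ±10 pence task currency. The schema keeps missing responses
but no model emits them: they are excluded from all likelihoods and
trigger no learning update.

Two conventions close gaps the task description leaves open:

* The first trial of each context chain has `n_gap := 1` and no
  forgetting is applied before the first exposure (beliefs start at the
  prior); the forgetting recursion is the identity at that point either
  way.
* The random interleaving is unconstrained (no maximum run length).

## Rescorla–Wagner family

All eight variants share the compressed-softmax choice rule

p(go) = ξ·σ(W_go − W_nogo) + (1 − ξ)/2,

where σ is the logistic function and ξ ∈ (0, 1) is the *irreducible
noise*: the probability mass reserved for a uniform lapse, bounding
choice probabilities inside [(1−ξ)/2, (1+ξ)/2]. Action values update
as Q ← Q + ε(ρ·r − Q) with learning rate ε and outcome sensitivity ρ
(ρ_win / ρ_loss in the dual-sensitivity variants); a state value V
updates identically but action-independently. ρ is functionally an
inverse temperature: scaling it multiplies every weight difference by
the same factor (asserted numerically in the tests).

The nesting is: Model 1 {ρ, ε} with ξ fixed at 1; Model 2 adds ξ;
Model 3 adds a go bias b; Model 4 adds the Pavlovian bias π·V(s) on the
go weight; Models 5/6 are 3/4 with dual ρ; Model 7 replaces π·V with a
*constant* Pavlovian bias π_c·sgn(V); Model 8 adds a decay δ that
multiplicatively shrinks all Q entries not updated on the current trial.
Conventions: Q and V start at exactly 0 (no free initial values);
sgn(V) for the constant bias latches permanently on the first non-null
outcome in a context (a 0 outcome does not latch); decay does not touch
V. With δ = 0, Model 8 reproduces Model 7 bit-for-bit (tested).

## Active-inference agent

The agent treats each cue as belonging to an unknown context and does
Bayesian inference over a 16-state space ({initial, lose, null, win} ×
4 contexts), of which 12 are reachable. Transitions are block-diagonal
over contexts; the initial state reaches the optimal outcome with
probability 0.8 under the context-appropriate action (0.2 under the
other), and outcome states are absorbing. The observation map is
deterministic, so the likelihood is folded into the transition matrices
rather than kept as a separate observation model.

Parameters (native ranges):

| parameter  | meaning                                             | default (group mean / SD in estimation space) |
|------------|-----------------------------------------------------|----------------------------------------------|
| α          | prior on policy precision (gamma shape, rate β = 1) | 1.627 / 0.31 (log)                           |
| c_τ        | precision of prior preferences over returns         | 5.785 / 0.019 (log)                          |
| f          | working-memory forgetting rate                      | 0.593 / 0.48 (logit)                         |
| p_W        | prior p(context is win-valenced)                    | 0.5163 / 0.14 (logit)                        |
| p_go_W     | prior p(best action is go | win)                    | 0.5211 / 0.21 (logit)                        |
| p_nogo_AL  | prior p(best action is no-go | avoid-loss)          | 0.5063 / 0.13 (logit)                        |

The three Pavlovian priors combine into the context prior D0 by direct
multiplication. Preferences c put mass on the 8 reachable outcome
states: the softmax of returns {−1, 0, +1} at inverse temperature c_τ,
tempered by the prior prevalence D0 of the outcome's context, then
normalized. c_τ is estimable but its tiny prior SD makes it virtually
fixed; the implementation honors the prior rather than hard-fixing it.

Per trial the agent: (1) decays the stored context posterior toward D0,
D_t ∝ D_stored·(1 − f^g) + D0·(1 − (1−f)^g) over the g = n_gap
intervening trials, renormalized (the weights already sum to one at
g = 1; renormalizing is the only way to keep a distribution at g > 1);
(2) scores each policy by the negative Kullback–Leibler divergence
between its predicted outcome distribution and c (the policy-quality
matrix Q, entries ≤ 0 with equality only when prediction and preference
coincide); (3) infers policy precision γ by fixed-point alternation of
π̂ = softmax(γ·Qŝ) and γ = α/(1 − π̂ᵀQŝ), so γ ∈ (0, α] and attains α
exactly when Qŝ = 0; (4) emits go with probability
Σ_j π̂(go|s_j)·ŝ(j), the per-state policy posterior mixed by the
context belief placed on the four initial states; and (5) Bayes-updates
the *decayed* belief with the transition-implied likelihood of the
observed action/outcome to form the new stored posterior. On a missing
response the decayed belief is stored unchanged.

Numerical choices: the fixed point starts at γ₀ = α, stops when
successive γ change by < 1e−6, and is capped at 64 iterations (the last
iterate is returned on cap); the agent's generative validity is fixed
at 0.8 (task instruction, not a free parameter); when p(go) = 0.5 in
simulation the action is still drawn from the RNG.

## Hierarchical fitting

Parameters are Gaussianized: log for positive scales (ρ's, α, c_τ),
logit for unit-interval rates (ε, ξ, δ, f, the three Pavlovian priors),
identity for unconstrained biases (b, π, π_c). Fitting is empirical-
Bayes EM: the E-step computes each subject's MAP in transformed space
(multi-start L-BFGS, default 5 starts — the first at the prior mean,
the rest jittered by half the prior SD — with a central-difference
Hessian inverted after eigenvalue clipping at 1e−6 for the Laplace
covariance); the M-step sets the group mean to the average MAP and the
group variance to the average second moment (MAP² + Laplace variance)
minus the squared mean, floored at SD 1e−3. EM stops when transformed
group means move < 1e−3 (default cap 20 iterations). The EM objective
is monitored and decreases are logged as warnings rather than errors,
since the Laplace E-step is approximate. A session with no observed
responses returns the prior mean and covariance.

## Model comparison

The integrated group-level likelihood draws N = 2000 parameter vectors
per subject from the fitted group Gaussian (in transformed space),
averages the data likelihoods with log-sum-exp, and sums the per-subject
logs. iBIC = −2·(integrated log-likelihood) + |θ|·ln|s| with |θ| the
number of group hyperparameters (a mean and an SD per free parameter)
and |s| the total number of observed choices; smaller is better.
Pseudo-R² = |1 − L/(t·ln ½)| per subject: 0 at chance, 1 at perfect
prediction, with the absolute value folding worse-than-chance fits back
into [0, 1].

## Behavioral statistics

The decision point of a signed action sequence (go = +1, no-go = −1) is
the earliest split d ∈ [0..n] maximizing
|Σ(a₁..a_d)| + |Σ(a_{d+1}..a_n)|; d = 0 means the subject never changed
their mind. Normalized switches are computed within context chains
(switching between contexts is not a change of policy) and divided by
the number of observed consecutive pairs, so the statistic is bounded
in [0, 1] even with missing trials. Accuracy curves average correctness
per context by within-chain trial; the above-chance flag requires
> 50 % correct in every context over the last 20 trials.

## Synthetic cohorts and the covariate

`synthetic_cohort` samples each subject's transformed parameters from
group Gaussians and simulates full sessions. The active-inference
defaults are the empirical group priors in the table above. The RL
group defaults are round synthetic conventions chosen once for this
task family, not estimates from any dataset: ρ 2.0 (log-SD 0.5),
ε 0.15 (logit-SD 0.7), ξ 0.85 (logit-SD 1.0), b 0.3 (SD 0.5), π/π_c
0.3 (SD 0.5), δ 0.1 (logit-SD 0.7).

The covariate emulates limbic-striatal D2/3 receptor availability
(BP_ND) only as a scalar: intercept + slope·g(θ) + quad·g(θ)² +
Gaussian noise, with g the source parameter's fitting transform
(defaults: source α, intercept 2.5, slope −0.3, quad 0, noise SD 0.3).
No kinetic modelling, scanner noise, or regional structure is
simulated, so passing association tests show the *pipeline* detects
constructed dependencies at the constructed size — they say nothing
about receptor biology.

What the generator does not emulate: reaction times, slow-response
warnings, attentional drift, session-position effects, or any
correlation structure between parameters (they are sampled
independently).

## Association stage

Fitted parameters enter the factor analysis in transformed space,
standardized. Default extraction is iterated principal-axis factoring
(communalities initialized at squared multiple correlations) with
varimax rotation and 3 retained factors; extraction method ("ml" via
scikit-learn is available), rotation, and factor count are
configuration keys because no single convention is canonical. Factor
scores use the Thurstone regression estimator. Covariate regressions
are OLS with intercept and optional quadratic term (t-tests on n − p
degrees of freedom); the purely linear model also reports the Pearson
correlation, whose p-value is algebraically identical to the slope's
t-test (asserted in the tests). No multiple-testing correction is
applied inside the stage; Bonferroni thresholds are left to the caller.

## Problem sizes and replication

Stochastic checks run at reduced replication chosen as this package's
own study sizes: parameter-recovery uses 50 subjects × 144 trials with
a short EM schedule (2 iterations, 3 optimizer starts) appropriate for
simulate–refit loops; model-recovery uses ten replicate 40-subject
cohorts (comparable to the 75-subject study scale — at much smaller
cohorts the iBIC's per-hyperparameter penalty of ln|s| nats outweighs
the likelihood advantage of the generating model's extra mechanisms,
and the comparison is uninformative about recoverability); integrated
likelihoods in tests use 300–1000 Monte-Carlo draws instead of the
production default of 2000.

## Known limitations

* Policy precision recovery under the default active-inference group
  distributions is weak: with f ≈ 0.6 the context beliefs stay close to
  the prior, the belief asymmetry that α acts through is small, and
  p(go) is nearly flat in α. An ideal grid-posterior estimator with all
  other parameters known recovers log α at r ≈ 0 at these settings, so
  simulate–refit correlations for α are low and seed-dependent. The
  other parameters (f, the Pavlovian priors, and the RL family's
  ρ_win/ε/b/π_c) recover well.
* The Laplace covariance can be inaccurate near transform boundaries
  (e.g. ξ → 1), inflating M-step variances.
* The EM objective is not guaranteed monotone under the Laplace
  approximation; decreases are logged.
* The agent's policy depth is a single action step; transition
  probabilities are fixed and not learned; the variational
  message-passing interpretation of the update scheme is out of scope.
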