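# Methods

## Task model and ideal observer

The environment is a box with `n_switches` binary switches (default 6) and
a deterministic outcome rule. Sparse: one hidden *working* switch; lights
on iff it is in the on-set. Dense: one hidden *broken* switch; lights on
iff any other switch is in the on-set. One paid activation of a chosen
on-set constitutes a trial; the activation toggle and coin slot are not
modelled mechanically.

With a uniform prior over the single hidden target and noiseless outcomes,
Bayesian updating degenerates to candidate elimination, so beliefs are
represented as candidate sets carrying an implicit uniform distribution.
A probability-vector belief would add nothing here and is deliberately out
of scope. Updating is monotone (candidates only shrink), the true target
always survives updating on its own evidence, and an observation that
empties the candidate set raises a contradiction error naming the trial —
it can only arise from a corrupt log. The empty on-set is legal (the box
can be activated with everything off) but is uninformative by construction
in both conditions.

Switch indices are 1-based in the API and all file formats, matching the
physical labelling of the box.

## Information metrics

EIG(a) = H(C) − Σₒ P(o|a,C)·H(C|a,o), computed in closed form from the
split of the candidate set by predicted outcome (0·log 0 = 0). Exact
brute-force enumeration of all 2ⁿ−1 on-sets (guarded at n ≤ 16) provides
the step-wise optimal benchmark. Useful exact facts, verified exhaustively
in the tests for n ≤ 8: in sparse the EIG-maximisers are precisely the
on-sets splitting the candidates as evenly as possible; in dense (≥ 3
candidates) an on-set is informative iff it is a single still-candidate
switch.

Per-trial efficiency is chosen EIG divided by the best EIG available at
the *true* posterior — the benchmark learner integrates all of the
participant's previous evidence, it is not memoryless. Trials where the
best available EIG is zero (e.g. after certainty) have undefined
efficiency and are excluded from participant means rather than scored 1:
exclusion cannot inflate group means and avoids rewarding vacuous tests.
A participant with no defined trial has an undefined mean.

## Simulated learners

Policies: `random` (each switch on with p = .5, empty set possible),
`test_one` (uniform over switches not yet tested singly, falling back to
untested candidates, then any candidate), `split_half` (uniform subset of
the candidate set of size ⌈|C|/2⌉; floor is configurable), `greedy_eig`
(uniform over exact EIG argmaxes) and `switcher` (alternates singleton and
split-half tests; used to plant "other" sessions). In the dense condition
split-half operates on the candidate *target* set — the natural transfer
of "possibly working" to "possibly broken". Policies stop at certainty or
when the token budget runs out; the matched random baseline instead forces
each simulant to the yoked participant's trial count. All draws flow
through per-participant generator streams derived from (global seed,
participant index), so cohorts are byte-reproducible.

One property worth flagging: with 6 switches in sparse, random p = .5
subsets are frequently near-half-splits, so random interveners score a
mean per-trial efficiency statistically indistinguishable from pure
test-one learners (~0.75 both). The robust qualitative pattern — split-half
dominant in sparse, test-one dominant in dense, random worst by a wide
margin in dense — is what the tests assert.

## Strategy classification

Eligible trials are those whose pre-trial candidate set holds ≥ 4
switches. A session is `test_one` if every eligible on-set has size 1,
`test_multiple` if every eligible on-set has size > 1, `other` for a mix,
and `unclassifiable` (excluded from tables) when no trial is eligible.
Changing ineligible trials never changes the label.

Information-optimality has two modes. `rule` (default for reporting):
sparse — first eligible test uses 2–4 switches and every later eligible
test turns on ⌊|C|/2⌋ or ⌈|C|/2⌉ of the switches still in contention;
dense — every eligible test is a single switch never turned on before.
`strict_eig` requires exact EIG-maximisation on every eligible trial. The
two deliberately diverge in sparse: 2- and 4-switch first tests satisfy
the rule at 0.918 bits while the optimum is 1.0, so `strict_eig` is a
strictly stronger sensitivity check, not a replacement.

Session-quality flags are documented approximations: `early_stop` — the
first guess was made with ≥ 2 candidates remaining; `unnecessary_tests` —
some paid test had zero best-available EIG or zero chosen EIG. Guesses are
verified free of charge and never enter EIG or classification.

## Token economy

Payout = (6 − paid tests) × €0.50 if the final answer is correct, else €0
(forfeiture on a wrong first guess is the default and is configurable,
since the procedure also allows re-guessing). `expected_policy_payout`
evaluates a policy exactly by dynamic programming over (belief, policy
bookkeeping, tests paid, revealed flag) in rational arithmetic, averaging
over the six equally likely targets and the policy's own randomisation.
Stopping rules: `certainty` stops once elimination leaves one candidate;
`direct_hit` keeps paying until a test's diagnostic outcome pins the
target directly (lights-on in sparse, lights-off in dense, with the
updated belief a singleton) — a learner certain by elimination still pays
one test on the sole candidate. Reference values recovered exactly:
dense test-one direct-hit €1.25 (E[tests] = 3.5); dense test-one certainty
€4/3; sparse split-half certainty €5/3 (T(6) = 1 + T(3), T(3) = 5/3).
No policy/stopping combination consistent with the entropy bound
(E[tests] ≥ log₂6 ≈ 2.585 for certainty in sparse) can reach an expected
return near €1.90 in sparse; the evaluator lets users check candidate
derivations rather than asserting one.

## Statistics

The two-sided Fisher exact p-value is the sum of hypergeometric
probabilities of margin-consistent tables no more probable than the
observed one (the dominant software convention; conventions differ, hence
documented). Computation is delegated to `scipy.stats.fisher_exact`; the
test suite carries an independent from-scratch enumeration oracle. Power
for a two-proportion design is estimated by Monte-Carlo: binomial group
counts per replicate, rejection at p < α, with the binomial standard
error reported. A 40-point difference is placed symmetrically as
0.30 vs 0.70 (the conservative symmetric placement; both proportions are
configurable). Exact enumeration gives 0.7822 for n = 25/group at α = .05
— the package reports the honest estimate rather than rounding it to the
conventional 80% planning bar. For reference, the 17/19 vs 3/7 accuracy
contingency has a two-sided Fisher p of 0.0278 by enumeration. Bootstrap
confidence intervals for group means use the percentile method with a
seeded generator.

## Synthetic cohorts

The generator emulates session logs: per cell (age group × condition ×
size), each simulant draws a planted strategy from a mixture over
{test_one, test_multiple_split_half, other_switcher}, runs the matching
policy until ≤ `guess_threshold` candidates remain (default 1) or tokens
run out, then guesses. With probability `inference_noise` the simulant
fails to integrate its evidence and guesses uniformly over **all**
switches — the candidate set of a non-integrating learner. (The
alternative reading, uniform over the true current candidates, is vacuous
once the belief is a singleton and could not lower accuracy at all; the
chosen model is what makes noise a pure *inference* deficit, leaving the
intervention sequence untouched.) Wrong guesses are verified free,
eliminate the guessed switch, and repeat until correct; only a correct
first guess pays out.

Defaults approximate the study conditions and are labelled approximations
in config, chosen once: cell sizes 24/29/28/23; per-cell mixtures set from
the reported first-test one/multiple percentages scaled by 0.8 with a flat
0.2 switcher share; inference noise 0.65 (younger) vs 0.10 (older),
placing the younger-group deficit in inference reliability and reproducing
an accuracy gap of roughly 45% vs 90% among test-multiple simulants as a
mechanism, not as a fit to specific counts.

What the generator does **not** emulate: reaction times, token-insertion
events, incomplete/excluded records, interleaved test-guess-test
sequences, or any age trend in intervention choice beyond the mixture.
Passing pipeline tests on synthetic cohorts therefore demonstrates
correctness of the analysis machinery, not fidelity of the behavioural
model to real children.

Log schema (CSV; the original logging format is unpublished, so this is a
documented invention): trials — participant_id, age_group, condition,
target_switch, trial_index, s1..sN ∈ {0,1}, lights_on ∈ {0,1}, optional
planted_strategy (off by default to mimic real data); guesses —
participant_id, guess_index, guessed_switch, verified_correct. Payout is
recomputed from the payment rule on read, so write→read round-trips are
lossless.

## Numerical choices and problem sizes

EIG ties are broken uniformly at random under the session seed (the value,
not a canonical set, is what the benchmark defines); tie detection uses a
1e-12 absolute tolerance on bits. Exact payout evaluation uses
`fractions.Fraction` throughout. Monte-Carlo sizes used by the test suite
were chosen to keep the full run near twenty seconds on one core while
leaving comfortable statistical margins: 100 000 sessions for the
enumeration-vs-simulation payout check, 2500–5000 replicates for power
estimates (binomial SE ≤ 0.7 points), 250–400 simulants for cohort-level
recovery and ordering checks. The power simulation deduplicates repeated
(x₁, x₂) tables before calling the exact test.

## Known limitations

- Single-target hypothesis spaces only; no interacting or stochastic
  switches, no multi-cause hypotheses.
- Efficiency is pure EIG ratio; no token-discounted value of information.
- The taxonomy can label a planted switcher `test_one` when its first
  singleton test luckily ends the session — a property of the taxonomy's
  eligibility window, inherited by any analysis built on it.
- Regression-based analyses (logistic/Poisson, Bayes factors, ROPE) are
  out of scope; the package stops at exact contingency tests, bootstrap
  summaries and power simulation.
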