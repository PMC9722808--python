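# switchbox

Tools for analysing **active causal learning on a six-switch box** under two
causal-sparsity regimes. In the *sparse* condition exactly one of six
switches works and the lights come on iff it is among the switches turned
on; in the *dense* condition exactly one switch is broken and the lights
come on iff any other switch is on. A learner pays one token (of six, worth
€0.50 each) per box activation, keeps the remaining tokens only if their
final answer is correct, and tries to identify the hidden target switch in
as few paid tests as possible.

The package is aimed at computational cognitive scientists studying
children's (and adults') intervention strategies: it provides the task
model, the Bayesian ideal observer, information-theoretic scoring of
intervention choices, simulated learner baselines, behavioural strategy
classification, exact reward-policy evaluation, and the contingency/power
statistics used for design and analysis — all runnable end-to-end on
seeded synthetic cohorts.

## The model

Because outcomes are deterministic and the prior over the target uniform,
the ideal observer is candidate elimination: the belief state *C* is the
set of hypotheses consistent with all evidence, with H(C) = log₂|C| bits of
uncertainty. The expected information gain of turning on a set *a* of
switches is

EIG(a) = H(C) − Σₒ P(o | a, C) · H(C | a, o),

which, with *k* candidates predicting lights-on, reduces to
log₂ m − (k/m)log₂ k − ((m−k)/m)log₂(m−k). In sparse, EIG is maximised by
*split-half* tests (turn on as close as possible to half the candidates);
in dense, only single untested switches are informative, making
one-at-a-time testing — the control-of-variables strategy — the only
effective approach. A participant's *efficiency* on each trial is their
chosen EIG as a proportion of the best EIG available given a fully
integrated posterior.

Sessions are classified from the trials made while ≥ 4 switches were still
in contention: *test one* (every eligible test a single switch), *test
multiple* (every eligible test more than one), *other* (a mix), with an
additional information-optimality flag.

## Worked example

```python
from switchbox import (BeliefState, PolicySpec, TaskConfig,
                       expected_information_gain, expected_policy_payout,
                       participant_efficiency, run_policy)

dense = TaskConfig(condition="dense")
sparse = TaskConfig(condition="sparse")

# EIG of a 3-switch test from the full sparse belief: a perfect split
print(expected_information_gain(BeliefState.full(sparse), {1, 2, 3}, sparse))
# 1.0                      (halves the 2.585-bit uncertainty optimally)

# Exact expected reward of one-switch-at-a-time search in dense,
# paying until the broken switch is directly observed:
print(expected_policy_payout(PolicySpec(kind="test_one"), dense,
                             stopping="direct_hit"))
# 1.25                     (E[tests] = 3.5 -> (6 - 3.5) x EUR 0.50)

# A simulated split-half learner hunting the working switch 6:
trials = run_policy(PolicySpec(kind="split_half", seed=0), sparse, target=6)
print([sorted(t.on_set) for t in trials],
      participant_efficiency(trials, sparse).participant_mean)
# [[4, 5, 6], [4, 6], [4]] 1.0
#    (each test halves the candidate set: 6 -> 3 -> 2 -> 1, all EIG-optimal)
```

The `examples/` directory holds one short script per capability (belief
updating, EIG scoring, policy baselines, classification, rewards,
statistics, cohort pipeline); each prints its numbers with a line on what
they mean. A thin CLI wraps the pipeline:

```bash
switchbox generate --out-dir logs --seed 5
switchbox analyze --log logs/trials.csv --out-dir reports --seed 5
switchbox power --p1 0.3 --p2 0.7 --n 25 --replicates 5000
```

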