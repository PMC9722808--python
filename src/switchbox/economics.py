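"""Token accounting and exact expected-reward evaluation of search policies.

Participants start with ``n_tokens`` tokens (6, worth 0.50 EUR each), pay
one per box activation, and keep the remainder only if their final answer is
correct. The best possible outcome — one lucky test then a correct guess —
is therefore (6 - 1) x 0.50 = 2.50 EUR.

``expected_policy_payout`` evaluates a policy *exactly*: a dynamic program
over (belief state, policy bookkeeping, tests paid) averages over the
uniformly random hidden target and over the policy's own randomisation, so
no Monte-Carlo error enters. Two stopping rules are supported:

* ``certainty`` — the learner stops paying as soon as elimination leaves a
  single candidate;
* ``direct_hit`` — the learner keeps paying until a test *directly* reveals
  the target (the diagnostic outcome with the target pinned down by the
  tested set itself); a learner certain by elimination still pays one more
  test on the sole candidate. Under this rule the single-switch-at-a-time
  searcher in the dense condition pays a uniform 1..6 tests, E = 3.5, hence
  the expected return (6 - 3.5) x 0.50 = 1.25 EUR.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from itertools import combinations
from typing import Iterable

from .core import BeliefState, Condition, TaskConfig, simulate_outcome
from .information import best_interventions
from .policies import PolicySpec, _split_half_size

STOPPING_RULES = ("direct_hit", "certainty")


@dataclass(frozen=True)
class PayoutRule:
    """The study's payment scheme."""

    n_tokens: int = 6
    token_value: float = 0.50
    forfeit_on_wrong_final_guess: bool = True


def realized_payout(
    n_tests: int, correct: bool, rule: PayoutRule = PayoutRule()
) -> float:
    """Cash actually earned: remaining tokens x value if correct, else 0."""
    if not 0 <= n_tests <= rule.n_tokens:
        raise ValueError(
            f"n_tests must lie in 0..{rule.n_tokens}, got {n_tests}"
        )
    if not correct and rule.forfeit_on_wrong_final_guess:
        return 0.0
    return (rule.n_tokens - n_tests) * rule.token_value


def _choice_distribution(
    policy: PolicySpec,
    belief: frozenset[int],
    singly_tested: frozenset[int],
    n_done: int,
    config: TaskConfig,
) -> dict[frozenset[int], Fraction]:
    """The policy's exact distribution over next on-sets."""
    kind = policy.kind
    if kind == "switcher":
        kind = "test_one" if n_done % 2 == 0 else "split_half"
    if kind == "random":
        switches = sorted(config.all_switches)
        p = Fraction(1, 2 ** config.n_switches)
        out: dict[frozenset[int], Fraction] = {}
        for r in range(config.n_switches + 1):
            for combo in combinations(switches, r):
                out[frozenset(combo)] = p
        return out
    if kind == "test_one":
        pool = config.all_switches - singly_tested
        if not pool:
            pool = belief - singly_tested
        if not pool:
            pool = belief
        p = Fraction(1, len(pool))
        return {frozenset({s}): p for s in pool}
    if kind == "split_half":
        k = _split_half_size(len(belief), policy.rounding)
        subsets = list(combinations(sorted(belief), k))
        p = Fraction(1, len(subsets))
        return {frozenset(c): p for c in subsets}
    # greedy_eig
    options = best_interventions(BeliefState(belief), config)
    p = Fraction(1, len(options))
    return {frozenset(o): p for o in options}


def _revealing_outcome(condition: Condition) -> bool:
    # the outcome that pins the target down directly, not by elimination
    return condition is Condition.SPARSE


def expected_policy_payout(
    policy: PolicySpec,
    config: TaskConfig,
    rule: PayoutRule = PayoutRule(),
    stopping: str = "certainty",
) -> float:
    """Exact expected payout of a policy, in currency units.

    Averages over the uniformly random target and the policy's own
    randomness by dynamic programming; a session that exhausts its tokens
    before identification guesses uniformly from the remaining candidates.
    """
    if stopping not in STOPPING_RULES:
        raise ValueError(f"stopping must be one of {STOPPING_RULES}")
    max_trials = policy.max_trials or config.n_tokens
    value = Fraction(rule.token_value).limit_denominator(10**6)

    @lru_cache(maxsize=None)
    def payout(
        target: int,
        belief: frozenset[int],
        singly: frozenset[int],
        n_done: int,
        revealed: bool,
    ) -> Fraction:
        identified = revealed if stopping == "direct_hit" else len(belief) == 1
        if identified:
            return (rule.n_tokens - n_done) * value
        if n_done >= max_trials:
            # forced guess, uniform over remaining candidates
            win = Fraction(1, len(belief))
            return win * (rule.n_tokens - n_done) * value
        if stopping == "direct_hit" and len(belief) == 1:
            # certain by elimination: pay one direct test on the candidate
            return (rule.n_tokens - n_done - 1) * value
        total = Fraction(0)
        for on, p in _choice_distribution(
            policy, belief, singly, n_done, config
        ).items():
            lights = simulate_outcome(config, target, on)
            new_belief = frozenset(
                h for h in belief if simulate_outcome(config, h, on) == lights
            )
            rev = (
                len(new_belief) == 1
                and lights == _revealing_outcome(config.condition)
            )
            # singly-tested bookkeeping only matters to test_one/switcher
            if policy.kind in ("test_one", "switcher") and len(on) == 1:
                new_singly = singly | on
            else:
                new_singly = singly
            total += p * payout(
                target, new_belief, new_singly, n_done + 1, rev
            )
        return total

    full = config.all_switches
    acc = sum(
        payout(t, full, frozenset(), 0, False) for t in sorted(full)
    )
    return float(acc / config.n_switches)
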