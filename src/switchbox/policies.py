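"""Seeded simulated learners used as baselines for the efficiency analysis.

Four policies:

* ``random`` — every switch independently on with probability .5.
* ``test_one`` — turns on a single switch not yet tested on its own,
  drawn uniformly; falls back to untested *candidates*, then any candidate,
  once all switches have been tried singly.
* ``split_half`` — turns on a uniformly drawn subset of the current
  candidate set of size ceil(|C|/2) (or floor, configurable). In the dense
  condition this operates on the candidate target set, the natural transfer
  of "possibly working" to "possibly broken".
* ``greedy_eig`` — a uniformly drawn maximiser of expected information gain.
* ``switcher`` — alternates a singleton test with a split-half test from
  trial to trial (used to plant "Other"-strategy sessions).

All randomness flows through a :class:`numpy.random.Generator`; per-
participant streams are derived deterministically from (seed, participant
index) so cohorts reproduce byte-identically under one global seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .core import (
    BeliefState,
    Condition,
    ParticipantRecord,
    TaskConfig,
    TrialRecord,
    simulate_outcome,
    update_belief,
)
from .information import best_interventions

POLICY_KINDS = ("random", "test_one", "split_half", "greedy_eig", "switcher")


@dataclass(frozen=True)
class PolicySpec:
    """A simulated learner: which rule, rounding for split-half, seed."""

    kind: str
    rounding: str = "ceil"  # ceil | floor, split-half only
    seed: int = 0
    max_trials: Optional[int] = None  # default: config.n_tokens

    def __post_init__(self) -> None:
        if self.kind not in POLICY_KINDS:
            raise ValueError(f"unknown policy kind {self.kind!r}")
        if self.rounding not in ("ceil", "floor"):
            raise ValueError("rounding must be 'ceil' or 'floor'")
        if self.max_trials is not None and self.max_trials < 1:
            raise ValueError("max_trials must be >= 1")


def participant_rng(seed: int, participant_index: int) -> np.random.Generator:
    """Deterministic per-participant stream from a single global seed."""
    return np.random.default_rng([seed, participant_index])


def _split_half_size(n_candidates: int, rounding: str) -> int:
    half = n_candidates / 2
    k = math.ceil(half) if rounding == "ceil" else math.floor(half)
    return max(1, k)


def _singly_tested(history: Sequence[TrialRecord]) -> frozenset[int]:
    return frozenset(
        next(iter(t.on_set)) for t in history if len(t.on_set) == 1
    )


def _draw_subset(
    rng: np.random.Generator, pool: frozenset[int], k: int
) -> frozenset[int]:
    chosen = rng.choice(sorted(pool), size=k, replace=False)
    return frozenset(int(s) for s in np.atleast_1d(chosen))


def next_intervention(
    policy: PolicySpec,
    belief: BeliefState,
    history: Sequence[TrialRecord],
    config: TaskConfig,
    rng: np.random.Generator,
) -> frozenset[int]:
    """Draw the policy's next on-set given the belief and trial history."""
    kind = policy.kind
    if kind == "switcher":
        # alternate singleton / split-half starting with a singleton
        base = "test_one" if len(history) % 2 == 0 else "split_half"
        return next_intervention(
            replace(policy, kind=base), belief, history, config, rng
        )
    if kind == "random":
        flips = rng.random(config.n_switches) < 0.5
        return frozenset(
            int(s) for s, f in zip(sorted(config.all_switches), flips) if f
        )
    if kind == "test_one":
        pool = config.all_switches - _singly_tested(history)
        if not pool:
            pool = belief.candidates - _singly_tested(history)
        if not pool:
            pool = belief.candidates
        return _draw_subset(rng, pool, 1)
    if kind == "split_half":
        k = _split_half_size(len(belief), policy.rounding)
        return _draw_subset(rng, belief.candidates, k)
    # greedy_eig: uniform over the exact-EIG argmax set
    options = best_interventions(belief, config)
    idx = int(rng.integers(len(options)))
    return options[idx]


def run_policy(
    policy: PolicySpec,
    config: TaskConfig,
    target: int,
    rng: Optional[np.random.Generator] = None,
    stop_at_candidates: int = 1,
) -> list[TrialRecord]:
    """Simulate one full session: choose, pay, observe, update, repeat.

    Stops as soon as at most ``stop_at_candidates`` hypotheses remain or the
    token budget (``max_trials``, default ``config.n_tokens``) is exhausted.
    """
    config.validate_switch(target)
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    max_trials = policy.max_trials or config.n_tokens
    belief = BeliefState.full(config)
    trials: list[TrialRecord] = []
    while len(belief) > stop_at_candidates and len(trials) < max_trials:
        on = next_intervention(policy, belief, trials, config, rng)
        lights = simulate_outcome(config, target, on)
        trials.append(TrialRecord(on, lights))
        belief = update_belief(belief, on, lights, config)
    return trials


def matched_random_cohort(
    participants: Sequence[ParticipantRecord],
    config: TaskConfig,
    seed: int,
) -> list[ParticipantRecord]:
    """Random interveners matched to real participants' trial counts.

    One simulated session per participant: same condition, same hidden
    target, but every intervention drawn by flipping each switch on with
    p = .5 — and exactly as many paid tests as the participant made (no
    early stopping, matching the yoked-baseline design).
    """
    if not participants:
        raise ValueError("participants must be nonempty")
    policy = PolicySpec(kind="random", seed=seed)
    out = []
    for i, part in enumerate(participants):
        cfg = replace(config, condition=Condition(part.condition))
        rng = participant_rng(seed, i)
        trials = []
        for _ in range(part.n_trials):
            on = next_intervention(
                policy, BeliefState.full(cfg), trials, cfg, rng
            )
            trials.append(
                TrialRecord(on, simulate_outcome(cfg, part.target_switch, on))
            )
        out.append(
            ParticipantRecord(
                participant_id=f"rand_{part.participant_id}",
                age_group=part.age_group,
                condition=cfg.condition,
                target_switch=part.target_switch,
                trials=tuple(trials),
                guesses=(),
                payout=0.0,
                planted_strategy="random",
            )
        )
    return out
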