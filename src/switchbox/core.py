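"""Deterministic switch-box environment and ideal-observer belief updating.

The task: a box with ``n_switches`` switches and a bank of lights. In the
*sparse* condition exactly one switch works and the lights come on iff that
switch is among those turned on. In the *dense* condition exactly one switch
is broken and the lights come on iff any working (non-target) switch is on.
The learner pays one token per activation and tries to identify the hidden
target switch.

Because outcomes are deterministic and the prior over targets uniform, the
Bayesian ideal observer reduces to candidate elimination: the belief state is
the set of target hypotheses consistent with every observed (intervention,
outcome) pair, carrying a uniform distribution over that set.

Switch indices are 1-based everywhere in the public API and in file formats,
matching the physical labelling of the box.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence


class Condition(str, Enum):
    """Causal sparsity condition of the box."""

    SPARSE = "sparse"  # one working switch among n
    DENSE = "dense"    # one broken switch among n


class InvalidSwitchError(ValueError):
    """A switch index outside 1..n_switches was supplied."""


class ContradictionError(RuntimeError):
    """Observed evidence is inconsistent with every remaining hypothesis.

    Raised when belief updating would empty the candidate set — impossible
    for logs generated by the deterministic box, so it flags corrupt data.
    """

    def __init__(self, message: str, trial_index: int | None = None):
        super().__init__(message)
        self.trial_index = trial_index


@dataclass(frozen=True)
class TaskConfig:
    """Task parameters: condition, box size and token economy.

    Defaults are the study design: 6 switches, 6 tokens, 0.50 EUR per token.
    """

    condition: Condition
    n_switches: int = 6
    n_tokens: int = 6
    token_value: float = 0.50

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        if self.n_switches < 2:
            raise ValueError("n_switches must be >= 2")
        if self.n_tokens < 1:
            raise ValueError("n_tokens must be >= 1")
        if self.token_value <= 0:
            raise ValueError("token_value must be > 0")

    @property
    def all_switches(self) -> frozenset[int]:
        return frozenset(range(1, self.n_switches + 1))

    def validate_switch(self, s: int) -> None:
        if not (1 <= s <= self.n_switches):
            raise InvalidSwitchError(
                f"switch index {s} outside 1..{self.n_switches}"
            )

    def validate_intervention(self, on_set: Iterable[int]) -> frozenset[int]:
        out = frozenset(on_set)
        for s in out:
            self.validate_switch(int(s))
        return out


@dataclass(frozen=True)
class TrialRecord:
    """One paid activation: the switches turned on and what the lights did."""

    on_set: frozenset[int]
    lights_on: bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "on_set", frozenset(self.on_set))


@dataclass(frozen=True)
class GuessRecord:
    """One (free) verification of a guessed target by the experimenter."""

    guessed_switch: int
    correct: bool


@dataclass(frozen=True)
class ParticipantRecord:
    """One participant's full session: paid tests, guesses and payout.

    ``planted_strategy`` is populated only for synthetic participants and
    names the generating policy; real logs leave it ``None``.
    """

    participant_id: str
    age_group: str
    condition: Condition
    target_switch: int
    trials: tuple[TrialRecord, ...]
    guesses: tuple[GuessRecord, ...] = ()
    payout: float = 0.0
    planted_strategy: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", Condition(self.condition))
        object.__setattr__(self, "trials", tuple(self.trials))
        object.__setattr__(self, "guesses", tuple(self.guesses))

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def first_guess_correct(self) -> bool | None:
        """Correctness of the first guess (the one the payout hinges on)."""
        return self.guesses[0].correct if self.guesses else None


@dataclass(frozen=True)
class BeliefState:
    """Uniform belief over the target hypotheses still in contention."""

    candidates: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "candidates", frozenset(self.candidates))
        if not self.candidates:
            raise ValueError("BeliefState requires a nonempty candidate set")

    @classmethod
    def full(cls, config: TaskConfig) -> "BeliefState":
        return cls(config.all_switches)

    def __len__(self) -> int:
        return len(self.candidates)

    def __contains__(self, switch: int) -> bool:
        return switch in self.candidates

    @property
    def is_certain(self) -> bool:
        return len(self.candidates) == 1

    @property
    def sole_candidate(self) -> int:
        if not self.is_certain:
            raise ValueError("belief is not a singleton")
        return next(iter(self.candidates))


def simulate_outcome(
    config: TaskConfig, target: int, on_set: Iterable[int]
) -> bool:
    """Lights-on outcome for a hidden target under the given intervention.

    sparse: lights on iff the working switch (``target``) is in ``on_set``.
    dense: lights on iff ``on_set`` contains any switch other than the
    broken ``target``.
    """
    config.validate_switch(target)
    on = config.validate_intervention(on_set)
    if config.condition is Condition.SPARSE:
        return target in on
    return any(s != target for s in on)


def update_belief(
    belief: BeliefState,
    on_set: Iterable[int],
    lights_on: bool,
    config: TaskConfig,
    trial_index: int | None = None,
) -> BeliefState:
    """Eliminate every candidate inconsistent with the observed outcome."""
    on = config.validate_intervention(on_set)
    kept = frozenset(
        h for h in belief.candidates
        if simulate_outcome(config, h, on) == lights_on
    )
    if not kept:
        where = "" if trial_index is None else f" at trial {trial_index}"
        raise ContradictionError(
            f"observation (on_set={sorted(on)}, lights_on={lights_on}) "
            f"rules out every remaining candidate{where}",
            trial_index=trial_index,
        )
    return BeliefState(kept)


def candidates_in_contention(
    trials: Sequence[TrialRecord], config: TaskConfig
) -> list[BeliefState]:
    """Belief state *before* each trial of one chronological session.

    The first entry is always the full switch set. Raises
    :class:`ContradictionError` naming the offending trial (1-based) if a
    recorded outcome is impossible.
    """
    beliefs: list[BeliefState] = []
    belief = BeliefState.full(config)
    for i, trial in enumerate(trials, start=1):
        beliefs.append(belief)
        belief = update_belief(
            belief, trial.on_set, trial.lights_on, config, trial_index=i
        )
    return beliefs


def final_belief(
    trials: Sequence[TrialRecord], config: TaskConfig
) -> BeliefState:
    """Belief after integrating a whole session's evidence."""
    belief = BeliefState.full(config)
    for i, trial in enumerate(trials, start=1):
        belief = update_belief(
            belief, trial.on_set, trial.lights_on, config, trial_index=i
        )
    return belief


def entropy(belief: BeliefState) -> float:
    """Shannon entropy (bits) of the uniform belief: log2 |candidates|."""
    return math.log2(len(belief))
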