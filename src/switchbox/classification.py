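"""Session-level strategy taxonomy and information-optimality flags.

Classification looks only at *eligible* trials — those performed while at
least four target hypotheses were still in contention, the window in which
testing multiple switches at once genuinely beats single-switch testing in
the sparse condition:

* ``test_one`` — every eligible test turned on exactly one switch;
* ``test_multiple`` — every eligible test turned on more than one;
* ``other`` — a mix of the two;
* ``unclassifiable`` — the session has no eligible trial (excluded from
  strategy tables).

The information-optimality flag has two modes. ``rule`` encodes the ideal
pattern stated for each condition: in sparse, a first eligible test of 2-4
switches followed by tests of half (floor or ceil) of the switches still in
contention; in dense, a fresh single switch with every eligible test.
``strict_eig`` demands every eligible trial attain the maximum expected
information gain exactly — a strictly stronger criterion in sparse, where
2- and 4-switch first tests satisfy the rule at 0.918 < 1.0 bits.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .core import (
    BeliefState,
    Condition,
    GuessRecord,
    ParticipantRecord,
    TaskConfig,
    TrialRecord,
    candidates_in_contention,
    update_belief,
)
from .information import best_intervention_value, expected_information_gain

ELIGIBILITY_MIN_CANDIDATES = 4


@dataclass(frozen=True)
class StrategyLabel:
    """Outcome of classifying one session."""

    label: str  # test_one | test_multiple | other | unclassifiable
    info_optimal: bool
    n_eligible_trials: int


@dataclass(frozen=True)
class SessionFlags:
    """Documented approximations of session-quality flags."""

    early_stop: bool
    unnecessary_tests: bool


def _eligible_pairs(
    trials: Sequence[TrialRecord], config: TaskConfig
) -> list[tuple[BeliefState, TrialRecord]]:
    beliefs = candidates_in_contention(trials, config)
    return [
        (b, t)
        for b, t in zip(beliefs, trials)
        if len(b) >= ELIGIBILITY_MIN_CANDIDATES
    ]


def eligible_trials(
    trials: Sequence[TrialRecord], config: TaskConfig
) -> list[TrialRecord]:
    """Trials whose pre-trial candidate set still held >= 4 switches."""
    return [t for _, t in _eligible_pairs(trials, config)]


def is_information_optimal(
    trials: Sequence[TrialRecord],
    config: TaskConfig,
    mode: str = "rule",
) -> bool:
    """Whether a session's eligible tests follow the ideal pattern.

    ``mode='rule'`` applies the per-condition ideal described above;
    ``mode='strict_eig'`` requires exact EIG-maximisation on every eligible
    trial.
    """
    if mode not in ("rule", "strict_eig"):
        raise ValueError("mode must be 'rule' or 'strict_eig'")
    pairs = _eligible_pairs(trials, config)
    if not pairs:
        return False
    if mode == "strict_eig":
        tol = 1e-12
        return all(
            expected_information_gain(b, t.on_set, config)
            >= best_intervention_value(b, config) - tol
            for b, t in pairs
        )
    if config.condition is Condition.SPARSE:
        first_belief, first_trial = pairs[0]
        if not (2 <= len(first_trial.on_set) <= 4):
            return False
        for belief, trial in pairs[1:]:
            m = len(belief)
            k = len(trial.on_set & belief.candidates)
            if k not in (m // 2, (m + 1) // 2):
                return False
        return True
    # dense: each eligible test is one switch never turned on before
    seen: set[int] = set()
    all_beliefs = candidates_in_contention(trials, config)
    for belief, trial in zip(all_beliefs, trials):
        if len(belief) >= ELIGIBILITY_MIN_CANDIDATES:
            if len(trial.on_set) != 1 or (trial.on_set & seen):
                return False
        seen |= trial.on_set
    return True


def classify_strategy(
    trials: Sequence[TrialRecord],
    config: TaskConfig,
    optimality_mode: str = "rule",
) -> StrategyLabel:
    """Classify one session from its eligible trials."""
    pairs = _eligible_pairs(trials, config)
    if not pairs:
        return StrategyLabel("unclassifiable", False, 0)
    sizes = [len(t.on_set) for _, t in pairs]
    if all(s == 1 for s in sizes):
        label = "test_one"
    elif all(s > 1 for s in sizes):
        label = "test_multiple"
    else:
        label = "other"
    return StrategyLabel(
        label,
        is_information_optimal(trials, config, mode=optimality_mode),
        len(pairs),
    )


def first_intervention_summary(
    cohort: Sequence[ParticipantRecord],
) -> pd.DataFrame:
    """Counts and percentages of first tests of one vs multiple switches.

    One row per (age_group, condition) cell, mirroring the standard
    first-intervention cross-tabulation.
    """
    rows = []
    for part in cohort:
        if not part.trials:
            raise ValueError(
                f"participant {part.participant_id} has no trials"
            )
        rows.append(
            {
                "age_group": part.age_group,
                "condition": Condition(part.condition).value,
                "first_multiple": len(part.trials[0].on_set) > 1,
            }
        )
    df = pd.DataFrame(rows)
    grouped = df.groupby(["age_group", "condition"], sort=True)
    out = grouped["first_multiple"].agg(
        n="count", test_multiple="sum"
    ).reset_index()
    out["test_one"] = out["n"] - out["test_multiple"]
    out["pct_test_one"] = 100.0 * out["test_one"] / out["n"]
    out["pct_test_multiple"] = 100.0 * out["test_multiple"] / out["n"]
    return out[
        [
            "age_group",
            "condition",
            "n",
            "test_one",
            "pct_test_one",
            "test_multiple",
            "pct_test_multiple",
        ]
    ]


def flag_session_anomalies(
    trials: Sequence[TrialRecord],
    guesses: Sequence[GuessRecord],
    config: TaskConfig,
) -> SessionFlags:
    """Approximate early-stopping and unnecessary-test flags.

    ``early_stop``: the first guess was made while two or more candidates
    remained. ``unnecessary_tests``: some paid test was made when nothing
    could be learned (best attainable EIG zero, e.g. after certainty) or
    learned nothing despite information being available (chosen EIG zero).
    """
    belief = BeliefState.full(config)
    unnecessary = False
    for trial in trials:
        best = best_intervention_value(belief, config)
        chosen = expected_information_gain(belief, trial.on_set, config)
        if best <= 0.0 or chosen <= 0.0:
            unnecessary = True
        belief = update_belief(belief, trial.on_set, trial.lights_on, config)
    early = bool(guesses) and len(belief) >= 2
    return SessionFlags(early_stop=early, unnecessary_tests=unnecessary)
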