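"""Expected information gain (EIG) of interventions and the efficiency metric.

EIG of an intervention is the prior entropy of the belief minus the
expected posterior entropy, with outcome probabilities induced by the
uniform belief and the deterministic outcome rule:

    EIG(a) = H(B) - sum_o P(o | a, B) * H(B | a, o)

Since the box is deterministic with a uniform belief over ``m`` candidates,
an intervention partitions the candidates into the subset predicting
lights-on (size ``k``) and lights-off (size ``m - k``), and

    EIG = log2 m - (k/m) log2 k - ((m-k)/m) log2 (m-k),   0 log 0 = 0.

Efficiency of a chosen intervention is its EIG as a proportion of the best
EIG attainable at that belief; trials where nothing can be learned (best
EIG = 0) have undefined efficiency and are excluded from averages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Iterable, Optional, Sequence

from .core import (
    BeliefState,
    TaskConfig,
    TrialRecord,
    entropy,
    simulate_outcome,
    update_belief,
)

_ENUMERATION_GUARD = 16


@dataclass(frozen=True)
class InterventionValue:
    """An intervention paired with its exact EIG in bits."""

    on_set: frozenset[int]
    eig: float


def expected_information_gain(
    belief: BeliefState, on_set: Iterable[int], config: TaskConfig
) -> float:
    on = config.validate_intervention(on_set)
    m = len(belief)
    k = sum(
        1 for h in belief.candidates if simulate_outcome(config, h, on)
    )
    if k == 0 or k == m:  # outcome certain under the belief
        return 0.0
    h_post = (k / m) * math.log2(k) + ((m - k) / m) * math.log2(m - k)
    return math.log2(m) - h_post


def enumerate_intervention_values(
    belief: BeliefState, config: TaskConfig
) -> list[InterventionValue]:
    """Exact EIG of every nonempty on-set (brute force; n_switches <= 16)."""
    n = config.n_switches
    if n > _ENUMERATION_GUARD:
        raise ValueError(
            f"enumeration over 2^{n}-1 interventions refused (n > "
            f"{_ENUMERATION_GUARD})"
        )
    switches = sorted(config.all_switches)
    out = []
    for r in range(1, n + 1):
        for combo in combinations(switches, r):
            on = frozenset(combo)
            out.append(
                InterventionValue(on, expected_information_gain(belief, on, config))
            )
    return out


def best_intervention_value(
    belief: BeliefState, config: TaskConfig
) -> float:
    """Maximum EIG over all nonempty interventions at this belief."""
    if belief.is_certain:
        return 0.0
    return max(
        iv.eig for iv in enumerate_intervention_values(belief, config)
    )


def best_interventions(
    belief: BeliefState, config: TaskConfig, tol: float = 1e-12
) -> list[frozenset[int]]:
    """All nonempty on-sets attaining the maximum EIG (within ``tol``)."""
    values = enumerate_intervention_values(belief, config)
    best = max(iv.eig for iv in values)
    return [iv.on_set for iv in values if iv.eig >= best - tol]


def efficiency_of_choice(
    belief: BeliefState, on_set: Iterable[int], config: TaskConfig
) -> Optional[float]:
    """Chosen EIG / best attainable EIG, or ``None`` when best = 0."""
    best = best_intervention_value(belief, config)
    if best <= 0.0:
        return None
    return expected_information_gain(belief, on_set, config) / best


@dataclass(frozen=True)
class EfficiencyScore:
    """Per-trial efficiencies of one session and their mean.

    ``per_trial`` holds ``None`` for trials with undefined efficiency;
    ``participant_mean`` is ``None`` when no trial was defined.
    """

    per_trial: tuple[Optional[float], ...]
    participant_mean: Optional[float]


def participant_efficiency(
    trials: Sequence[TrialRecord], config: TaskConfig
) -> EfficiencyScore:
    """Efficiency of each trial against the true (fully integrated) posterior.

    The benchmark at every step is the step-wise optimal learner that has
    accurately integrated all the participant's previous evidence.
    """
    belief = BeliefState.full(config)
    per_trial: list[Optional[float]] = []
    for i, trial in enumerate(trials, start=1):
        per_trial.append(efficiency_of_choice(belief, trial.on_set, config))
        belief = update_belief(
            belief, trial.on_set, trial.lights_on, config, trial_index=i
        )
    defined = [e for e in per_trial if e is not None]
    mean = sum(defined) / len(defined) if defined else None
    return EfficiencyScore(tuple(per_trial), mean)
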