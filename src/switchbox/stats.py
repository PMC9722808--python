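"""Exact 2x2 contingency inference, bootstrap CIs and Fisher power simulation.

The two-sided Fisher exact p-value follows the dominant software
convention: the sum of hypergeometric probabilities of all tables sharing
the observed margins whose probability does not exceed the observed
table's. The power simulation draws group success counts binomially and
reports the rejection fraction with its Monte-Carlo standard error —
the sample-size planning tool for designs comparing two strategy-use
proportions (e.g. 25 per group for a 40-point difference at alpha .05).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .core import ParticipantRecord


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts [[a, b], [c, d]]: rows = groups, columns = success/failure."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("counts must be non-negative")
        if self.a + self.b + self.c + self.d == 0:
            raise ValueError("table is empty")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


@dataclass(frozen=True)
class PowerDesign:
    """A two-group binomial design evaluated by the Fisher exact test."""

    n_per_group: int
    p1: float
    p2: float
    alpha: float = 0.05
    replicates: int = 5000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.p1 <= 1 and 0 <= self.p2 <= 1):
            raise ValueError("p1, p2 must lie in [0, 1]")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_per_group < 1 or self.replicates < 1:
            raise ValueError("n_per_group and replicates must be >= 1")


@dataclass(frozen=True)
class PowerEstimate:
    power: float
    se: float
    replicates: int


def fisher_exact_two_sided(table: ContingencyTable2x2) -> float:
    """Two-sided Fisher exact p-value of a 2x2 table."""
    arr = table.as_array()
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("a margin of the table is zero; p-value undefined")
    return float(sps.fisher_exact(arr, alternative="two-sided")[1])


def fisher_power_simulation(design: PowerDesign) -> PowerEstimate:
    """Monte-Carlo power of the two-sided Fisher test under a design.

    Success counts are drawn Binomial(n, p1) and Binomial(n, p2) per
    replicate; power is the fraction of replicates with p < alpha.
    Identical (x1, x2) draws share one p-value computation.
    """
    rng = np.random.default_rng(design.seed)
    n = design.n_per_group
    x1 = rng.binomial(n, design.p1, size=design.replicates)
    x2 = rng.binomial(n, design.p2, size=design.replicates)
    pairs, counts = np.unique(
        np.stack([x1, x2], axis=1), axis=0, return_counts=True
    )
    rejected = 0
    for (a, c), mult in zip(pairs, counts):
        table = ContingencyTable2x2(int(a), n - int(a), int(c), n - int(c))
        try:
            p = fisher_exact_two_sided(table)
        except ValueError:  # degenerate margin: never significant
            p = 1.0
        if p < design.alpha:
            rejected += int(mult)
    power = rejected / design.replicates
    se = float(np.sqrt(power * (1 - power) / design.replicates))
    return PowerEstimate(power=power, se=se, replicates=design.replicates)


def bootstrap_mean_ci(
    values: Sequence[float],
    level: float = 0.95,
    resamples: int = 2000,
    seed: int = 0,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("values must be nonempty")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(resamples, arr.size))
    means = arr[idx].mean(axis=1)
    lo, hi = np.quantile(means, [(1 - level) / 2, (1 + level) / 2])
    return float(lo), float(hi)


def proportion_table(
    cohort: Sequence[ParticipantRecord],
    strategy_labels: Sequence[str],
    restrict_to: str,
    group_field: str = "age_group",
    group_order: Optional[Sequence[str]] = None,
) -> ContingencyTable2x2:
    """2x2 table of group x first-guess-correct within one strategy class.

    ``strategy_labels`` pairs with ``cohort`` (one label per participant);
    only participants labelled ``restrict_to`` enter the table. Rows follow
    ``group_order`` (default: sorted distinct group values); a row with zero
    total triggers a degenerate-table warning via ``UserWarning``.
    """
    if len(cohort) != len(strategy_labels):
        raise ValueError("one strategy label per participant required")
    kept = [
        p for p, lab in zip(cohort, strategy_labels) if lab == restrict_to
    ]
    if not kept:
        raise ValueError(f"no participants labelled {restrict_to!r}")
    groups = sorted({getattr(p, group_field) for p in kept})
    if group_order is not None:
        groups = list(group_order)
    if len(groups) != 2:
        import warnings

        warnings.warn(
            f"expected two groups, found {groups}: degenerate table",
            UserWarning,
            stacklevel=2,
        )
        groups = (groups + [None, None])[:2]
    counts = {g: [0, 0] for g in groups}
    for p in kept:
        g = getattr(p, group_field)
        if g not in counts:
            continue
        correct = bool(p.first_guess_correct)
        counts[g][0 if correct else 1] += 1
    (a, b), (c, d) = counts[groups[0]], counts[groups[1]]
    return ContingencyTable2x2(a, b, c, d)
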