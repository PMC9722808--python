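"""Exact contingency inference, power simulation and bootstrap CIs.

The Fisher oracle below enumerates the hypergeometric distribution over
all tables sharing the observed margins from scratch (math.comb only) and
sums the probabilities not exceeding the observed table's — independent of
the library's implementation route.
"""

import math

import numpy as np
import pytest

from switchbox import (
    Condition,
    GuessRecord,
    ParticipantRecord,
    TrialRecord,
)
from switchbox.stats import (
    ContingencyTable2x2,
    PowerDesign,
    bootstrap_mean_ci,
    fisher_exact_two_sided,
    fisher_power_simulation,
    proportion_table,
)


def oracle_fisher_two_sided(a, b, c, d):
    row1, row2 = a + b, c + d
    col1 = a + c
    total = row1 + row2

    def prob(x):  # table [[x, row1-x], [col1-x, row2-col1+x]]
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(total, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = prob(a)
    return sum(
        prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9)
    )


@pytest.mark.parametrize(
    "table,expected",
    [
        ((15, 0, 2, 4), 0.0025),   # 15/15 vs 2/6 accuracy comparison
        ((5, 5, 5, 5), 1.0),       # modal table
        ((17, 2, 3, 4), 0.0278),   # 17/19 vs 3/7 accuracy comparison
    ],
)
def test_fisher_two_sided_frozen(table, expected):
    a, b, c, d = table
    p = fisher_exact_two_sided(ContingencyTable2x2(a, b, c, d))
    assert p == pytest.approx(expected, abs=5e-5)
    assert p == pytest.approx(oracle_fisher_two_sided(a, b, c, d), rel=1e-9)


def test_fisher_matches_oracle_on_grid():
    for a in range(0, 8, 2):
        for b in range(1, 8, 3):
            for c in range(1, 8, 3):
                for d in range(0, 8, 2):
                    got = fisher_exact_two_sided(
                        ContingencyTable2x2(a, b, c, d)
                    )
                    assert got == pytest.approx(
                        oracle_fisher_two_sided(a, b, c, d), rel=1e-9
                    )


def test_fisher_rejects_zero_margin():
    with pytest.raises(ValueError):
        fisher_exact_two_sided(ContingencyTable2x2(0, 0, 3, 4))


def test_hypergeometric_probabilities_sum_to_one():
    a, b, c, d = 7, 3, 2, 8
    row1, row2, col1 = a + b, c + d, a + c
    total = row1 + row2
    lo, hi = max(0, col1 - row2), min(col1, row1)
    s = sum(
        math.comb(row1, x) * math.comb(row2, col1 - x) / math.comb(total, col1)
        for x in range(lo, hi + 1)
    )
    assert s == pytest.approx(1.0, abs=1e-12)


def test_power_null_controls_type_one():
    est = fisher_power_simulation(
        PowerDesign(n_per_group=25, p1=0.5, p2=0.5, replicates=3000, seed=9)
    )
    assert est.power <= 0.05 + 3 * max(est.se, 1e-3)


def test_power_extremes_and_target():
    sure = fisher_power_simulation(
        PowerDesign(n_per_group=25, p1=0.0, p2=1.0, replicates=500, seed=1)
    )
    assert sure.power == pytest.approx(1.0)
    planned = fisher_power_simulation(
        PowerDesign(n_per_group=25, p1=0.3, p2=0.7, replicates=4000, seed=1)
    )
    assert 0.70 <= planned.power <= 0.88  # exact value is 0.782


def test_power_monotone_in_effect_and_n():
    base = dict(alpha=0.05, replicates=2500, seed=4)
    by_gap = [
        fisher_power_simulation(
            PowerDesign(n_per_group=25, p1=0.5 - g, p2=0.5 + g, **base)
        ).power
        for g in (0.05, 0.15, 0.25)
    ]
    assert by_gap == sorted(by_gap)
    by_n = [
        fisher_power_simulation(
            PowerDesign(n_per_group=n, p1=0.3, p2=0.7, **base)
        ).power
        for n in (10, 25, 50)
    ]
    assert by_n == sorted(by_n)


def test_power_reproducible_under_seed():
    d = PowerDesign(n_per_group=25, p1=0.3, p2=0.7, replicates=1000, seed=77)
    assert fisher_power_simulation(d) == fisher_power_simulation(d)


def test_bootstrap_ci_basics():
    lo, hi = bootstrap_mean_ci([0.7, 0.7, 0.7], seed=0)
    assert lo == pytest.approx(0.7) and hi == pytest.approx(0.7)
    vals = [0.2, 0.5, 0.9, 0.4, 0.6, 0.3, 0.8]
    lo, hi = bootstrap_mean_ci(vals, seed=1)
    assert lo <= np.mean(vals) <= hi
    with pytest.raises(ValueError):
        bootstrap_mean_ci([], seed=0)
    a = bootstrap_mean_ci(vals, seed=5)
    assert a == bootstrap_mean_ci(vals, seed=5)


def test_bootstrap_coverage_on_gaussian():
    """Percentile-interval coverage close to nominal on Gaussian samples."""
    rng = np.random.default_rng(123)
    level, n, experiments = 0.90, 50, 1000
    hits = 0
    for i in range(experiments):
        sample = rng.normal(0.0, 1.0, size=n)
        lo, hi = bootstrap_mean_ci(sample, level=level, resamples=500, seed=i)
        hits += lo <= 0.0 <= hi
    coverage = hits / experiments
    se = math.sqrt(level * (1 - level) / experiments)
    # percentile intervals under-cover slightly at finite n; allow 3 SE
    # around nominal plus that small-sample bias
    assert abs(coverage - level) <= 3 * se + 0.02


def _labelled_participant(pid, age, correct):
    return ParticipantRecord(
        pid, age, Condition.SPARSE, 6,
        (TrialRecord(frozenset({1, 2}), False),),
        (GuessRecord(6 if correct else 1, correct),),
    )


def test_proportion_table_round_trip():
    cohort, labels = [], []
    for i in range(10):
        age = "older" if i < 6 else "younger"
        correct = i % 2 == 0
        cohort.append(_labelled_participant(f"p{i}", age, correct))
        labels.append("test_multiple")
    table = proportion_table(cohort, labels, restrict_to="test_multiple")
    assert (table.a, table.b, table.c, table.d) == (3, 3, 2, 2)
    assert table.a + table.b + table.c + table.d == len(cohort)


def test_proportion_table_degenerate_group_warns():
    cohort = [_labelled_participant("p0", "older", True)]
    with pytest.warns(UserWarning, match="degenerate"):
        table = proportion_table(cohort, ["test_multiple"], "test_multiple")
    assert (table.c, table.d) == (0, 0)
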