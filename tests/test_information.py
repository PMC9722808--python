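"""EIG, the optimal-learner benchmark and the efficiency statistic.

The oracle here recomputes EIG from first principles — enumerate the two
outcomes, split the candidate set by predicted outcome, weight posterior
entropies — independently of the library's formula.
"""

import math
from itertools import chain, combinations

import pytest

from switchbox import (
    BeliefState,
    Condition,
    TaskConfig,
    TrialRecord,
    best_intervention_value,
    best_interventions,
    efficiency_of_choice,
    entropy,
    enumerate_intervention_values,
    expected_information_gain,
    participant_efficiency,
    simulate_outcome,
)


def oracle_eig(belief, on_set, cfg):
    m = len(belief.candidates)
    h_prior = math.log2(m)
    h_post = 0.0
    for outcome in (True, False):
        sub = [
            h for h in belief.candidates
            if simulate_outcome(cfg, h, on_set) == outcome
        ]
        if sub:
            h_post += (len(sub) / m) * math.log2(len(sub))
    return h_prior - h_post


def all_beliefs(n, min_size=1):
    switches = range(1, n + 1)
    return [
        frozenset(c)
        for r in range(min_size, n + 1)
        for c in combinations(switches, r)
    ]


def nonempty_subsets(n):
    switches = range(1, n + 1)
    return chain.from_iterable(
        combinations(switches, r) for r in range(1, n + 1)
    )


@pytest.mark.parametrize(
    "condition,on_set,expected",
    [
        ("sparse", {1, 2, 3}, 1.0),                        # log2 6 - log2 3
        ("sparse", {1}, math.log2(6) - (5 / 6) * math.log2(5)),
        ("dense", {1, 2}, 0.0),                            # opaque
    ],
)
def test_eig_frozen_examples(condition, on_set, expected):
    cfg = TaskConfig(condition=condition)
    belief = BeliefState.full(cfg)
    got = expected_information_gain(belief, on_set, cfg)
    assert got == pytest.approx(expected, abs=1e-9)
    assert got == pytest.approx(oracle_eig(belief, on_set, cfg), abs=1e-12)


def test_eig_zero_when_certain(sparse, dense):
    for cfg in (sparse, dense):
        solved = BeliefState(frozenset({3}))
        assert expected_information_gain(solved, {1, 3}, cfg) == 0.0


def test_eig_matches_oracle_everywhere():
    """Exact agreement with the first-principles oracle over every belief
    and every intervention, both conditions, n = 6 and n = 8."""
    for n in (6, 8):
        for condition in (Condition.SPARSE, Condition.DENSE):
            cfg = TaskConfig(condition=condition, n_switches=n)
            for cands in all_beliefs(n, min_size=1):
                belief = BeliefState(cands)
                for on in nonempty_subsets(n):
                    on = frozenset(on)
                    got = expected_information_gain(belief, on, cfg)
                    want = oracle_eig(belief, on, cfg)
                    assert got == pytest.approx(want, abs=1e-12)
                    assert -1e-12 <= got <= entropy(belief) + 1e-12


def test_enumeration_and_best(sparse, dense):
    full_sparse = BeliefState.full(sparse)
    values = enumerate_intervention_values(full_sparse, sparse)
    assert len(values) == 63  # 2^6 - 1 nonempty on-sets
    assert max(v.eig for v in values) == pytest.approx(1.0)
    assert best_intervention_value(full_sparse, sparse) == pytest.approx(1.0)

    full_dense = BeliefState.full(dense)
    dense_vals = enumerate_intervention_values(full_dense, dense)
    informative = [v for v in dense_vals if v.eig > 1e-12]
    assert len(informative) == 6
    assert all(len(v.on_set) == 1 for v in informative)
    assert best_intervention_value(full_dense, dense) == pytest.approx(
        math.log2(6) - (5 / 6) * math.log2(5)
    )
    assert best_intervention_value(BeliefState(frozenset({2})), sparse) == 0.0


def test_enumeration_guard():
    cfg = TaskConfig(condition="sparse", n_switches=17)
    with pytest.raises(ValueError, match="enumeration"):
        enumerate_intervention_values(BeliefState.full(cfg), cfg)


def test_split_half_argmax_sparse():
    """For every candidate-set size 2..8 the EIG-maximising interventions
    are exactly those splitting the candidates as evenly as possible."""
    n = 8
    cfg = TaskConfig(condition=Condition.SPARSE, n_switches=n)
    for size in range(2, n + 1):
        cands = frozenset(range(1, size + 1))
        belief = BeliefState(cands)
        lo, hi = size // 2, (size + 1) // 2
        argmax = {frozenset(s) for s in best_interventions(belief, cfg)}
        for on in nonempty_subsets(n):
            on = frozenset(on)
            k = len(on & cands)
            assert (on in argmax) == (k in (lo, hi) and 0 < k < size)


def test_dense_singleton_informativeness():
    """With >= 3 dense candidates, EIG > 0 iff the on-set is one single
    still-candidate switch (exhaustive at n = 6)."""
    cfg = TaskConfig(condition=Condition.DENSE)
    for cands in all_beliefs(6, min_size=3):
        belief = BeliefState(cands)
        for on in nonempty_subsets(6):
            on = frozenset(on)
            informative = (
                expected_information_gain(belief, on, cfg) > 1e-12
            )
            assert informative == (len(on) == 1 and on <= cands)


def test_efficiency_of_choice(sparse, dense):
    full = BeliefState.full(sparse)
    one = expected_information_gain(full, {1}, sparse)
    assert efficiency_of_choice(full, {1}, sparse) == pytest.approx(one)
    assert efficiency_of_choice(full, {1, 2, 3}, sparse) == pytest.approx(1.0)
    # nothing left to learn -> undefined
    assert efficiency_of_choice(BeliefState(frozenset({6})), {1}, dense) is None


def test_participant_efficiency(sparse):
    # all-optimal session
    trials = [
        TrialRecord(frozenset({1, 2, 3}), False),
        TrialRecord(frozenset({4}), True),
    ]
    score = participant_efficiency(trials, sparse)
    assert score.participant_mean == pytest.approx(1.0)
    # a single suboptimal singleton from the full set
    score = participant_efficiency([TrialRecord(frozenset({1}), False)], sparse)
    assert score.participant_mean == pytest.approx(
        math.log2(6) - (5 / 6) * math.log2(5)
    )
    # solved box: any further test has undefined efficiency
    trials = [
        TrialRecord(frozenset({1, 2, 3}), True),
        TrialRecord(frozenset({1}), True),   # belief -> {1}
        TrialRecord(frozenset({1}), True),   # nothing learnable
    ]
    score = participant_efficiency(trials, sparse)
    assert score.per_trial[2] is None
    assert score.participant_mean == pytest.approx(1.0)
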