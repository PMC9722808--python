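"""Classifying intervention sequences into test-one / test-multiple / other."""

from switchbox import TaskConfig, TrialRecord, classify_strategy

sparse = TaskConfig(condition="sparse")
T = lambda on, lit: TrialRecord(frozenset(on), lit)

sessions = {
    "halver":   [T({1, 2, 3}, True), T({1}, False), T({2}, True)],
    "one-by-one": [T({1}, False), T({2}, False), T({3}, True)],
    "switcher": [T({4}, False), T({1, 2, 3}, True), T({1}, True)],
}
for name, trials in sessions.items():
    lab = classify_strategy(trials, sparse)
    print(f"{name:<10} -> {lab.label:<13} "
          f"(eligible trials: {lab.n_eligible_trials}, "
          f"information-optimal: {lab.info_optimal})")
# Only trials with >= 4 switches still in contention count; the halver is
# additionally flagged ideal because it opens with 2-4 switches and then
# always splits the remaining candidates in half.
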