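"""Candidate elimination on the switch box: how evidence narrows beliefs."""

from switchbox import (BeliefState, TaskConfig, TrialRecord,
                       candidates_in_contention, entropy, update_belief)

sparse = TaskConfig(condition="sparse")
belief = BeliefState.full(sparse)
print(f"start: candidates {sorted(belief.candidates)}, "
      f"{entropy(belief):.3f} bits of uncertainty")

belief = update_belief(belief, {1, 2, 3}, lights_on=True, config=sparse)
print(f"after 1,2,3 -> lights ON : {sorted(belief.candidates)} "
      f"({entropy(belief):.3f} bits)")
belief = update_belief(belief, {1}, lights_on=False, config=sparse)
print(f"after 1     -> lights OFF: {sorted(belief.candidates)} "
      f"({entropy(belief):.3f} bits)")
# The working switch must be among {1,2,3} (lights came on) but is not 1.

dense = TaskConfig(condition="dense")
trials = [TrialRecord(frozenset({1}), True),
          TrialRecord(frozenset({2}), True),
          TrialRecord(frozenset({3}), False)]
pre = candidates_in_contention(trials, dense)
print("dense single-switch tests, candidates before each trial:",
      [sorted(b.candidates) for b in pre])
# Each lights-on singleton proves that switch works; 3 -> OFF pins the
# broken switch directly.
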