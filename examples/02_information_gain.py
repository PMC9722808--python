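"""EIG of interventions and why split-half rules sparse but fails dense."""

from switchbox import (BeliefState, TaskConfig, best_intervention_value,
                       efficiency_of_choice, expected_information_gain)

for condition in ("sparse", "dense"):
    cfg = TaskConfig(condition=condition)
    full = BeliefState.full(cfg)
    print(f"--- {condition}: 6 candidates, 2.585 bits ---")
    for on in ({1}, {1, 2}, {1, 2, 3}, {1, 2, 3, 4, 5}):
        eig = expected_information_gain(full, on, cfg)
        print(f"  turn on {sorted(on)}: EIG = {eig:.3f} bits")
    best = best_intervention_value(full, cfg)
    eff = efficiency_of_choice(full, {1}, cfg)
    print(f"  best available = {best:.3f} bits; "
          f"efficiency of testing one switch = {eff:.3f}")
# Sparse: the 3-switch half-split earns a full bit, the optimum; dense:
# only singletons are informative, so testing one switch is optimal there.
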