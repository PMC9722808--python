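"""Exact expected returns of search policies under the token economy."""

from switchbox import PayoutRule, PolicySpec, TaskConfig, realized_payout
from switchbox.economics import expected_policy_payout

rule = PayoutRule()  # 6 tokens x EUR 0.50, forfeited on a wrong answer
print(f"max reward (1 lucky test): {realized_payout(1, True, rule):.2f} EUR")

for kind, condition, stopping in [
    ("test_one", "dense", "direct_hit"),
    ("test_one", "dense", "certainty"),
    ("split_half", "sparse", "certainty"),
    ("split_half", "sparse", "direct_hit"),
    ("random", "dense", "certainty"),
]:
    cfg = TaskConfig(condition=condition)
    v = expected_policy_payout(PolicySpec(kind=kind), cfg, rule, stopping)
    print(f"{kind:<10} {condition:<6} {stopping:<10} -> {v:.4f} EUR")
# Exact expectations over the 6 equally likely targets (no Monte-Carlo).
# direct_hit pays until a test observes the target itself; certainty stops
# as soon as elimination leaves one candidate. One switch at a time in
# dense under direct_hit gives the canonical 1.25 EUR.
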