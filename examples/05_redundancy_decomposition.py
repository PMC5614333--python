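"""Redundant versus synergistic population codes, told apart by the pipeline.

Two constructed populations: in one, both neurons track the same food
gradient (each alone nearly suffices — redundant); in the other, food state
is written only in the sign of the inter-neuron correlation (neither alone
carries anything — synergistic).  Redundancy = sum of marginal informations
minus joint information; its sign labels the strategy.
"""

from wormcode import decompose_records, simulate_expression
from wormcode.synthetic import redundant_config, synergistic_config

for name, cfg in (("shared-gradient", redundant_config(seed=0)),
                  ("correlation-coded", synergistic_config(seed=0))):
    records = simulate_expression(cfg)
    dec = decompose_records(records, gs=15, seed=0)
    print(f"{name} population ({cfg.n_states} states x {cfg.n_per_state} worms):")
    print(f"  I_joint      = {dec.I_joint:+.3f} bits")
    print(f"  sum I_N      = {sum(dec.I_marginal):+.3f} bits  "
          f"({', '.join(f'{i:.3f}' for i in dec.I_marginal)})")
    print(f"  I_shuffle    = {dec.I_shuffle:+.3f} bits")
    print(f"  redundancy   = {dec.redundancy:+.3f} bits -> {dec.label}")
    print(f"  signal corr  = {dec.signal_corr:+.3f} bits, "
          f"noise corr = {dec.noise_corr:+.3f} bits")
    print()

print("Positive redundancy: the parts repeat each other.  Negative: the joint\n"
      "response carries more than its parts — information lives in their\n"
      "co-variation, which the shuffle surrogate destroys.")
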