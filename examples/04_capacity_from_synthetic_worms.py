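"""Channel capacity of a synthetic six-food-level, three-neuron population.

Simulates worms whose log-normal expression distributions shift with food
level, estimates per-condition grid densities, and runs Blahut-Arimoto to
find how many bits the three readouts jointly encode about food — compared
against the Monte-Carlo oracle that knows the true distributions.
"""

import numpy as np

from wormcode import capacity_from_records, oracle_mi, simulate_expression
from wormcode.synthetic import default_coding_config

seed = 1
cfg = default_coding_config(n_per_state=300, seed=seed)
records = simulate_expression(cfg)
print(f"simulated {len(records)} worms: {cfg.n_states} food levels x "
      f"{cfg.n_per_state}, readouts {', '.join(cfg.readouts)}")

res = capacity_from_records(records, gs=20, seed=seed)
print(f"\nestimated channel capacity: {res.capacity:.3f} bits "
      f"(max possible log2(6) = {np.log2(6):.3f})")
print("capacity-achieving input p*(f):")
for s, p in zip(cfg.states, res.p_star):
    print(f"  food {s:>8}: {p:.3f}")

truth, se = oracle_mi(cfg, p_in=res.p_star, seed=seed)
print(f"\noracle MI at p* (true distributions): {truth:.3f} +/- {se:.3f} bits")
print("\nThe capacity says how finely downstream physiology could in principle\n"
      "distinguish food levels from these three expression readouts alone;\n"
      "p* concentrates on the food levels the code separates best.")
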