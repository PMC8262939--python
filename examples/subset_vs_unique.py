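"""RM-set identity decides coexistence: nested vs disjoint RM complements.

Memory-model communities with three RM levels (m_v = 0.75).  When every
host's RM set nests the previous one ("subset"), phage methylated by the
top host evade all lower hosts' defenses and competitively exclude them at
high nutrient supply.  When the sets are pairwise disjoint ("unique"),
every host keeps a private defense and nearly all populations coexist.
"""

import numpy as np

from rmeco import ModelParams, build_community, classify_outcome, sweep_supply

grid = np.logspace(3, 9, 9)
params = ModelParams().with_(m_v=0.75)

for arrangement in ("subset", "unique"):
    hosts, phages = build_community(3, arrangement, "memory")
    sw = sweep_supply("memory", hosts, phages, params, grid)
    print(f"\n{arrangement} arrangement:")
    print(f"{'S':>10} {'1-RM':>11} {'2-RM':>11} {'3-RM':>11}  outcome")
    for S, state in zip(sw.S, sw.states):
        _, label = classify_outcome(state)
        b = state.B
        print(f"{S:10.1e} {b[0]:11.2e} {b[1]:11.2e} {b[2]:11.2e}  {label}")

print(
    "\nAt high supply the subset community collapses to the 3-RM host alone,"
    "\nwhile the unique-set community keeps all three hosts above threshold"
    "\nand carries more total biomass."
)
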