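"""Fed-batch verification: does adding water or glycerol raise the final
product mass?

Three 15-L runs with product-inhibited (Aibe) kinetics: group 1 is a plain
batch, group 2 receives 1 L of water at 40 h and 60 h, group 3 receives
1 L of 30% w/v glycerol (300 g) at each of those times.  Feed events are
instantaneous mass balances: dilution lowers the inhibitory product
concentration, and the glycerol feed also replenishes substrate.
"""

import numpy as np

import epferm as ep

schedules, spec = ep.make_group_fixtures()
labels = ["group 1 (no feed)", "group 2 (water)", "group 3 (glycerol)"]
for label, sched in zip(labels, schedules):
    s = ep.simulate_fed_batch(spec.kind, spec.params, sched, np.asarray(spec.times))
    mass = s.product[-1] * s.volume[-1]
    print(
        f"{label:22s} final volume {s.volume[-1]:5.1f} L, "
        f"product {s.product[-1]:6.1f} ug/L, total mass {mass:8.0f} ug"
    )
print(
    "\nDilution relieves product inhibition (group 2 > group 1) and the"
    "\nglycerol feed adds substrate on top of it (group 3 highest)."
)
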