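"""Do two runs break down in the same order?  Dice convergence of death orders.

For a pair of runs, D(n) is the overlap of the first-n dead sets.  The time
to convergence tc is the earliest death-count fraction after which D stays
at or above t_conv = 0.8; a small tc means the two runs share their
breakdown pattern almost from the start.
"""

import itertools

import numpy as np

from nexosim import (SeedSpec, SimulationConfig, dice_curve, run_simulation,
                     test_network_config, time_to_convergence)

netcfg = test_network_config()


def runs(p):
    cfg = SimulationConfig(
        network=netcfg, solubility="insoluble",
        seed=SeedSpec(kind="single", layer=2, cell_type="RS"),
        R_M=0.09, sigma_z=500.0, f_at=0.001, transfer_mode="low_increase",
        p_intercolumnar=p, horizon=25_000)
    return [run_simulation(cfg, s) for s in range(3)]


for p in (0.01, 1.0, 100.0):
    rs = runs(p)
    tcs = [time_to_convergence(dice_curve(a.death_order, b.death_order))
           for a, b in itertools.combinations(rs, 2)]
    print(f"selectivity p = {p:>6}: mean tc over 3 run pairs = "
          f"{np.mean(tcs):.3f}")

# Any spread selectivity (avoiding intercolumnar routes, p = 0.01, or
# seeking them, p = 100) constrains where protein can travel, so replicate
# runs agree on the death order earlier (lower tc) than unselective spread.
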