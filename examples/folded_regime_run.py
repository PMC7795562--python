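"""A reduced folded-regime run with free-energy profiles.

Two snake proteins on a 40x40 lattice between hydrophobic walls at warm
temperature (T* = 0.4, c = 4.5%): the published folded regime.  The run
starts from native placements, anneals the water at frozen conformations,
equilibrates with a drift check, and histograms the three order parameters.
Takes a few minutes; scale `PROD` up for tighter statistics.
"""

import hydrofold as hf
from hydrofold.montecarlo import Simulation, detect_equilibration
from hydrofold.observables import find_minimum, free_energy_profile

PROD = 30_000

params = hf.make_parameters(scale_id=0, T_star=0.4, P_star=0.0)
state = hf.init_state(params, L=40, n_proteins=2, seed=7, start="native")
sim = Simulation(state, params, seed=7)

sim.anneal_water(2_000)
equil = sim.run(10_000, record_stride=5)
print("equilibrated at step:", detect_equilibration(equil, window=200))

prod = sim.run(PROD, record_stride=5, step0=10_000)
for col, quantum, tie in (
    ("Nc", 1 / sim.nc_max, "upper"),
    ("Ic", 1 / sim.ic_max, "lower"),
    ("Mc", 1 / sim.mc_max, "lower"),
):
    prof = free_energy_profile(prod[col], params.T_star, quantum)
    loc = find_minimum(prof, min_count=10, tie_break=tie)
    print(f"F*({col}): global minimum at {col} = {loc}")
print("acceptance rates:", {k: round(v, 3) for k, v in sim.acceptance_rates().items()})
# Minima at Nc = 1, Ic = 0, Mc = 0 mean the proteins stay folded, dispersed
# and desorbed from the walls: the folded corner of the phase behaviour.
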