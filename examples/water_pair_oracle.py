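"""Validate the sampler against exact enumeration on a two-water system.

Two neighbouring water cells embedded in frozen chains carry 8 bonding
variables -- few enough to enumerate all 6^8 joint states exactly.  The
Monte Carlo sampler, restricted to the same degrees of freedom, must agree
within statistical error; with cooperativity switched off, the bond
probability also has a closed form e^(J/T) / (e^(J/T) + q - 1).
"""

import dataclasses

import numpy as np

import hydrofold as hf
from hydrofold.montecarlo import Simulation

fx = hf.generate_fixture("two-waters", seed=0, scale_id=0, T_star=0.4)
print(f"exact <NHB> = {fx.expected['NHB'].sum():.5f}  (zeta-shell pair, full couplings)")
print(f"exact <E>   = {fx.expected['E']:.3f} eps")

sim = Simulation(fx.state.copy(), fx.params, seed=1, volume_moves=False,
                 protein_moves=False)
sim.step(500)
hb = []
for _ in range(10_000):
    sim.step(1)
    hb.append(sim.nhb_counts().sum())
print(f"MC    <NHB> = {np.mean(hb):.5f}  over {len(hb)} steps")

p_nocoop = dataclasses.replace(fx.params, Jsig=0.0, Jsig_phi=0.0)
ex = hf.enumerate_exact(fx.state, p_nocoop)
closed = np.exp(p_nocoop.J / 0.4) / (np.exp(p_nocoop.J / 0.4) + 5)
print(f"no cooperativity: enumeration {ex['NHB'].sum():.7f} vs closed form {closed:.7f}")
# The enumeration and the closed form agree to numerical precision; the MC
# estimate fluctuates around them within sampling error.
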