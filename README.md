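# hydrofold

Monte Carlo simulation of lattice proteins in a coarse-grained water
monolayer confined between two hydrophobic walls — folding, unfolding and
aggregation as a function of temperature, concentration and hydrophobic
strength.

## The problem

Proteins near hydrophobic interfaces (nanoparticle surfaces, membranes)
unfold and aggregate differently than in bulk. `hydrofold` implements a
2D coarse-grained model of this situation for people studying
hydration-driven protein stability: self-avoiding 36-residue "snake"
proteins on a square lattice, explicit many-body water in every other cell,
and two structureless hydrophobic walls confining the slab.

## The model

Water occupies each non-residue cell and carries four bonding variables
σᵢⱼ ∈ {1..q}, q = 6. Bulk water energy:

    H(b) = Σᵢⱼ U(rᵢⱼ) − J·N_HB(b) − J_σ·N_coop(b)

with `U` a double-truncated Lennard-Jones potential (hard core at r₀,
cutoff 6r₀), a hydrogen bond on every nearest-neighbour pair with
σᵢⱼ = σⱼᵢ (and the density condition nᵢnⱼ = 1), and a cooperative term
over the six pairs of each molecule's four bonding variables. Each HB adds
a volume v_HB to the total V = Nv + N_HB·v_HB.

Hydration water is classified by adjacency — hydrophobic (Φ), hydrophilic
(ζ), mixed (χ), with walls counting as Φ — and its HBs use class-resolved
couplings: J_Φ > J (interfacial HBs are stronger), J_ζ = J,
J_χ = (J_Φ+J_ζ)/2, and a Φ-shell HB volume that shrinks under pressure,
v_HBΦ = v⁰_HBΦ(1 − k₁P). Residues interact through the Miyazawa–Jernigan
contact matrix (×2 for the 2D surface/volume ratio) and attract water with
−ε_Φ (hydrophobic) or −ε_ζ = 0 (hydrophilic). Three published parameter
sets, Scales 0/1/2, progressively weaken ε_Φ, J_Φ, J_σΦ — mimicking, e.g.,
rising ion concentration.

Sampling is Metropolis MC at constant (T, P): per step, Np global chain
moves (shift / rotation / crankshaft / pivot), m ~ U[1, 4L²] local moves
(corner flips for residues, σ flips for water), and one global volume move.
Order parameters: native-contact fraction `Nc` (per 25 per protein),
inter-protein + wall contacts `Ic` (per 36 per protein), wall contacts
`Mc` (per 2L). Free-energy profiles are F*(O) = −T* ln P(O), min-shifted.

## Worked example

```
$ python examples/folded_regime_run.py
equilibrated at step: 5
F*(Nc): global minimum at Nc = 1.0
F*(Ic): global minimum at Ic = 0.0
F*(Mc): global minimum at Mc = 0.0
acceptance rates: {'shift': 0.0, 'rotation': 0.0, 'crankshaft': 0.0,
                   'pivot': 0.02, 'corner': 0.0, 'sigma': 0.173, 'volume': 0.094}
```

Two proteins at c = 4.5%, T* = 0.4, Scale 0: the free energy is minimal at
full native contacts, zero inter-protein contacts and zero wall contacts —
folded, dispersed, desorbed. `examples/build_protein.py` constructs the
protein itself, `examples/water_pair_oracle.py` checks the sampler against
exact enumeration (e.g. ⟨N_HB⟩ = 0.98776 exact vs 0.98610 sampled over
10⁴ steps), and `examples/experiment_driver.py` shows the config-driven
experiment pipeline (also available as the `hydrofold` CLI:
`hydrofold run config.yaml`). `examples/reproduce_full.py` holds the
full-length overnight protocol for the published state points.

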