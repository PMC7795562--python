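# Methods

This note documents the model implemented in `hydrofold`, the conventions
and numerical choices behind it, and what the shipped tests do and do not
establish. Reduced units are used throughout: energies in the LJ well
depth ε, lengths in the water van der Waals diameter r₀, volumes in
v₀ = r₀²h with monolayer height h (so h = 1 and r₀ = 1), temperatures
T* = k_BT/ε, pressures P* = Pv₀/ε.

## Geometry and state

The system is an L×L square lattice, periodic along x, confined along y by
two structureless hydrophobic walls just outside rows y = 0 and y = L−1.
The walls are pure excluded volume: they accept no hydrogen bonds and
carry no attraction; their only other effect is that wall-adjacent water
counts as hydrophobically solvated (below). Every cell holds either one
water molecule or one protein residue. One global degree of freedom, the
cell volume v ≥ v₀, sets the nearest-neighbour spacing r = √(v/h). (The
alternative reading r = v/h is dimensionally inconsistent with
v₀ = r₀²h; √(v/h) is the only consistent choice and is used throughout.)

Each cell carries four bonding variables σ ∈ {1..6}, one per face. They
are attached to *cells*, not molecules: when a protein move changes the
occupancy of a cell, its bonding variables stay in place, latent and
energy-invisible while a residue sits there. This convention means no
move ever creates or destroys degrees of freedom, which keeps detailed
balance trivial for occupancy-changing moves.

## Hamiltonian

Water–water dispersion is a double-truncated Lennard-Jones potential
(∞ below r₀, zero at and beyond 6r₀) summed over all water pairs within
the cutoff, with minimum-image convention along x only and no pair across
a wall. Residues have no LJ term.

A nearest-neighbour water pair (i, j) forms a hydrogen bond iff
(1) the density index permits it — nᵢ = 1 iff v/v₀ < n_threshold, a
global condition since v is global — and (2) the facing bonding variables
match, σᵢⱼ = σⱼᵢ. Each molecule additionally gains a cooperative energy
−J_σ per equal-valued pair among its four bonding variables (6 pairs
max), including faces toward residues or walls; those faces simply can
never carry an HB. This is the literal reading of the cooperative sum;
freezing residue-facing faces instead would change nothing in the HB
physics and slightly reduce the entropy of shell water.

The printed density condition for HB formation ("v/v₀ < 0.5") conflicts
with the stated O–O distance bound r < r_max ≈ 4 Å given r₀ ≈ 2.9 Å,
which implies v/v₀ < (r_max/r₀)² ≈ 1.9; with the 0.5 threshold the
liquid at ambient pressure (v/v₀ ≈ 1.26 at the LJ minimum) would never
bond at all. The default is `n_threshold = 2.0` (the distance-bound
reading); 0.5 remains available as a config option.

Hydration water is classified per cell from its four neighbours:
Φ if it touches ≥ 1 hydrophobic residue or a wall and no hydrophilic
residue; ζ in the mirror case; χ if both kinds; bulk if neither. An HB
takes the class of its endpoints: bulk if either endpoint is bulk (the
conservative choice for the unspecified bulk–shell case — bulk couplings
apply), Φ/ζ if both endpoints share that label, χ otherwise. Cooperative
terms use the molecule's own label. Shell couplings follow
J_ζ = J, J_σζ = J_σ, J_χ = (J_Φ+J_ζ)/2, J_σχ = (J_σΦ+J_σζ)/2.

Each HB adds volume: v_HB(b) for bulk and ζ bonds, the pressure-dependent
v_HBΦ = v⁰_HBΦ(1 − k₁P) (clipped at zero) for Φ bonds, and — by the same
averaging convention as the couplings, since the case is unspecified —
(v_HBΦ + v_HB(b))/2 for χ bonds. At P = 0 the volume terms do not enter
the acceptance probabilities.

Residue–residue contacts (nearest neighbours not adjacent along a chain,
intra- and inter-chain) use the packaged 20×20 Miyazawa–Jernigan contact
energy table, scaled ×2 to compensate the lower surface/volume ratio in
2D. Entries are read as multiples of ε after that scaling; the table's
row order is the documented alphabet `CMFILVWYAGTSNQDEHRKP` and the
loader validates symmetry. Residue–water faces contribute −ε_Φ or −ε_ζ
by the residue's hydropathy; ε_ζ = 0 in all published parameter sets.

All published couplings are tabulated in units of 8ε and converted
exactly once at construction (e.g. Scale 0: J = 0.3·8ε = 2.4ε,
J_Φ = 9.6ε, ε_Φ = 3.84ε). The conversion factor is exposed
(`table_energy_factor`) purely to make the convention explicit.

## The protein

The native state is the boustrophedon filling of a 6×6 square: 35 chain
bonds, 25 non-bonded nearest-neighbour contacts (the native contact map),
20 water-exposed residues. "Sides" are the four 6-cell edges of the
square. The published sequence constraints are: 7 of the 20 interface
residues hydrophobic, at least one side fully hydrophilic, no side fully
hydrophobic. Hydropathy of the 20 amino-acid types is the sign of the
Kyte–Doolittle scale: {A, C, F, I, L, M, V} hydrophobic, the rest
hydrophilic.

The published protein was *selected* to sit in its native state at
ambient conditions, but its residue string was never printed. The
packaged default therefore pairs the surface constraints with identities
chosen for fold stability: hydrophobic interface positions at mid-side
cells (6, 11, 17, 18, 23, 29, 33 — never chain ends or corners, where a
detached residue is cheapest to hydrate), an L/F core (the strongest
entries of the contact table), W/Y/H/T at the hydrated interface and H at
both chain ends. An early variant with alphabet-cycled identities and
hydrophobic ends left the native state thermally unstable at T* = 0.4
(reversible end detachment), which is why the assignment is deliberate.
`design_sequence` draws constraint-satisfying alternatives at random, and
an independent checker (`check_sequence`) validates any sequence against
the constraints; user-supplied sequences are accepted everywhere.

Known limitation: the default sequence is *not* a designed-unique-ground-
state sequence. Alternative compact conformations (e.g. a rows→columns
refold of the 6×6 square) can sit below the snake native state once the
hydration water relaxes around them, because extra exposed hydrophobic
faces are enthalpically rewarded (ε_Φ, J_Φ > J). At the reduced scales
used here these basins are kinetically inaccessible from native
placements once the water is annealed, so folded-regime runs sample the
native basin — which is precisely what the reduced-scale checks measure.
Conclusions about full equilibrium at large step counts would require a
properly designed sequence.

## Monte Carlo

One MC step is:

1. Draw one global move kind uniformly from {shift, rotation, crankshaft,
   pivot}; repeat Np times: draw a chain uniformly (with replacement) and
   attempt that move.
2. Draw m ~ U[1, 4L²]; repeat m times: draw a cell uniformly; a residue
   cell attempts a corner flip, a water cell a σ flip on a uniformly
   drawn face with a uniformly drawn new value.
3. Attempt one global volume move, v′ = v + U(−δ_max, +δ_max), rejected
   outright below v₀ (the LJ hard core enforces this anyway); the
   proposal is uniform in v with no Jacobian term. δ_max defaults to
   0.05 v₀, giving ~10% acceptance in the liquid at T* = 0.4.

Move definitions (the source cites an external move set without detail):
shift translates the whole chain one lattice unit; rotation rotates the
whole chain by 90/180/270° about a uniformly chosen residue; crankshaft
flips a two-residue U-turn by 180°; pivot applies a uniformly chosen
non-identity lattice isometry (3 rotations, 4 reflections) to the segment
from a uniformly chosen residue to a uniformly chosen end. Every proposal
kernel is closed under inversion with equal probabilities, so plain
Metropolis acceptance min(1, e^−(ΔH+PΔV)/k_BT) satisfies detailed
balance; proposals that overlap residues or walls are outright
rejections. Corner flips are the only local conformational move (no end
flips); pivots and rotations restore ergodicity for chain ends.

Rejected moves leave the state bit-identical (asserted in the tests by
hashing the full state). A single counter-based RNG stream drives each
run; the seed is recorded in the metadata and every result in this
package is reproducible bit-for-bit from config + seed.

## Bookkeeping

The inner loop is numba-compiled and maintains exact *integer* tallies:
σ-matching pair counts per shell class, cooperative pair counts per
class, residue–water faces, and a histogram of water–water pair counts by
squared lattice separation (d² ≤ 36). Energies and volumes are always
derived from these counts — the LJ sum is a 37-term dot product against a
tabulated potential for the current v — so incremental updates cannot
drift; the only floating-point accumulation is the running MJ energy.
Occupancy-changing moves retally the affected neighbourhood (moved cells
plus their neighbours) before and after; shell labels are cached per cell
and recomputed only there. A full-recompute reference implementation
(`energetics.py`, plain Python) is kept deliberately independent, and the
suite verifies exact count agreement and ≤ 10⁻⁹ relative energy/volume
agreement after ≥ 10⁴ accepted moves.

## Observables and profiles

Nc counts current non-bonded NN pairs whose index pair is in the native
contact map — contact-map identity, hence invariant under rigid motions —
normalized by 25 Np. Ic counts inter-chain residue pairs plus
residue–wall faces, normalized by 36 Np. Mc counts residue–wall faces,
normalized by 2L. Profiles histogram the recorded series on the
observable's natural quantum (1/(25Np), 1/(36Np), 1/(2L)); F* = −T* ln P,
min-shifted to zero; empty bins carry no value and no pseudo-counts or
smoothing are applied (barrier heights are out of scope). Minima are read
over bins with ≥ 10 samples, ties broken toward the folded (larger Nc) or
unaggregated (smaller Ic/Mc) side. The 2D surface uses (Nc in percent,
25Np·Ic) axes.

Equilibration is declared when, over a trailing window of records, the
fitted linear slope of each of Nc, Ic, Mc is statistically
indistinguishable from zero (|slope| < 3 s.e.).

## Initial states and the reduced-scale protocol

`init_state` builds deterministic initial conditions: extended rods on a
homogeneous grid (the published high-temperature start) or native squares
away from the walls, with uniform-random bonding variables and
v = 1.2 v₀ (near the LJ minimum, v_eq/v₀ ≈ 1.21 at T* = 0.4, P = 0).
These generators emulate a freshly prepared homogeneous solution; they do
not emulate concentration gradients, pre-formed aggregates, or
sequence heterogeneity between chains.

Published runs use 10⁶–1.2×10⁷ equilibration steps and 10⁷ production
steps per state point — hours to days per point on one core. The shipped
tests and the acceptance script use a reduced protocol chosen as this
package's desk-scale default: native placements, a 2000-step water-only
annealing phase (conformational moves frozen) so that protein moves are
judged against relaxed hydration water rather than high-T noise, a
drift-checked equilibration of 10⁴–2×10⁴ steps, and productions of
2×10⁴–10⁵ steps. At this scale the folded-regime minima (Nc = 1, Ic = 0,
Mc = 0 at Scale 0, T* = 0.4, c ≤ 11%) are sharp and seed-stable. The
long-run state points (slight unfolding to Nc ≈ 0.94 at c = 22%,
aggregation onset at ambient T and c = 27%, Scale 1/2 trends) are checked
only in trend mode with wide tolerances; their quantitative reproduction
needs the full protocol in `examples/reproduce_full.py` plus a designed
sequence (above).

## Exact enumeration oracle

For frozen-occupancy states with ≤ 3 water cells (≤ 12 bonding variables)
the Boltzmann distribution is enumerated outright (per-cell state tables
over 6⁴ configurations), yielding exact ⟨N_HB⟩, ⟨N_coop⟩, ⟨E⟩ and their
thermal variances. The enumeration shares no code with the sampler's
bookkeeping. Fixtures pave a 4×4 lattice with immobile chains around two
free waters: hydrophilic paving yields a ζ-shell pair whose couplings
equal the bulk ones (so the textbook isolated-pair result
P(HB) = e^{J/k_BT}/(e^{J/k_BT}+q−1) applies literally at J_σ = 0), and
hydrophobic paving on the wall row yields a Φ-shell pair. MC agreement is
required within 3 block-averaged standard errors; where a quantity is so
deeply bound that a finite window shows no fluctuation events at all
(βJ_Φ = 24 at Scale 0, T* = 0.4), a floor of a tenth of the exact thermal
width covers the rare-event resolution.

## Known limitations

- 2D monolayer only; wall separation fixed at L; single homogeneous wall
  type.
- The default sequence satisfies the published constraints but is not the
  (unpublished) designed original; full-equilibrium claims at large step
  counts depend on sequence design (see above).
- The MJ table is transcribed from the standard 1996 contact-energy
  table; the unit mapping (entries = ε after ×2) is a documented
  convention, not a published fact.
- No reweighting/WHAM, no error bars on F* beyond per-bin counts, no
  barrier analysis, no cluster moves or parallel tempering.
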