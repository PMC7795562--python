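"""Model parameters for the confined water + lattice-protein Hamiltonian.

Reduced units are used throughout: the Lennard-Jones well depth ``eps`` is the
energy unit, the water van der Waals diameter ``r0`` the length unit, and the
excluded cell volume ``v0 = r0**2 * h`` the volume unit (monolayer height
``h = v0 / r0**2 = 1``).  Temperatures are ``T* = kB*T/eps`` and pressures
``P* = P*v0/eps``.

The published coupling tables list energies in units of ``8*eps``; they are
converted to ``eps`` exactly once, at construction.  Three parameter sets
("scales" 0, 1 and 2) differ only in the hydrophobic-shell couplings
``eps_phi``, ``J_phi`` and ``Jsig_phi``, progressively weakening the
hydrophobic effect (mimicking, e.g., increasing ion concentration).
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["ModelParameters", "make_parameters", "SCALE_TABLE"]

#: Published couplings per scale, in units of 8*eps (energies) and v0 (volumes):
#: (J, Jsig, vHB_b, eps_phi, J_phi, Jsig_phi, vHB0_phi, k1, eps_zeta)
SCALE_TABLE = {
    0: (0.3, 0.05, 0.5, 0.48, 1.20, 0.20, 2.0, 4.0, 0.0),
    1: (0.3, 0.05, 0.5, 0.24, 0.60, 0.10, 2.0, 4.0, 0.0),
    2: (0.3, 0.05, 0.5, 0.10, 0.35, 0.05, 2.0, 4.0, 0.0),
}

#: Orientational states per bonding variable: only 1/q of mutual orientations
#: (a +-30 degree cone out of 360) qualify as a hydrogen bond.
Q_STATES = 6


@dataclass(frozen=True)
class ModelParameters:
    """All Hamiltonian couplings plus the thermodynamic state.

    Energies in units of ``eps``, volumes in units of ``v0``, lengths in
    ``r0``.  Derived mixed-shell (chi) couplings follow the averaging rules
    ``J_chi = (J_phi + J_zeta)/2`` and ``Jsig_chi = (Jsig_phi + Jsig_zeta)/2``.
    """

    scale_id: int
    T_star: float
    P_star: float

    # bulk water
    J: float
    Jsig: float
    vHB_b: float

    # hydrophobic (phi) shell
    eps_phi: float
    J_phi: float
    Jsig_phi: float
    vHB0_phi: float
    k1: float

    # hydrophilic (zeta) shell: HBs as in bulk
    eps_zeta: float
    J_zeta: float = field(init=False)
    Jsig_zeta: float = field(init=False)
    vHB_zeta: float = field(init=False)

    # mixed (chi) shell, averages of phi and zeta
    J_chi: float = field(init=False)
    Jsig_chi: float = field(init=False)

    # geometry / bookkeeping
    q: int = Q_STATES
    r0: float = 1.0
    h: float = 1.0
    v0: float = 1.0
    lj_cutoff: float = 6.0          # in units of r0
    n_threshold: float = 2.0        # ni = 1 iff v/v0 < n_threshold
    mj_scale: float = 2.0           # 2D surface/volume compensation factor

    def __post_init__(self) -> None:
        object.__setattr__(self, "J_zeta", self.J)
        object.__setattr__(self, "Jsig_zeta", self.Jsig)
        object.__setattr__(self, "vHB_zeta", self.vHB_b)
        object.__setattr__(self, "J_chi", 0.5 * (self.J_phi + self.J_zeta))
        object.__setattr__(self, "Jsig_chi", 0.5 * (self.Jsig_phi + self.Jsig_zeta))
        if self.Jsig >= self.J and self.J > 0:
            raise ValueError("cooperative coupling must satisfy Jsig < J")

    # -- pressure-dependent phi-shell HB volume -------------------------------
    def vHB_phi(self, P_star: float | None = None) -> float:
        """Volume carried by one hydrophobic-shell HB, ``vHB0_phi*(1 - k1*P)``.

        The hydrophobic hydration shell densifies under pressure; the linear
        law is clipped at zero.
        """
        P = self.P_star if P_star is None else P_star
        return max(0.0, self.vHB0_phi * (1.0 - self.k1 * P))

    def vHB_chi(self, P_star: float | None = None) -> float:
        """Mixed-shell HB volume, averaged like the chi couplings."""
        return 0.5 * (self.vHB_phi(P_star) + self.vHB_zeta)


def make_parameters(
    scale_id: int,
    T_star: float,
    P_star: float = 0.0,
    *,
    n_threshold: float = 2.0,
    table_energy_factor: float = 8.0,
) -> ModelParameters:
    """Build :class:`ModelParameters` for one of the published scales.

    Parameters
    ----------
    scale_id
        0, 1 or 2; the sets differ only in the hydrophobic-shell couplings.
    T_star, P_star
        Reduced temperature ``kB*T/eps`` and pressure ``P*v0/eps``.
    n_threshold
        Density condition for HB formation: ``ni = 1`` iff ``v/v0 <
        n_threshold``.  The default 2.0 corresponds to the O-O distance bound
        ``r < rmax ~ 4 A`` with ``r0 ~ 2.9 A``; the alternative printed value
        0.5 can be passed explicitly (it suppresses all HBs in the liquid at
        ambient pressure).
    table_energy_factor
        The published coupling tables are in units of ``8*eps``; this factor
        performs that conversion and exists only to make the convention
        explicit and overridable.
    """
    if scale_id not in SCALE_TABLE:
        raise ValueError(f"unknown parameter scale {scale_id!r}; choose 0, 1 or 2")
    J, Jsig, vHB_b, eps_phi, J_phi, Jsig_phi, vHB0_phi, k1, eps_zeta = SCALE_TABLE[scale_id]
    f = table_energy_factor
    return ModelParameters(
        scale_id=scale_id,
        T_star=T_star,
        P_star=P_star,
        J=J * f,
        Jsig=Jsig * f,
        vHB_b=vHB_b,
        eps_phi=eps_phi * f,
        J_phi=J_phi * f,
        Jsig_phi=Jsig_phi * f,
        vHB0_phi=vHB0_phi,
        k1=k1,
        eps_zeta=eps_zeta * f,
        n_threshold=n_threshold,
    )
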