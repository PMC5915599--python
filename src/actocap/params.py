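"""Parameter containers for the membrane actin-growth model.

Unit conventions used throughout the package:

* bulk concentrations in µM, areal densities in µm⁻², lengths in µm
  (except ``delta_nm``), times in s;
* second-order rate constants in µM⁻¹ s⁻¹, first-order in s⁻¹;
* ``N_PER_UM3_PER_UM`` converts µM to molecules per µm³ so that bulk
  and membrane species can be mixed in one conservation law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace, fields as dc_fields

#: molecules per µm³ at 1 µM (6.02214076e23 / litre / 1e15)
N_PER_UM3_PER_UM = 602.214076

#: thermal energy at 25 °C in pN·nm
KBT_PN_NM_25C = 4.1164


class ParameterError(ValueError):
    """Raised when a kinetic or geometric parameter violates its constraints."""


@dataclass(frozen=True)
class RateParams:
    """Rate constants of the seven-reaction branching/capping network.

    The network couples membrane-tethered VCA, the Arp2/3 complex, actin
    monomers (G) and capping protein (CP):

    1. ``VCA + G -> VCA·G``                      (k_bind_VG, µM⁻¹s⁻¹)
    2. ``VCA·G + Arp -> Arp* + VCA_spent + G``   (k_act, µM⁻¹s⁻¹)
    3. ``Arp* -> B``            de-novo seeding  (k_seed, s⁻¹)
    4. ``Arp* + B -> 2B``       branching        (k_branch, µM⁻¹s⁻¹)
    5. ``B: G -> P``            elongation       (k_elong·(G − c_crit) per end)
    6. ``B + CP -> B_capped``                    (k_cap, µM⁻¹s⁻¹)
    7. ``VCA_spent -> VCA``     regeneration     (k_regen, s⁻¹)

    ``k_elong``, ``k_cap`` and ``c_crit`` are standard actin biochemistry;
    the remaining constants are calibrated defaults (see docs/methods.md).
    ``k_branch`` is stored in bulk (µM⁻¹s⁻¹) units; for two membrane-bound
    partners it is converted to a 2D constant through the reaction-shell
    thickness (see :meth:`Geometry.k2d_factor`).
    """

    k_bind_VG: float = 1.0
    k_act: float = 2.0e-3
    k_seed: float = 2.0e-4
    k_branch: float = 10.0
    k_elong: float = 11.6
    k_cap: float = 3.0
    k_regen: float = 1.0e-4
    delta_nm: float = 2.7
    c_crit: float = 0.1
    eta_seed_membrane: float = 1.0e-5
    K_nuc_G_uM: float = 0.3

    # eta_seed_membrane: de novo nucleation efficiency of membrane-tethered
    # Arp* relative to solution (tethered, VCA-bound Arp2/3 without a mother
    # filament nucleates poorly); dimensionless, calibrated.
    # K_nuc_G_uM: Michaelis constant of the monomer dependence of nucleation
    # (seeding and branching consume a first monomer, so both shut down as
    # G approaches the critical concentration).

    def __post_init__(self) -> None:
        for f in ("k_bind_VG", "k_act", "k_seed", "k_branch", "k_elong",
                  "k_cap", "k_regen"):
            v = getattr(self, f)
            if not (v >= 0.0) or not math.isfinite(v):
                raise ParameterError(f"rate constant {f} must be >= 0, got {v}")
        if self.delta_nm <= 0:
            raise ParameterError(f"delta_nm must be > 0, got {self.delta_nm}")
        if self.c_crit < 0:
            raise ParameterError(f"c_crit must be >= 0, got {self.c_crit}")
        if not (0.0 <= self.eta_seed_membrane <= 1.0):
            raise ParameterError("eta_seed_membrane must be in [0, 1]")
        if self.K_nuc_G_uM <= 0:
            raise ParameterError("K_nuc_G_uM must be > 0")
        if self.k_regen >= self.k_act and self.k_act > 0:
            raise ParameterError(
                "k_regen must be smaller than k_act (regeneration is slow): "
                f"k_regen={self.k_regen}, k_act={self.k_act}"
            )

    @property
    def delta_um(self) -> float:
        return self.delta_nm * 1e-3

    def v_free_um_s(self, G_uM: float) -> float:
        """Unloaded network growth speed k_elong·(G − c_crit)·delta in µm/s."""
        return max(self.k_elong * (G_uM - self.c_crit), 0.0) * self.delta_um

    def nucleation_monomer_factor(self, G_uM: float) -> float:
        """Saturating monomer dependence of seeding and branching,
        s(G) = (G − c_crit)_+ / (K + (G − c_crit)_+), in [0, 1)."""
        x = max(G_uM - self.c_crit, 0.0)
        return x / (self.K_nuc_G_uM + x)

    def with_(self, **kw) -> "RateParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class Geometry:
    """Vesicle geometry and the membrane reaction-shell thickness.

    ``shell_thickness_um`` sets the volume↔area conversion for reactions
    between two membrane species and for the bookkeeping that expresses
    membrane populations in bulk µM-equivalents.
    """

    R_vesicle_um: float = 15.0
    shell_thickness_um: float = 0.08

    def __post_init__(self) -> None:
        if self.R_vesicle_um <= 0:
            raise ParameterError("R_vesicle_um must be > 0")
        if not (0 < self.shell_thickness_um < 0.2 * self.R_vesicle_um):
            raise ParameterError(
                "shell_thickness_um must be positive and small compared with "
                f"the vesicle radius, got {self.shell_thickness_um}"
            )

    @property
    def area_um2(self) -> float:
        return 4.0 * math.pi * self.R_vesicle_um ** 2

    @property
    def volume_um3(self) -> float:
        return 4.0 / 3.0 * math.pi * self.R_vesicle_um ** 3

    @property
    def conv_uM_per_per_um2(self) -> float:
        """µM-equivalent of one molecule per µm² of membrane, for this vesicle."""
        return self.area_um2 / (self.volume_um3 * N_PER_UM3_PER_UM)

    @property
    def k2d_factor(self) -> float:
        """Divide a µM⁻¹s⁻¹ constant by (N·h) to get a µm²s⁻¹ 2D constant."""
        return N_PER_UM3_PER_UM * self.shell_thickness_um

    def areal_total_per_um2(self, c_uM: float) -> float:
        """Areal density when a bulk pool of ``c_uM`` is fully membrane-bound."""
        return c_uM / self.conv_uM_per_per_um2


@dataclass(frozen=True)
class Concentrations:
    """Encapsulated protein concentrations (the experimental mix).

    Profilin is not an explicit model species: its roles (no pointed-end
    growth, suppressed spontaneous nucleation) are built into the reaction
    set, so the field is documentation only.
    """

    actin_uM: float = 3.0
    vca_uM: float = 0.3
    arp_uM: float = 0.3
    profilin_uM: float = 13.5
    cp_nM: float = 80.0

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            if getattr(self, f.name) < 0:
                raise ParameterError(f"concentration {f.name} must be >= 0")

    @property
    def cp_uM(self) -> float:
        return self.cp_nM * 1e-3

    def with_(self, **kw) -> "Concentrations":
        return replace(self, **kw)
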