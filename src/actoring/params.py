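"""Parameter sets for the mechanochemical actomyosin model.

Units used throughout the package: lengths in nm, forces in pN, energies
in pN·nm, times in s, concentrations in µM unless noted. Defaults are the
published calibration for non-muscle actomyosin networks confined to a
thin oblate volume (T-cell synapse geometry).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

AVOGADRO = 6.02214076e23

#: length of one actin monomer along the filament axis (nm)
MONOMER_SIZE = 2.7
#: maximum monomers per cylinder element (108 nm)
MAX_MONOMERS_PER_CYLINDER = 40


@dataclass
class MechParams:
    """Mechanical energy constants.

    K_fil_str : cylinder axial stretching constant (pN/nm)
    K_fil_bend : inter-cylinder bending constant (pN·nm)
    theta0 : equilibrium bending angle (rad), 0 for straight filaments
    K_vol : excluded-volume prefactor (pN/nm^4) for the 1/r^4 pair potential
    K_linker_str : alpha-actinin spring constant (pN/nm)
    K_nmii_str_per_head : NMII ensemble spring constant per head (pN/nm);
        heads act in parallel, so ensemble stiffness is per-head × n_heads
    eps_boundary : boundary repulsion energy scale (pN·nm)
    lambda_screen : boundary screening length (nm)
    a0 : inward shift of the repulsive barrier from the mechanical wall (nm)
    """

    K_fil_str: float = 100.0
    K_fil_bend: float = 672.0
    theta0: float = 0.0
    K_vol: float = 1.0e5
    K_linker_str: float = 8.0
    K_nmii_str_per_head: float = 2.5
    eps_boundary: float = 100.0
    lambda_screen: float = 2.7
    a0: float = 100.0

    def validate(self) -> list[str]:
        out = []
        for name in ("K_fil_str", "K_fil_bend", "K_vol", "K_linker_str",
                     "K_nmii_str_per_head", "eps_boundary", "lambda_screen", "a0"):
            if getattr(self, name) <= 0:
                out.append(f"MechParams.{name} must be > 0")
        if self.theta0 != 0.0:
            out.append("MechParams.theta0 must be 0")
        return out


@dataclass
class ChemParams:
    """Reaction and diffusion rate constants.

    Polymerization on-rates are in (µM·s)^-1, off-rates in s^-1.
    The barbed-end on-rate and pointed-end off-rate are the treadmilling
    control knobs: (11.6, 0.8) is the slow in-vitro baseline, (34.8, 2.4)
    the three-fold formin/cofilin-boosted fast condition.
    """

    D_diff: float = 20.0e6          # nm^2/s (= 20 µm^2/s)
    k_on_BE: float = 11.6           # (µM·s)^-1
    k_on_PE: float = 1.3            # (µM·s)^-1
    k_off_BE: float = 1.4           # s^-1
    k_off_PE: float = 0.8           # s^-1
    k_destruction: float = 1.0      # s^-1, 2-monomer filaments only
    k_nu: float = 0.005             # s^-1 per free formin with local G-actin
    k_off_formin: float = 0.01      # s^-1
    k_on_linker: float = 0.7        # (µM·s)^-1
    k_off_linker: float = 0.3       # s^-1
    k_on_head: float = 0.2          # s^-1 per myosin head
    k_off_head: float = 1.7         # s^-1 per myosin head
    k_walk0: float = 7.4            # s^-1 unloaded per-step walk rate
    monomer_size: float = MONOMER_SIZE
    max_monomers_per_cylinder: int = MAX_MONOMERS_PER_CYLINDER

    def validate(self) -> list[str]:
        out = []
        for name in ("D_diff", "k_on_BE", "k_on_PE", "k_off_BE", "k_off_PE",
                     "k_destruction", "k_nu", "k_off_formin", "k_on_linker",
                     "k_off_linker", "k_on_head", "k_off_head", "k_walk0"):
            if getattr(self, name) < 0:
                out.append(f"ChemParams.{name} must be >= 0")
        if self.monomer_size != MONOMER_SIZE:
            out.append("ChemParams.monomer_size is fixed at 2.7 nm")
        if self.max_monomers_per_cylinder != MAX_MONOMERS_PER_CYLINDER:
            out.append("ChemParams.max_monomers_per_cylinder is fixed at 40")
        return out


@dataclass
class MechanoChemParams:
    """Force-dependence parameters for the four mechanosensitive laws.

    F_poly0 : Brownian-ratchet characteristic polymerization force (pN)
    F_linker_unbind : slip-bond characteristic force for alpha-actinin (pN)
    beta : catch-bond prefactor for NMII unbinding (dimensionless)
    gamma : catch-bond force sensitivity (pN^-1); the characteristic
        ensemble unbinding force is F_nmii_unbind = 1/gamma
    xi : force-sharing factor in the Hill force-velocity relation
    F_stall : per-head stall force (pN)
    duty_ratio : fraction of time a head spends attached
    n_heads_min / n_heads_max : inclusive range of NMII mini-filament heads
    """

    F_poly0: float = 1.5
    F_linker_unbind: float = 17.2
    beta: float = 0.2
    gamma: float = 0.05
    xi: float = 0.1
    F_stall: float = 12.62
    duty_ratio: float = 0.1
    n_heads_min: int = 15
    n_heads_max: int = 30

    @property
    def F_nmii_unbind(self) -> float:
        return 1.0 / self.gamma

    def validate(self) -> list[str]:
        out = []
        for name in ("F_poly0", "F_linker_unbind", "beta", "gamma", "xi", "F_stall"):
            if getattr(self, name) <= 0:
                out.append(f"MechanoChemParams.{name} must be > 0")
        if not (0.0 < self.duty_ratio < 1.0):
            out.append("MechanoChemParams.duty_ratio must be in (0,1)")
        if not (1 <= self.n_heads_min <= self.n_heads_max):
            out.append("MechanoChemParams head range invalid")
        return out


@dataclass
class Params:
    """Bundle of all parameter sets."""

    mech: MechParams = field(default_factory=MechParams)
    chem: ChemParams = field(default_factory=ChemParams)
    mechchem: MechanoChemParams = field(default_factory=MechanoChemParams)
    #: compartment edge length for the solution phase (nm)
    compartment_edge: float = 500.0
    #: fractional binding-site positions along each cylinder axis
    binding_site_fractions: tuple = (0.125, 0.375, 0.625, 0.875)
    #: motor/linker binding-site separation windows (nm)
    motor_span: tuple = (175.0, 225.0)
    linker_span: tuple = (30.0, 40.0)
    #: excluded-volume term switch (production calibration runs without it)
    use_excluded_volume: bool = False

    def validate(self) -> list[str]:
        out = self.mech.validate() + self.chem.validate() + self.mechchem.validate()
        if self.compartment_edge <= 0:
            out.append("Params.compartment_edge must be > 0")
        return out

    def to_dict(self) -> dict:
        return asdict(self)


def concentration_to_copies(conc_uM: float, volume_L: float) -> int:
    """Convert a molar concentration to an integer copy number.

    Parameters
    ----------
    conc_uM : concentration in µM (must be >= 0)
    volume_L : volume in litres (must be > 0)

    Returns ``round(conc * 1e-6 * N_A * volume)``.
    """
    if conc_uM < 0:
        raise ValueError("concentration must be non-negative")
    if volume_L <= 0:
        raise ValueError("volume must be positive")
    return int(round(conc_uM * 1e-6 * AVOGADRO * volume_L))


def copies_to_concentration(n: int, volume_L: float) -> float:
    """Inverse of :func:`concentration_to_copies` (returns µM)."""
    if volume_L <= 0:
        raise ValueError("volume must be positive")
    return n / (1e-6 * AVOGADRO * volume_L)
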