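"""Material property tables for tissues and implant alloys.

Each material is described by the electrical and thermal parameters that the
power-deposition and bioheat stages consume.  Implant metals carry zero
perfusion and zero metabolic heat; the skin flag selects the higher
thermoregulatory perfusion cap.

Tissue values are literature-typical dielectric/thermal/perfusion parameters
for the RF band around 64-128 MHz (muscle, fat, subcutaneous adipose tissue,
skin, cortical bone).  They are configuration, not physical constants: any
entry may be replaced through the ``property_table`` of a
:class:`~implantheat.phantom.TissueModel`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


@dataclass(frozen=True)
class TissueProperties:
    """Electrical, thermal and perfusion parameters of one material.

    Parameters
    ----------
    name : str
        Material label.
    sigma : float
        Electric conductivity, S/m.
    eps_r : float
        Relative permittivity (dimensionless).
    mu_r : float
        Relative permeability (dimensionless).
    lambda_th : float
        Thermal conductivity, W/(m K).
    c_p : float
        Specific heat capacity, J/(kg K).
    rho : float
        Mass density, kg/m^3.
    h_b0 : float
        Blood-perfusion coefficient at rest, W/(m^3 K).
    P_met0 : float
        Metabolic power density at rest, W/m^3.
    is_skin : bool
        Selects the skin thermoregulation perfusion cap (32 instead of 15).
    """

    name: str
    sigma: float
    eps_r: float
    mu_r: float
    lambda_th: float
    c_p: float
    rho: float
    h_b0: float
    P_met0: float
    is_skin: bool = False

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError(f"{self.name}: sigma must be >= 0")
        if self.rho <= 0 or self.c_p <= 0 or self.lambda_th <= 0:
            raise ValueError(f"{self.name}: rho, c_p, lambda_th must be > 0")
        if self.h_b0 < 0 or self.P_met0 < 0:
            raise ValueError(f"{self.name}: h_b0 and P_met0 must be >= 0")

    def with_(self, **kwargs) -> "TissueProperties":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)


# Implant materials (cast CoCrMo alloy and UHMW polyethylene liner).
COCRMO = TissueProperties(
    name="CoCrMo", sigma=1.16e6, eps_r=1.0, mu_r=1.0,
    lambda_th=14.0, c_p=450.0, rho=8445.0, h_b0=0.0, P_met0=0.0,
)
POLYETHYLENE = TissueProperties(
    name="polyethylene", sigma=0.0, eps_r=2.25, mu_r=1.0,
    lambda_th=0.47, c_p=1900.0, rho=940.0, h_b0=0.0, P_met0=0.0,
)

# Soft-tissue phantom materials.  Conductivities are RF-band values used by
# the synthetic birdcage deposition law; perfusion coefficients h_b0 are
# w * rho_tissue * rho_b * c_b / 6e7 with w the perfusion rate in
# ml/(min kg) and rho_b*c_b ~= 3.8 MJ/(m^3 K) for blood.
MUSCLE = TissueProperties(
    name="muscle", sigma=0.70, eps_r=66.0, mu_r=1.0,
    lambda_th=0.49, c_p=3421.0, rho=1090.0, h_b0=2550.0, P_met0=990.0,
)
FAT = TissueProperties(
    name="fat", sigma=0.07, eps_r=12.0, mu_r=1.0,
    lambda_th=0.21, c_p=2348.0, rho=911.0, h_b0=1900.0, P_met0=465.0,
)
SAT = TissueProperties(
    name="SAT", sigma=0.07, eps_r=12.0, mu_r=1.0,
    lambda_th=0.23, c_p=2348.0, rho=911.0, h_b0=1900.0, P_met0=465.0,
)
SKIN = TissueProperties(
    name="skin", sigma=0.50, eps_r=62.0, mu_r=1.0,
    lambda_th=0.37, c_p=3391.0, rho=1109.0, h_b0=7400.0, P_met0=1830.0,
    is_skin=True,
)
BONE = TissueProperties(
    name="bone", sigma=0.07, eps_r=15.0, mu_r=1.0,
    lambda_th=0.32, c_p=1313.0, rho=1908.0, h_b0=1200.0, P_met0=286.0,
)

#: Canonical voxel labels used by the phantom generator.
AIR = 0
LABEL_SKIN = 1
LABEL_SAT = 2
LABEL_FAT = 3
LABEL_MUSCLE = 4
LABEL_BONE = 5
LABEL_METAL = 6
LABEL_LINER = 7

#: Default label -> properties table for generated phantoms.
DEFAULT_PROPERTY_TABLE: dict[int, TissueProperties] = {
    LABEL_SKIN: SKIN,
    LABEL_SAT: SAT,
    LABEL_FAT: FAT,
    LABEL_MUSCLE: MUSCLE,
    LABEL_BONE: BONE,
    LABEL_METAL: COCRMO,
    LABEL_LINER: POLYETHYLENE,
}

#: Labels occupied by implant materials.
IMPLANT_LABELS = (LABEL_METAL, LABEL_LINER)
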