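"""Per-voxel RF power deposition: synthetic birdcage model or imported maps.

The synthetic deposition law is an explicit stand-in for a full-wave coil
simulation and is **not** absolute RF dosimetry: within the coil footprint
the deposited power density follows the quasi-static birdcage E-field
scaling ``P_RF ~ sigma_tissue * r^2`` (r = distance from the bore axis),
with a raised-cosine axial roll-off beyond the coil ends.  Its purpose is
pipeline exercise and relative body-position studies.

Maps are referenced to a stated time-averaged B1^2; scaling a map to a
sequence is linear in the sequence's <B1^2> (so dead time dilutes power
proportionally).  Implant metal voxels carry zero RF power (perfect-electric-
conductor masking); the implant mass still counts in whole-body SAR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np

from .phantom import TissueModel

#: Default transmit-coil footprint: axial length (m), centered at isocenter.
COIL_LENGTH = 0.450
#: Default raised-cosine roll-off length beyond each coil end, m.
ROLLOFF_LENGTH = 0.150


@dataclass
class RFPowerMap:
    """Volumetric RF power density per voxel, W/m^3, at a reference <B1^2>."""

    P_RF: np.ndarray
    reference_b1sq: float
    coil_footprint: float = COIL_LENGTH
    coil_center_z: float = 0.0

    def __post_init__(self) -> None:
        self.P_RF = np.asarray(self.P_RF, dtype=float)
        if self.reference_b1sq <= 0:
            raise ValueError("reference_b1sq must be > 0")
        if np.any(self.P_RF < 0):
            raise ValueError("P_RF must be >= 0 everywhere")

    def save(self, path: str, spacing: float, origin) -> None:
        affine = np.diag([spacing * 1e3] * 3 + [1.0])
        affine[:3, 3] = np.asarray(origin) * 1e3
        nib.save(nib.Nifti1Image(self.P_RF, affine), f"{path}.nii.gz")
        with open(f"{path}.json", "w") as fh:
            json.dump(
                {
                    "reference_b1sq": self.reference_b1sq,
                    "coil_footprint": self.coil_footprint,
                    "coil_center_z": self.coil_center_z,
                },
                fh,
            )


def axial_rolloff(z: np.ndarray, footprint: float = COIL_LENGTH,
                  center: float = 0.0, rolloff: float = ROLLOFF_LENGTH) -> np.ndarray:
    """Unit weight inside the coil, raised-cosine decay over ``rolloff`` m
    beyond the coil ends, zero farther out."""
    half = footprint / 2
    d = np.abs(np.asarray(z, dtype=float) - center) - half
    w = np.where(d <= 0, 1.0, np.where(d >= rolloff, 0.0,
                 0.5 * (1 + np.cos(np.pi * np.clip(d, 0, rolloff) / rolloff))))
    return w


def pec_mask(P: np.ndarray, model: TissueModel) -> np.ndarray:
    """Zero the RF power on implant metal voxels (idempotent)."""
    out = np.array(P, dtype=float, copy=True)
    out[model.metal_mask()] = 0.0
    return out


def synthetic_rf_map(
    model: TissueModel,
    reference_b1sq: float,
    footprint: float = COIL_LENGTH,
    coil_center_z: float = 0.0,
    rolloff: float = ROLLOFF_LENGTH,
    sar_wb_centered: float = 2.0,
) -> RFPowerMap:
    """Deterministic synthetic deposition profile for a phantom.

    ``P_RF = C * sigma * r^2 * rolloff(z)``, PEC-masked on the implant.  The
    scale C is fixed so that the *centered* body (its axial mid-plane at the
    coil center) would absorb ``sar_wb_centered`` W/kg at the reference
    <B1^2>; C does not depend on the actual position, so moving the body out
    of the coil reduces the deposited power accordingly.
    """
    X, Y, Z = model.coords()
    sigma = model.field_grid("sigma")
    sigma[model.implant_mask] = 0.0  # deposition law applies to tissue only
    r2 = X**2 + Y**2
    base = sigma * r2

    # normalization against the centered configuration
    z_rel = Z - (model.origin[2] + (model.shape[2] - 1) / 2 * model.spacing)
    w_centered = axial_rolloff(z_rel, footprint, 0.0, rolloff)
    rho = model.field_grid("rho")
    mass = rho.sum() * model.voxel_volume
    power_centered = (base * w_centered).sum() * model.voxel_volume
    if power_centered <= 0:
        raise ValueError("phantom has no conductive tissue to normalize against")
    C = sar_wb_centered * mass / power_centered

    P = C * base * axial_rolloff(Z, footprint, coil_center_z, rolloff)
    P = pec_mask(P, model)
    return RFPowerMap(P, reference_b1sq, footprint, coil_center_z)


def import_rf_map(path: str, model: TissueModel) -> RFPowerMap:
    """Load an externally computed RF power-density map onto the model grid.

    Accepts a NIfTI volume (with JSON sidecar carrying ``reference_b1sq``)
    whose grid either matches the model or is an integer refinement of it;
    refined maps are block-averaged, which conserves local volume integrals
    of power exactly.  Negative values are rejected.
    """
    img = nib.load(f"{path}.nii.gz")
    data = np.asarray(img.dataobj, dtype=float)
    with open(f"{path}.json") as fh:
        sidecar = json.load(fh)
    if np.any(data < 0):
        raise ValueError("imported RF map contains negative power density")
    if data.shape != model.shape:
        factors = [s // m for s, m in zip(data.shape, model.shape)]
        if any(f < 1 or s != f * m for f, s, m in
               zip(factors, data.shape, model.shape)):
            bad = [d for d in range(3) if data.shape[d] % model.shape[d]]
            raise ValueError(
                f"grid mismatch on dimensions {bad or list(range(3))}: "
                f"map {data.shape} vs model {model.shape}"
            )
        data = _block_mean(data, factors)
    P = pec_mask(data, model)
    return RFPowerMap(
        P,
        reference_b1sq=float(sidecar["reference_b1sq"]),
        coil_footprint=float(sidecar.get("coil_footprint", COIL_LENGTH)),
        coil_center_z=float(sidecar.get("coil_center_z", 0.0)),
    )


def _block_mean(data: np.ndarray, factors) -> np.ndarray:
    fx, fy, fz = factors
    nx, ny, nz = (s // f for s, f in zip(data.shape, factors))
    return data.reshape(nx, fx, ny, fy, nz, fz).mean(axis=(1, 3, 5))


def scale_to_sequence(rf_map: RFPowerMap, b1sq: float) -> RFPowerMap:
    """Scale the map to a sequence's time-averaged <B1^2> (linear in duty)."""
    factor = b1sq / rf_map.reference_b1sq
    return replace(rf_map, P_RF=rf_map.P_RF * factor, reference_b1sq=b1sq)


def sar_wb(rf_map: RFPowerMap, model: TissueModel) -> float:
    """Whole-body SAR, W/kg: total deposited power over total body mass.

    The implant is excluded from the numerator by PEC masking but its mass
    counts in the denominator.
    """
    rho = model.field_grid("rho")
    mass = rho.sum() * model.voxel_volume
    if mass <= 0:
        raise ValueError("model has no mass")
    power = pec_mask(rf_map.P_RF, model).sum() * model.voxel_volume
    return float(power / mass)
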