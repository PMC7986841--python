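"""Voxelized tissue phantoms with an embedded hip implant.

The generator produces a layered cylindrical soft-tissue phantom
(skin -> subcutaneous adipose tissue -> fat -> muscle, with a bone core)
and voxelizes a simplified unilateral hip endoprosthesis into it: a CoCrMo
stem with neck and hemispherical femoral head, a hemispherical acetabular
shell with fixation screw, and a polyethylene liner between head and shell.

Coordinate convention: right handed, axes ordered (x, y, z) with z along the
scanner bore, isocenter at the origin, grid indices 0-based, positions in
meters.  ``origin`` is the physical coordinate of the center of voxel
(0, 0, 0); voxel centers sit at ``origin + index * spacing``.  A voxel
belongs to a geometric primitive iff its center lies inside the primitive.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np
from scipy import ndimage

from .properties import (
    AIR,
    COCRMO,
    DEFAULT_PROPERTY_TABLE,
    IMPLANT_LABELS,
    LABEL_BONE,
    LABEL_FAT,
    LABEL_LINER,
    LABEL_METAL,
    LABEL_MUSCLE,
    LABEL_SAT,
    LABEL_SKIN,
    POLYETHYLENE,
    TissueProperties,
)

#: z coordinate of the implant head (m) for body positions 1..12: thorax
#: imaging down to femur/knee imaging, in 64 mm increments.
POSITION_HEAD_Z = tuple(
    z * 1e-3
    for z in (288, 224, 160, 96, 32, -32, -96, -160, -224, -288, -352, -416)
)


class ResolutionError(ValueError):
    """Voxel spacing too coarse to resolve the implant geometry."""


class GeometryError(ValueError):
    """Requested geometry does not fit the phantom grid."""


@dataclass(frozen=True)
class ImplantSpec:
    """Dimensions and materials of the simplified hip implant.

    Lengths in meters.  Defaults describe a 142 mm stem, a 30 mm
    hemispherical head, an 8 mm thick / 66 mm outer-diameter acetabular
    shell, a 34 mm fixation screw and a 10 mm polyethylene liner, with a
    total height of 230 mm from stem tip to head top.  Stem, neck and screw
    diameters are canonical-pose choices (the assembly is modeled coaxial,
    stem along +z, shell dome opening downward onto the head).
    """

    stem_length: float = 0.142
    head_diameter: float = 0.030
    shell_outer_diameter: float = 0.066
    shell_thickness: float = 0.008
    screw_length: float = 0.034
    liner_thickness: float = 0.010
    total_height: float = 0.230
    stem_diameter: float = 0.014
    neck_diameter: float = 0.012
    screw_diameter: float = 0.006
    metal: TissueProperties = COCRMO
    liner: TissueProperties = POLYETHYLENE

    def __post_init__(self) -> None:
        lengths = (
            self.stem_length, self.head_diameter, self.shell_outer_diameter,
            self.shell_thickness, self.screw_length, self.liner_thickness,
            self.total_height, self.stem_diameter, self.neck_diameter,
            self.screw_diameter,
        )
        if any(v <= 0 for v in lengths):
            raise ValueError("all implant dimensions must be > 0")
        if self.shell_thickness >= self.shell_outer_diameter / 2:
            raise ValueError("shell_thickness must be < shell_outer_diameter/2")
        if self.total_height <= self.stem_length + self.head_diameter / 2:
            raise ValueError("total_height too small for stem + head")

    @property
    def head_center_z(self) -> float:
        """z of the femoral head (hemisphere) center above the stem tip."""
        return self.total_height - self.head_diameter / 2

    @property
    def extent_z(self) -> float:
        """Total axial extent of the voxelized assembly (stem tip to screw top)."""
        shell_inner = self.shell_outer_diameter / 2 - self.shell_thickness
        return max(
            self.head_center_z + self.shell_outer_diameter / 2,
            self.head_center_z + shell_inner + self.screw_length,
        )


@dataclass
class ImplantMasks:
    """Voxelization of one implant on a local grid.

    ``origin`` is the coordinate of voxel (0,0,0) center in the implant frame
    (stem tip at z=0 on the assembly axis x=y=0); ``head_center`` is the
    femoral-head center in the same frame.
    """

    metal: np.ndarray
    liner: np.ndarray
    spacing: float
    origin: np.ndarray
    head_center: np.ndarray

    @property
    def head_voxel(self) -> tuple[int, int, int]:
        idx = np.rint((self.head_center - self.origin) / self.spacing)
        return tuple(int(i) for i in idx)


def make_implant(spec: ImplantSpec, spacing: float) -> ImplantMasks:
    """Voxelize the implant with the center-inside membership rule.

    Raises :class:`ResolutionError` when ``spacing > head_diameter/4``, below
    which the hemispherical head would degenerate to a couple of voxels.
    """
    if spacing > spec.head_diameter / 4:
        raise ResolutionError(
            f"spacing {spacing} m too coarse: must be <= head_diameter/4 "
            f"= {spec.head_diameter / 4} m"
        )
    h = spacing
    r_out = spec.shell_outer_diameter / 2
    half_xy = r_out + h  # margin of one voxel
    # Even number of centers straddling the axis (centers at +-h/2, +-3h/2,...)
    # keeps the voxelization symmetric and deterministic.
    n_half = int(np.ceil(half_xy / h))
    nx = ny = 2 * n_half
    x = (np.arange(nx) - (nx - 1) / 2) * h
    z_top = spec.extent_z + h
    nz = int(np.ceil(z_top / h)) + 1
    z = (np.arange(nz) + 0.5) * h - h  # one air voxel below the stem tip
    origin = np.array([x[0], x[0], z[0]])

    X, Y, Z = np.meshgrid(x, x, z, indexing="ij")
    R2 = X**2 + Y**2
    zc = spec.head_center_z
    D2 = R2 + (Z - zc) ** 2  # squared distance from the head center

    stem = (R2 <= (spec.stem_diameter / 2) ** 2) & (Z >= 0) & (Z <= spec.stem_length)
    neck = (
        (R2 <= (spec.neck_diameter / 2) ** 2)
        & (Z > spec.stem_length)
        & (Z < zc)
    )
    r_head = spec.head_diameter / 2
    head = (D2 <= r_head**2) & (Z >= zc)
    r_shell_in = r_out - spec.shell_thickness
    shell = (D2 > r_shell_in**2) & (D2 <= r_out**2) & (Z >= zc)
    screw_base = zc + r_shell_in
    screw = (
        (R2 <= (spec.screw_diameter / 2) ** 2)
        & (Z >= screw_base)
        & (Z <= screw_base + spec.screw_length)
    )
    metal = stem | neck | head | shell | screw

    r_liner = r_head + spec.liner_thickness
    liner = (D2 > r_head**2) & (D2 <= min(r_liner, r_shell_in) ** 2) & (Z >= zc)
    liner &= ~metal

    return ImplantMasks(
        metal=metal,
        liner=liner,
        spacing=h,
        origin=origin,
        head_center=np.array([0.0, 0.0, zc]),
    )


@dataclass
class TissueModel:
    """Voxel grid of tissue labels with material properties and implant mask.

    Attributes
    ----------
    spacing : float
        Isotropic voxel edge, m.
    labels : ndarray of int
        3D tissue label grid, 0 = air.
    implant_mask : ndarray of bool
        Voxels occupied by implant materials (metal and liner).
    property_table : dict[int, TissueProperties]
        Label -> material properties; every nonzero label must be present.
    origin : ndarray
        Coordinate (m) of voxel (0,0,0) center relative to the isocenter.
    head_voxel : tuple or None
        Grid index of the implant head center, if an implant is present.
    """

    spacing: float
    labels: np.ndarray
    implant_mask: np.ndarray
    property_table: dict[int, TissueProperties]
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    head_voxel: tuple[int, int, int] | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.implant_mask = np.asarray(self.implant_mask, dtype=bool)
        self.origin = np.asarray(self.origin, dtype=float)
        if self.labels.shape != self.implant_mask.shape:
            raise ValueError("labels and implant_mask shapes differ")
        present = set(np.unique(self.labels)) - {AIR}
        missing = present - set(self.property_table)
        if missing:
            raise ValueError(f"labels without property-table entry: {missing}")
        bad = self.implant_mask & ~np.isin(self.labels, IMPLANT_LABELS)
        if bad.any():
            raise ValueError("implant_mask covers non-implant labels")

    # -- geometry helpers -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-center coordinate grids (x, y, z) in meters."""
        axes = [
            self.origin[d] + np.arange(self.shape[d]) * self.spacing
            for d in range(3)
        ]
        return np.meshgrid(*axes, indexing="ij")

    @property
    def voxel_volume(self) -> float:
        return self.spacing**3

    def body_mask(self) -> np.ndarray:
        return self.labels != AIR

    def metal_mask(self) -> np.ndarray:
        return self.labels == LABEL_METAL

    def surface_mask(self) -> np.ndarray:
        """Body voxels with at least one face-adjacent air voxel."""
        body = self.body_mask()
        eroded = ndimage.binary_erosion(body, structure=_FACE_STRUCT, border_value=1)
        return body & ~eroded

    # -- property lookups --------------------------------------------------
    def field_grid(self, attr: str, default: float = 0.0) -> np.ndarray:
        """Per-voxel grid of one TissueProperties attribute (air -> default)."""
        max_label = int(self.labels.max(initial=0))
        lut = np.full(max_label + 1, default, dtype=float)
        for lbl, props in self.property_table.items():
            if lbl <= max_label:
                lut[lbl] = float(getattr(props, attr))
        return lut[self.labels]

    def skin_mask(self) -> np.ndarray:
        max_label = int(self.labels.max(initial=0))
        lut = np.zeros(max_label + 1, dtype=bool)
        for lbl, props in self.property_table.items():
            if lbl <= max_label:
                lut[lbl] = props.is_skin
        return lut[self.labels]

    def masses(self) -> dict[str, float]:
        """Total mass (kg) per tissue label name."""
        out: dict[str, float] = {}
        for lbl, props in self.property_table.items():
            n = int(np.count_nonzero(self.labels == lbl))
            if n:
                out[props.name] = n * self.voxel_volume * props.rho
        return out

    def with_origin(self, origin) -> "TissueModel":
        return replace(self, origin=np.asarray(origin, dtype=float))

    # -- I/O ---------------------------------------------------------------
    def save(self, path: str) -> None:
        """Write labels + implant mask as NIfTI and a JSON sidecar.

        ``path`` is a stem: writes ``<path>_labels.nii.gz``,
        ``<path>_implant.nii.gz`` and ``<path>.json``.
        """
        affine = np.diag([self.spacing * 1e3] * 3 + [1.0])
        affine[:3, 3] = self.origin * 1e3  # NIfTI convention: mm
        nib.save(
            nib.Nifti1Image(self.labels.astype(np.int16), affine),
            f"{path}_labels.nii.gz",
        )
        nib.save(
            nib.Nifti1Image(self.implant_mask.astype(np.uint8), affine),
            f"{path}_implant.nii.gz",
        )
        sidecar = {
            "spacing": self.spacing,
            "origin": self.origin.tolist(),
            "head_voxel": list(self.head_voxel) if self.head_voxel else None,
            "property_table": {
                str(lbl): props.__dict__ for lbl, props in self.property_table.items()
            },
        }
        with open(f"{path}.json", "w") as fh:
            json.dump(sidecar, fh, indent=1)

    @classmethod
    def load(cls, path: str) -> "TissueModel":
        labels = np.asarray(nib.load(f"{path}_labels.nii.gz").dataobj).astype(np.int16)
        implant = np.asarray(nib.load(f"{path}_implant.nii.gz").dataobj).astype(bool)
        with open(f"{path}.json") as fh:
            sidecar = json.load(fh)
        table = {
            int(lbl): TissueProperties(**props)
            for lbl, props in sidecar["property_table"].items()
        }
        head = sidecar.get("head_voxel")
        return cls(
            spacing=float(sidecar["spacing"]),
            labels=labels,
            implant_mask=implant,
            property_table=table,
            origin=np.asarray(sidecar["origin"], dtype=float),
            head_voxel=tuple(head) if head else None,
        )


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)

#: Default concentric layers (label, thickness in m) from the body surface in.
DEFAULT_LAYERS = (
    (LABEL_SKIN, 0.004),
    (LABEL_SAT, 0.006),
    (LABEL_FAT, 0.010),
)


def make_phantom(
    shape: tuple[int, int, int],
    layers=DEFAULT_LAYERS,
    spec: ImplantSpec | None = ImplantSpec(),
    spacing: float = 0.002,
    bone_core_radius: float = 0.020,
    property_table: dict[int, TissueProperties] | None = None,
) -> TissueModel:
    """Build a layered cylindrical phantom with an optional embedded implant.

    The body is a circular cylinder along z filling the grid cross-section
    (one air voxel margin on every face), layered from the surface inward
    per ``layers`` with a muscle fill and a coaxial bone core.  The implant
    (if any) is placed coaxially, head toward +z, axially centered, and
    overrides the tissue labels it intersects.

    Parameters follow :class:`TissueModel`; ``spec=None`` omits the implant.
    """
    nx, ny, nz = shape
    h = spacing
    table = dict(property_table or DEFAULT_PROPERTY_TABLE)

    ax = [(np.arange(n) - (n - 1) / 2) * h for n in (nx, ny, nz)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    r = np.hypot(X, Y)

    body_radius = (min(nx, ny) / 2 - 1) * h
    z_half = (nz / 2 - 1) * h
    body = (r <= body_radius) & (np.abs(Z) <= z_half)

    labels = np.zeros(shape, dtype=np.int16)
    fill = LABEL_MUSCLE
    depth = 0.0
    labels[body] = fill
    for lbl, thick in layers:
        sel = body & (r > body_radius - depth - thick) & (r <= body_radius - depth)
        labels[sel] = lbl
        depth += thick
    if depth >= body_radius:
        raise GeometryError("layers thicker than the body radius")
    labels[body & (r <= bone_core_radius)] = LABEL_BONE

    implant_mask = np.zeros(shape, dtype=bool)
    head_voxel = None
    if spec is not None:
        masks = make_implant(spec, h)
        mnx, mny, mnz = masks.metal.shape
        if mnx > nx - 2 or mny > ny - 2 or mnz > nz - 2:
            raise GeometryError("implant exceeds phantom bounds")
        # coaxial, axially centered placement
        off = [(shape[d] - masks.metal.shape[d]) // 2 for d in range(3)]
        sl = tuple(slice(off[d], off[d] + masks.metal.shape[d]) for d in range(3))
        inside = body[sl]
        if not (inside[masks.metal] | ~masks.metal[masks.metal]).all():
            raise GeometryError("implant extends outside the body")
        sub = labels[sl]
        sub[masks.liner] = LABEL_LINER
        sub[masks.metal] = LABEL_METAL
        imp = implant_mask[sl]
        imp |= masks.metal | masks.liner
        hv = masks.head_voxel
        head_voxel = tuple(off[d] + hv[d] for d in range(3))

    origin = np.array([a[0] for a in ax])
    return TissueModel(
        spacing=h,
        labels=labels,
        implant_mask=implant_mask,
        property_table=table,
        origin=origin,
        head_voxel=head_voxel,
    )


def place_body(model: TissueModel, position_index: int) -> TissueModel:
    """Shift the model so the implant head sits at the configured bore offset.

    ``position_index`` runs 1 (thorax imaging, head at z=+288 mm) to 12
    (femur/knee imaging, head at z=-416 mm) in 64 mm increments.
    """
    if not 1 <= position_index <= 12:
        raise ValueError("position_index must be in 1..12")
    if model.head_voxel is None:
        raise ValueError("model has no implant head recorded")
    target_z = POSITION_HEAD_Z[position_index - 1]
    origin = model.origin.copy()
    origin[2] = target_z - model.head_voxel[2] * model.spacing
    return model.with_origin(origin)


def head_position(model: TissueModel) -> np.ndarray:
    """Physical coordinate (m) of the implant head center."""
    if model.head_voxel is None:
        raise ValueError("model has no implant head recorded")
    return model.origin + np.asarray(model.head_voxel) * model.spacing
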