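"""Safety metrics derived from the temperature-increase field.

Reports the quantities used to judge implant-heating risk: maximum
temperature increase (whole body or within a region of influence around the
implant), the tissue mass exceeding temperature-increase thresholds
(1 K / 3 K by default, matching the 39 degC / 41 degC local-temperature
limits), the time until a threshold is first exceeded, and the temperature
increase of each voxel versus its distance from the implant surface.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .bioheat import ThermalResult
from .phantom import TissueModel

#: Default region-of-influence box dimensions (x, y, z), m.
DEFAULT_ROI_SIZE = (0.217, 0.188, 0.282)


@dataclass(frozen=True)
class RegionOfInfluence:
    """Axis-aligned box around the implant within which metrics are reported."""

    size: tuple[float, float, float] = DEFAULT_ROI_SIZE

    def mask(self, model: TissueModel) -> np.ndarray:
        """Boolean voxel mask of the box centered on the implant bounding box."""
        if not model.implant_mask.any():
            raise ValueError("model has no implant")
        idx = np.nonzero(model.implant_mask)
        center = np.array([(i.min() + i.max()) / 2 for i in idx])
        half = np.array(self.size) / (2 * model.spacing)
        bbox_half = np.array([(i.max() - i.min()) / 2 for i in idx])
        if np.any(half < bbox_half):
            raise ValueError("region of influence smaller than the implant bounding box")
        out = np.zeros(model.shape, dtype=bool)
        lo = np.maximum(0, np.ceil(center - half).astype(int))
        hi = np.minimum(model.shape, np.floor(center + half).astype(int) + 1)
        out[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return out


def max_delta_T(state, mask: np.ndarray | None = None) -> float:
    """Maximum temperature increase (K) over the mask (default: everywhere)."""
    dT = state.delta_T if hasattr(state, "delta_T") else np.asarray(state)
    if mask is None:
        return float(dT.max())
    if not mask.any():
        raise ValueError("empty mask")
    return float(dT[mask].max())


def mass_above_threshold(state, model: TissueModel, threshold: float,
                         region: np.ndarray | None = None) -> dict[str, float]:
    """Grams of tissue per label with delta_T > threshold inside ``region``.

    Implant voxels (metal and liner) are excluded; tissues with no heated
    voxels report 0.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    dT = state.delta_T if hasattr(state, "delta_T") else np.asarray(state)
    hot = (dT > threshold) & ~model.implant_mask
    if region is not None:
        hot &= region
    out: dict[str, float] = {}
    vv = model.voxel_volume
    from .properties import IMPLANT_LABELS

    for lbl, props in model.property_table.items():
        if lbl in IMPLANT_LABELS:
            continue
        n = int(np.count_nonzero(hot & (model.labels == lbl)))
        out[props.name] = n * vv * props.rho * 1e3  # grams
    return out


def time_to_threshold(times: np.ndarray, max_series: np.ndarray,
                      threshold: float) -> float | None:
    """First time (s) the running-max temperature increase exceeds threshold.

    Linearly interpolated between marching steps; None if never exceeded
    within the series.
    """
    times = np.asarray(times, dtype=float)
    running = np.maximum.accumulate(np.asarray(max_series, dtype=float))
    above = running > threshold
    if not above.any():
        return None
    s = int(np.argmax(above))
    if s == 0:
        return float(times[0])
    t0, t1 = times[s - 1], times[s]
    v0, v1 = running[s - 1], running[s]
    return float(t0 + (threshold - v0) / (v1 - v0) * (t1 - t0))


def implant_surface(model: TissueModel) -> np.ndarray:
    """Implant voxels with at least one face-adjacent non-implant voxel."""
    imp = model.implant_mask
    if not imp.any():
        raise ValueError("model has no implant")
    eroded = ndimage.binary_erosion(
        imp, structure=ndimage.generate_binary_structure(3, 1), border_value=0
    )
    return imp & ~eroded


def distance_to_implant(model: TissueModel) -> np.ndarray:
    """Per-voxel Euclidean center-to-center distance (m) to the nearest
    implant-surface voxel (zero on the surface itself)."""
    surf = implant_surface(model)
    return ndimage.distance_transform_edt(~surf) * model.spacing


def distance_profile(state, model: TissueModel,
                     region: np.ndarray | None = None):
    """(distance, delta_T, tissue name) per non-implant body voxel in region.

    Returns a list of three arrays suitable for scatter plotting or CSV
    export, sorted by distance.
    """
    dT = state.delta_T if hasattr(state, "delta_T") else np.asarray(state)
    dist = distance_to_implant(model)
    sel = model.body_mask() & ~model.implant_mask
    if region is not None:
        sel &= region
    idx = np.nonzero(sel)
    d = dist[idx]
    order = np.argsort(d)
    names = {lbl: p.name for lbl, p in model.property_table.items()}
    tissue = np.array([names[int(l)] for l in model.labels[idx][order]])
    return d[order], dT[idx][order], tissue


def distance_profile_csv(path: str, state, model: TissueModel,
                         region: np.ndarray | None = None) -> None:
    d, dT, tissue = distance_profile(state, model, region)
    with open(path, "w") as fh:
        fh.write("distance_m,delta_T_K,tissue\n")
        for row in zip(d, dT, tissue):
            fh.write(f"{row[0]:.6g},{row[1]:.6g},{row[2]}\n")


@dataclass
class SafetyReport:
    """Summary safety metrics for one exposure case."""

    case: str
    max_delta_T: dict[float, float]  # snapshot time -> max dT (K)
    max_delta_T_roi: dict[float, float]
    heated_mass_g: dict[float, dict[str, float]]  # threshold -> tissue -> g
    time_to_threshold_s: dict[float, float | None]
    thresholds: tuple[float, ...] = (1.0, 3.0)
    roi_size: tuple[float, float, float] = DEFAULT_ROI_SIZE
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        times = [self.time_to_threshold_s.get(t) for t in sorted(self.time_to_threshold_s)]
        known = [t for t in times if t is not None]
        if known != sorted(known):
            raise ValueError("time-to-threshold must be monotone in the threshold")

    def to_json(self, path: str) -> None:
        payload = {
            "case": self.case,
            "thresholds_K": list(self.thresholds),
            "roi_size_m": list(self.roi_size),
            "max_delta_T_K": {str(t): v for t, v in self.max_delta_T.items()},
            "max_delta_T_roi_K": {str(t): v for t, v in self.max_delta_T_roi.items()},
            "heated_mass_g": {
                str(thr): masses for thr, masses in self.heated_mass_g.items()
            },
            "time_to_threshold_s": {
                str(t): v for t, v in self.time_to_threshold_s.items()
            },
            "meta": self.meta,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def build_report(result: ThermalResult, model: TissueModel, case: str,
                 roi: RegionOfInfluence = RegionOfInfluence(),
                 thresholds=(1.0, 3.0), meta=None) -> SafetyReport:
    """Assemble the safety metrics from one thermal solve."""
    roi_mask = roi.mask(model) if model.implant_mask.any() else None
    max_dT = {t: max_delta_T(s) for t, s in result.snapshots.items()}
    max_dT[result.final.time] = max_delta_T(result.final)
    max_roi = {
        t: (max_delta_T(s, roi_mask) if roi_mask is not None else float("nan"))
        for t, s in {**result.snapshots, result.final.time: result.final.delta_T}.items()
    }
    heated = {
        thr: mass_above_threshold(result.final, model, thr, roi_mask)
        for thr in thresholds
    }
    ttt = {
        thr: time_to_threshold(result.times, result.max_history, thr)
        for thr in thresholds
    }
    return SafetyReport(
        case=case,
        max_delta_T=max_dT,
        max_delta_T_roi=max_roi,
        heated_mass_g=heated,
        time_to_threshold_s=ttt,
        thresholds=tuple(thresholds),
        roi_size=roi.size,
        meta=meta or {},
    )
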