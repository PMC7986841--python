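"""Marching-step-averaged power density for the three exposure cases.

P1 deposits only the gradient-coil eddy power (nonzero only in the implant
metal), P2 only the RF power (zero in the metal by PEC masking), and
P3 = P1 + P2 samplewise.  Within active acquisition intervals both sources
carry their interval-averaged power density; during dead/idle times the
deposited power is zero.  Each thermal marching step therefore scales the
per-voxel base map by the exact active-time fraction of that step, which
conserves the deposited energy identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

CASES = ("P1", "P2", "P3")


@dataclass
class PowerMap:
    """Per-step volumetric power density, factored as base * step_scale.

    ``base`` is the per-voxel power density (W/m^3) during active intervals;
    ``step_scale[s]`` is the active-time fraction of marching step s.
    """

    case: str
    base: np.ndarray
    step_scale: np.ndarray
    step_duration: float

    def __post_init__(self) -> None:
        if self.case not in CASES:
            raise ValueError(f"case must be one of {CASES}")
        if np.any(self.base < 0):
            raise ValueError("P_em must be >= 0")
        if self.step_duration <= 0:
            raise ValueError("step duration must be > 0")

    @property
    def n_steps(self) -> int:
        return self.step_scale.size

    def step_power(self, s: int) -> np.ndarray:
        """P_em averaged over marching step ``s``, W/m^3."""
        return self.base * self.step_scale[s]

    def total_energy(self, voxel_volume: float) -> float:
        """Deposited energy over all steps, J."""
        return float(
            self.base.sum() * voxel_volume * self.step_scale.sum() * self.step_duration
        )

    def to_hdf5(self, path: str) -> None:
        with h5py.File(path, "w") as fh:
            fh.attrs["case"] = self.case
            fh.attrs["step_duration"] = self.step_duration
            fh.create_dataset("base", data=self.base, compression="gzip")
            fh.create_dataset("step_scale", data=self.step_scale)

    @classmethod
    def from_hdf5(cls, path: str) -> "PowerMap":
        with h5py.File(path, "r") as fh:
            return cls(
                case=str(fh.attrs["case"]),
                base=fh["base"][()],
                step_scale=fh["step_scale"][()],
                step_duration=float(fh.attrs["step_duration"]),
            )


def activity_fraction(schedule, t0: float, t1: float) -> float:
    """Fraction of [t0, t1] covered by active acquisition intervals.

    ``schedule`` is a list of (active, dead) duration pairs laid end to end.
    Time past the end of the schedule counts as idle.
    """
    if t1 <= t0:
        raise ValueError("t1 must be > t0")
    active = 0.0
    t = 0.0
    for act, dead in schedule:
        a0, a1 = t, t + act
        active += max(0.0, min(t1, a1) - max(t0, a0))
        t = a1 + dead
        if t >= t1:
            break
    return active / (t1 - t0)


def schedule_span(schedule) -> float:
    return float(sum(a + d for a, d in schedule))


def combine(
    p_gc: np.ndarray | None,
    p_rf: np.ndarray | None,
    schedule,
    case: str,
    thermal_dt: float = 0.1,
    duration: float = 360.0,
) -> PowerMap:
    """Build the marching-step power map for one exposure case.

    ``p_gc`` is the interval-averaged gradient-coil power density during
    active intervals (zero outside the implant); ``p_rf`` the RF power
    density referenced to the active-interval <B1^2> (zero in the metal).
    The schedule must cover ``duration``; dead/idle times between
    acquisitions contribute zero power and are honored exactly in each
    step's average, including steps straddling an active/dead boundary.
    """
    if case not in CASES:
        raise ValueError(f"case must be one of {CASES}")
    if schedule_span(schedule) < duration - 1e-9:
        raise ValueError(
            f"schedule covers {schedule_span(schedule):.1f} s "
            f"< requested duration {duration} s"
        )
    parts = []
    if case in ("P1", "P3"):
        if p_gc is None:
            raise ValueError("case P1/P3 requires p_gc")
        parts.append(np.asarray(p_gc, dtype=float))
    if case in ("P2", "P3"):
        if p_rf is None:
            raise ValueError("case P2/P3 requires p_rf")
        parts.append(np.asarray(p_rf, dtype=float))
    base = parts[0] if len(parts) == 1 else parts[0] + parts[1]
    n_steps = int(round(duration / thermal_dt))
    scale = np.array(
        [
            activity_fraction(schedule, s * thermal_dt, (s + 1) * thermal_dt)
            for s in range(n_steps)
        ]
    )
    return PowerMap(case=case, base=base, step_scale=scale, step_duration=thermal_dt)
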