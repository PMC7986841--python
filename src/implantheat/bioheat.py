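"""Pennes bioheat solver in temperature-increase form with thermoregulation.

Solves, per voxel,

    rho c_p dDT/dt = div(lambda grad DT) - 2^(DT/DB) h_b0 DT
                     + (1.1^DT - 1) P_met0 + P_em

for the temperature elevation DT above the resting state, so the resting
temperature field never needs to be known.  Blood perfusion responds to local
heating through the multiplier L_B = 2^(DT/DB) (DB = 1.6 K), capped at 15
(32 on skin); metabolic heat scales as 1.1^DT.  A Robin condition
lambda dDT/dn = -h_amb DT (h_amb = 7 W/(m^2 K)) applies on tissue-air faces;
the grid boundary itself is adiabatic, so phantoms should keep an air margin.

Time stepping uses the Douglas-Gunn alternating-direction-implicit splitting
(three directional tridiagonal solves per step, second-order in time for the
linear part); the nonlinear perfusion/metabolic terms are lagged one step
(Picard linearization), which is accurate for the sub-second steps used here
because the perfusion relaxation time rho c_p / h_b0 is O(10^3 s).
Heterogeneous conductivity enters through harmonic-mean face values, so
implant metal participates in conduction while carrying zero perfusion and
metabolism.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .phantom import TissueModel
from .power import PowerMap

DEFAULT_H_AMB = 7.0  # W/(m^2 K)


@dataclass(frozen=True)
class ThermoregulationModel:
    """Parameters of the instantaneous local thermoregulation response."""

    delta_B: float = 1.6  # K, perfusion doubling scale
    L_B_cap_default: float = 15.0
    L_B_cap_skin: float = 32.0
    metabolic_base: float = 1.1  # per K

    def __post_init__(self) -> None:
        if self.delta_B <= 0:
            raise ValueError("delta_B must be > 0")
        if self.L_B_cap_default < 1 or self.L_B_cap_skin < 1:
            raise ValueError("perfusion caps must be >= 1")


def thermoreg_multipliers(delta_T, thermo: ThermoregulationModel = ThermoregulationModel(),
                          is_skin=False):
    """Perfusion multiplier L_B and metabolic source factor for a given DT.

    L_B = min(cap, 2^(DT/delta_B)) for DT > 0, clamped at 1 for DT <= 0
    (no perfusion reduction on cooling); the metabolic factor is
    1.1^DT - 1 (negative below the resting temperature).
    """
    delta_T = np.asarray(delta_T, dtype=float)
    cap = np.where(is_skin, thermo.L_B_cap_skin, thermo.L_B_cap_default)
    L_B = np.minimum(cap, np.exp2(np.maximum(delta_T, 0.0) / thermo.delta_B))
    L_met = thermo.metabolic_base**delta_T - 1.0
    if delta_T.ndim == 0:
        return float(L_B), float(L_met)
    return L_B, L_met


@dataclass
class ThermalState:
    """Temperature-increase field at one instant."""

    delta_T: np.ndarray
    time: float

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.delta_T)):
            raise ValueError("delta_T must be finite")


@dataclass
class ThermalResult:
    """Output of a bioheat solve: snapshots, history and crossing times."""

    snapshots: dict[float, np.ndarray]
    final: ThermalState
    times: np.ndarray
    max_history: np.ndarray  # running max-over-grid delta_T per step
    crossing_time: dict[float, np.ndarray]  # threshold -> per-voxel time (nan = never)
    thresholds: tuple[float, ...] = field(default_factory=tuple)


class InstabilityError(RuntimeError):
    pass


class BioheatSolver:
    """Douglas-Gunn bioheat stepper bound to one tissue model.

    Precomputes face conductances, Robin sink coefficients and the
    thermoregulation lookup grids; reusable across power cases.
    """

    def __init__(self, model: TissueModel,
                 thermo: ThermoregulationModel = ThermoregulationModel(),
                 h_amb: float = DEFAULT_H_AMB):
        self.model = model
        self.thermo = thermo
        self.h_amb = h_amb
        h = model.spacing
        lam = model.field_grid("lambda_th")
        rho = model.field_grid("rho")
        c_p = model.field_grid("c_p")
        cap_vol = rho * c_p
        body = model.body_mask()
        inv_cap = np.where(body, 1.0 / np.where(cap_vol > 0, cap_vol, 1.0), 0.0)
        self._ich2 = np.ascontiguousarray(inv_cap / h**2)
        self._cond = []
        self._robin = []
        for d in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[d] = slice(None, -1)
            hi[d] = slice(1, None)
            l1, l2 = lam[tuple(lo)], lam[tuple(hi)]
            b1, b2 = body[tuple(lo)], body[tuple(hi)]
            with np.errstate(divide="ignore", invalid="ignore"):
                cond = np.where(b1 & b2, 2 * l1 * l2 / (l1 + l2), 0.0)
            self._cond.append(np.ascontiguousarray(cond))
            # Robin sink: tissue faces exposed to air inside the grid
            n_air = np.zeros(model.shape)
            lo_air = b1 & ~b2  # lower voxel tissue, upper air
            hi_air = b2 & ~b1
            n_air[tuple(lo)] += lo_air
            n_air[tuple(hi)] += hi_air
            self._robin.append(np.ascontiguousarray(h_amb * n_air * inv_cap / h))
        self._hb0_ic = np.ascontiguousarray(model.field_grid("h_b0") * inv_cap)
        self._pmet_ic = np.ascontiguousarray(model.field_grid("P_met0") * inv_cap)
        cap_grid = np.where(model.skin_mask(), thermo.L_B_cap_skin,
                            thermo.L_B_cap_default)
        self._cap = np.ascontiguousarray(cap_grid.astype(float))
        self._inv_cap = inv_cap
        shape = model.shape
        self._Ax = np.empty(shape)
        self._Ay = np.empty(shape)
        self._Az = np.empty(shape)
        self._scratch = np.empty(shape)
        self._src = np.empty(shape)

    def step(self, delta_T: np.ndarray, dt: float, P_em: np.ndarray) -> np.ndarray:
        """Advance the field one Douglas-Gunn step; returns a new array."""
        if dt <= 0:
            raise ValueError("dt must be > 0")
        T = delta_T
        cx, cy, cz = self._cond
        rx, ry, rz = self._robin
        _kernels.apply_ops(T, cx, cy, cz, rx, ry, rz, self._ich2,
                           self._Ax, self._Ay, self._Az)
        _kernels.reaction_source(
            T, self._hb0_ic, self._pmet_ic,
            np.ascontiguousarray(P_em * self._inv_cap),
            1.0 / self.thermo.delta_B, self._cap,
            np.log(self.thermo.metabolic_base), self._src,
        )
        theta_dt = 0.5 * dt
        R = T + dt * (0.5 * self._Ax + self._Ay + self._Az + self._src)
        out = np.empty_like(T)
        _kernels.solve_x(R, cx, rx, self._ich2, theta_dt, out)
        R = out - theta_dt * self._Ay
        _kernels.solve_y(R, cy, ry, self._ich2, theta_dt, self._scratch)
        R = self._scratch - theta_dt * self._Az
        _kernels.solve_z(R, cz, rz, self._ich2, theta_dt, out)
        if not np.all(np.isfinite(out)):
            bad = np.unravel_index(int(np.argmax(~np.isfinite(out))), out.shape)
            raise InstabilityError(
                f"non-finite temperature update at voxel {bad} with dt={dt}"
            )
        return out

    def solve(self, power: PowerMap, duration: float,
              snapshot_times=(), thresholds=(1.0, 3.0),
              initial: np.ndarray | None = None) -> ThermalResult:
        """March the schedule-averaged power over ``duration`` seconds."""
        dt = power.step_duration
        n_steps = int(round(duration / dt))
        if n_steps > power.n_steps:
            raise ValueError(
                f"power map covers {power.n_steps * dt:.1f} s "
                f"< requested {duration} s"
            )
        T = np.zeros(self.model.shape) if initial is None else initial.copy()
        snap_steps = {int(round(t / dt)): t for t in snapshot_times}
        snapshots: dict[float, np.ndarray] = {}
        if 0 in snap_steps:
            snapshots[snap_steps[0]] = T.copy()
        max_hist = np.zeros(n_steps + 1)
        crossing = {thr: np.full(self.model.shape, np.nan) for thr in thresholds}
        t_prev = T
        for s in range(1, n_steps + 1):
            T = self.step(T, dt, power.step_power(s - 1))
            max_hist[s] = T.max()
            for thr, ct in crossing.items():
                newly = np.isnan(ct) & (T > thr)
                if newly.any():
                    # linear interpolation of the first crossing inside the step
                    T0 = t_prev[newly]
                    T1 = T[newly]
                    frac = np.clip((thr - T0) / np.maximum(T1 - T0, 1e-300), 0, 1)
                    ct[newly] = (s - 1 + frac) * dt
            if s in snap_steps:
                snapshots[snap_steps[s]] = T.copy()
            t_prev = T
        return ThermalResult(
            snapshots=snapshots,
            final=ThermalState(T, n_steps * dt),
            times=np.arange(n_steps + 1) * dt,
            max_history=max_hist,
            crossing_time=crossing,
            thresholds=tuple(thresholds),
        )


def step(state: ThermalState, dt: float, model: TissueModel,
         thermo: ThermoregulationModel, P_em: np.ndarray) -> ThermalState:
    """One Douglas-Gunn step (convenience wrapper building a fresh solver)."""
    solver = BioheatSolver(model, thermo)
    return ThermalState(solver.step(state.delta_T, dt, P_em), state.time + dt)


def solve(model: TissueModel, thermo: ThermoregulationModel, power: PowerMap,
          duration: float, snapshot_times=(), thresholds=(1.0, 3.0)) -> ThermalResult:
    """Full marching solve (convenience wrapper; see BioheatSolver.solve)."""
    return BioheatSolver(model, thermo).solve(
        power, duration, snapshot_times, thresholds
    )
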