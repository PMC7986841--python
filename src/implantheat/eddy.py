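"""Quasi-static voxel eddy-current solver for the metallic implant.

For a time-harmonic gradient field with vector potential phasor ``c * a(r)``
(``a`` per unit gradient strength), the induced electric field in the metal
is ``E = -j w c (a + grad psi)`` where the scalar ``psi`` enforces charge
conservation ``div(sigma E) = 0`` with zero normal current on the metal
surface.  In this resistive limit (skin depth large compared to the part
thickness; the reaction field of the eddy currents is neglected) ``psi`` is
real and frequency independent, so a single potential solve per coil axis
serves every harmonic: the per-harmonic current phasor is
``J_k = -j w_k c_k sigma F`` with the basis field ``F = a + grad psi``.

The solver discretizes conservation with a face-flux finite-volume scheme on
the metal voxels (harmonic-mean face conductivities) and grounds one node per
connected metal component.  A warning is logged when the skin depth at a
retained harmonic drops below the smallest implant part dimension, where the
resistive limit degrades.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, sparse
from scipy.sparse.linalg import splu

from .gradients import MU_0, CoilModel, HarmonicSet, vector_potential
from .phantom import TissueModel


def skin_depth(sigma: float, frequency: float, mu_r: float = 1.0) -> float:
    """delta = sqrt(2 / (mu sigma omega)), m."""
    omega = 2 * np.pi * frequency
    return np.sqrt(2.0 / (MU_0 * mu_r * sigma * omega))


@dataclass
class EddyBasis:
    """Frequency-independent solution basis on the metal voxels.

    ``F`` maps coil axis -> (n_metal, 3) real field ``a + grad psi`` per unit
    gradient; ``J(t) = -sigma F_axis dG_axis/dt`` superposed over axes.
    """

    F: dict[int, np.ndarray]
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    sigma: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    residuals: dict[int, float]

    @property
    def n_voxels(self) -> int:
        return self.sigma.size


@dataclass
class EddySolution:
    """Complex current-density phasor per metal voxel for one harmonic."""

    J: np.ndarray  # (n_metal, 3), A/m^2
    indices: tuple[np.ndarray, np.ndarray, np.ndarray]
    sigma: np.ndarray
    spacing: float
    shape: tuple[int, int, int]
    frequency: float
    residual: float

    def current_density_grid(self) -> np.ndarray:
        out = np.zeros((*self.shape, 3), dtype=complex)
        out[self.indices] = self.J
        return out

    def total_power(self) -> float:
        """Time-averaged dissipated power, W: sum |J|^2 / (2 sigma) * V."""
        p = np.sum(np.abs(self.J) ** 2, axis=1) / (2 * self.sigma)
        return float(p.sum() * self.spacing**3)


class _PotentialProblem:
    """Face-flux discretization of div(sigma(grad psi + a)) = 0 on the metal."""

    def __init__(self, model: TissueModel):
        sigma_grid = model.field_grid("sigma")
        metal = model.implant_mask & (sigma_grid > 0)
        if not metal.any():
            raise ValueError("metal mask is empty")
        self.model = model
        self.metal = metal
        self.h = model.spacing
        self.indices = np.nonzero(metal)
        self.n = len(self.indices[0])
        self.sigma = sigma_grid[self.indices]
        idx_grid = np.full(metal.shape, -1, dtype=np.int64)
        idx_grid[self.indices] = np.arange(self.n)
        self.idx_grid = idx_grid
        # internal faces per axis: pairs (i, j) of flat unknown ids + face conductivity
        self.faces: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
        rows, cols, vals = [], [], []
        diag = np.zeros(self.n)
        for d in range(3):
            sl_lo = [slice(None)] * 3
            sl_hi = [slice(None)] * 3
            sl_lo[d] = slice(None, -1)
            sl_hi[d] = slice(1, None)
            both = metal[tuple(sl_lo)] & metal[tuple(sl_hi)]
            ii = idx_grid[tuple(sl_lo)][both]
            jj = idx_grid[tuple(sl_hi)][both]
            s_lo = sigma_grid[tuple(sl_lo)][both]
            s_hi = sigma_grid[tuple(sl_hi)][both]
            s_face = 2 * s_lo * s_hi / (s_lo + s_hi)
            w = s_face * self.h  # sigma * area / spacing
            self.faces.append((ii, jj, s_face))
            rows.extend([ii, jj])
            cols.extend([jj, ii])
            vals.extend([-w, -w])
            np.add.at(diag, ii, w)
            np.add.at(diag, jj, w)
        rows.append(np.arange(self.n))
        cols.append(np.arange(self.n))
        # ground one node per connected component to fix the potential gauge
        labels, n_comp = ndimage.label(metal)
        comp = labels[self.indices]
        pin = np.zeros(self.n)
        for c in range(1, n_comp + 1):
            pin[np.argmax(comp == c)] = 1.0
        vals.append(diag + pin)
        L = sparse.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )
        self.lu = splu(L)
        self.L = L

    def coords(self) -> np.ndarray:
        pts = np.stack(self.indices, axis=1) * self.h + self.model.origin
        return pts

    def solve_axis(self, a_at, axis_points=None) -> tuple[np.ndarray, float]:
        """Solve for F = a + grad psi given a callable a_at(points)->(n,3)."""
        h = self.h
        pts = self.coords()
        a_center = a_at(pts)
        b = np.zeros(self.n)
        face_a = []
        for d, (ii, jj, s_face) in enumerate(self.faces):
            mid = (pts[ii] + pts[jj]) / 2
            a_d = a_at(mid)[:, d]
            face_a.append(a_d)
            w = s_face * h
            np.add.at(b, ii, -w * h * a_d)
            np.add.at(b, jj, +w * h * a_d)
        # sign: (L psi)_i = sum_f w (psi_i - psi_j); conservation requires
        # L psi = -sum_f(+) w h a_d + sum_f(-) w h a_d, handled above.
        psi = self.lu.solve(b)
        res = np.linalg.norm(self.L @ psi - b) / max(np.linalg.norm(b), 1e-300)
        if res > 1e-8:
            raise RuntimeError(f"potential solve did not converge: residual {res:.2e}")

        # gradient of psi at voxel centers: average the lower/upper face
        # gradients per axis; at surface faces the Neumann condition
        # grad psi . n = -a_n supplies the value, keeping E . n = 0 there.
        grad = np.empty((self.n, 3))
        for d in range(3):
            ii, jj, _ = self.faces[d]
            mid = pts.copy()
            mid[:, d] -= h / 2
            g_lo = -a_at(mid)[:, d]
            mid[:, d] += h
            g_hi = -a_at(mid)[:, d]
            gface = (psi[jj] - psi[ii]) / h
            g_hi[ii] = gface
            g_lo[jj] = gface
            grad[:, d] = (g_lo + g_hi) / 2
        return a_center + grad, res


def solve_eddy_basis(model: TissueModel, coil: CoilModel,
                     axes=(0, 1, 2)) -> EddyBasis:
    """Unit-gradient basis fields F = a + grad psi for the requested axes."""
    prob = _PotentialProblem(model)
    F: dict[int, np.ndarray] = {}
    residuals: dict[int, float] = {}
    for axis in axes:
        F[axis], residuals[axis] = prob.solve_axis(
            lambda pts, ax=axis: vector_potential(coil, pts, ax, 1.0)
        )
    return EddyBasis(
        F=F, indices=prob.indices, sigma=prob.sigma, spacing=prob.h,
        shape=model.labels.shape, residuals=residuals,
    )


def uniform_b_potential(b_z: float):
    """Symmetric-gauge vector potential of a uniform axial field B = b_z z_hat."""

    def a_at(points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(points)
        A = np.zeros_like(points)
        A[:, 0] = -b_z * points[:, 1] / 2
        A[:, 1] = +b_z * points[:, 0] / 2
        return A

    return a_at


def solve_eddy_harmonic(model: TissueModel, frequency: float, a_source,
                        amplitude: complex = 1.0) -> EddySolution:
    """Current-density phasor for one harmonic source.

    ``a_source`` is a callable mapping points (n, 3) to the vector potential
    (n, 3) of the unit source; ``amplitude`` is the complex harmonic
    coefficient.  The returned phasor is ``J = -j w amp sigma (a + grad psi)``
    on the metal voxels and zero elsewhere.  A skin-depth warning is issued
    when the resistive limit is strained.
    """
    if frequency < 0:
        raise ValueError("frequency must be >= 0")
    prob = _PotentialProblem(model)
    F, res = prob.solve_axis(a_source)
    omega = 2 * np.pi * frequency
    _skin_depth_check(prob, frequency)
    J = (-1j * omega * amplitude) * (prob.sigma[:, None] * F)
    return EddySolution(
        J=J, indices=prob.indices, sigma=prob.sigma, spacing=prob.h,
        shape=model.labels.shape, frequency=frequency, residual=res,
    )


def _skin_depth_check(prob: _PotentialProblem, frequency: float) -> None:
    if frequency <= 0:
        return
    delta = skin_depth(float(prob.sigma.max()), frequency)
    # smallest part dimension: estimated from the metal-mask thickness
    thickness = _min_part_thickness(prob.metal, prob.h)
    if delta < thickness:
        warnings.warn(
            f"skin depth {delta * 1e3:.1f} mm below part thickness "
            f"{thickness * 1e3:.1f} mm at {frequency:.0f} Hz: the resistive-limit "
            "solution underestimates shielding",
            stacklevel=3,
        )


def _min_part_thickness(metal: np.ndarray, h: float) -> float:
    """Smallest characteristic thickness over the connected metal parts."""
    labels, n_comp = ndimage.label(metal)
    dist = ndimage.distance_transform_edt(metal) * h
    return min(
        2 * float(dist[labels == c].max()) for c in range(1, n_comp + 1)
    )


def max_retained_frequency(harmonics: HarmonicSet) -> float:
    freqs = harmonics.all_frequencies()
    return float(freqs.max()) if freqs.size else 0.0


# ---------------------------------------------------------------------------
# Time-domain reconstruction and power maps
# ---------------------------------------------------------------------------

def _gradient_derivative(harmonics: HarmonicSet, axis: int,
                         t: np.ndarray) -> np.ndarray:
    """dG_axis/dt reconstructed from the retained harmonics at times t (s).

    Times are interpreted modulo the interval Delta; each subsignal
    contributes on its own window.
    """
    tm = np.mod(t, harmonics.delta_interval)
    out = np.zeros_like(tm)
    dt = harmonics.dt
    for h in harmonics.per_axis[axis]:
        t0 = h.start * dt
        t1 = t0 + h.n_samples * dt
        in_win = (tm >= t0) & (tm < t1)
        if not in_win.any():
            continue
        tau = tm[in_win] - t0
        phase = np.exp(2j * np.pi * np.outer(h.frequencies, tau))
        deriv = (2j * np.pi * h.frequencies * h.coefficients) @ phase
        out[in_win] = np.real(deriv)
    return out


def reconstruct_power(basis: EddyBasis, harmonics: HarmonicSet,
                      t_grid: np.ndarray) -> np.ndarray:
    """Instantaneous P_GC(t) per metal voxel, W/m^3, shape (n_t, n_metal).

    Superposes the per-axis current contributions (vector addition before
    squaring) at the requested times, which are taken modulo Delta.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    missing = [a for a in range(3) if a not in basis.F]
    if any(len(harmonics.per_axis[a]) > 0 and a in missing for a in range(3)):
        raise ValueError(f"missing eddy basis for axes {missing}")
    dG = np.stack([
        _gradient_derivative(harmonics, axis, t_grid) if axis in basis.F
        else np.zeros_like(t_grid)
        for axis in range(3)
    ])  # (3, n_t)
    # J(t) = -sigma sum_a F_a dG_a ; P = |J|^2 / sigma
    P = np.zeros((t_grid.size, basis.n_voxels))
    for comp in range(3):
        Fc = np.stack([basis.F[a][:, comp] if a in basis.F else
                       np.zeros(basis.n_voxels) for a in range(3)])  # (3, n_metal)
        Jc = dG.T @ Fc  # (n_t, n_metal), sign irrelevant after squaring
        P += Jc**2
    return P * basis.sigma[None, :]


def mean_power_map(basis: EddyBasis, harmonics: HarmonicSet,
                   oversample: int = 1) -> np.ndarray:
    """Time-averaged P_GC over the interval Delta per metal voxel, W/m^3.

    Uses the exact quadratic form P_avg = sigma * sum_ab (F_a . F_b) M_ab
    with M the covariance of the reconstructed gradient derivatives over
    Delta, so cross-axis correlations are retained.
    """
    n = max(2, int(round(harmonics.delta_interval / harmonics.dt)) * oversample)
    t = (np.arange(n) + 0.5) * (harmonics.delta_interval / n)
    dG = np.stack([
        _gradient_derivative(harmonics, axis, t) if axis in basis.F
        else np.zeros_like(t)
        for axis in range(3)
    ])
    M = dG @ dG.T / n  # (3, 3) time-averaged dG_a dG_b
    P = np.zeros(basis.n_voxels)
    for a in range(3):
        for b in range(3):
            if M[a, b] == 0 or a not in basis.F or b not in basis.F:
                continue
            P += M[a, b] * np.einsum("ij,ij->i", basis.F[a], basis.F[b])
    return P * basis.sigma


def mean_power_grid(basis: EddyBasis, harmonics: HarmonicSet) -> np.ndarray:
    """Delta-averaged P_GC on the full voxel grid (zero outside the metal)."""
    out = np.zeros(basis.shape)
    out[basis.indices] = mean_power_map(basis, harmonics)
    return out
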