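"""Numba kernels for the Douglas-Gunn time-split bioheat scheme.

Air voxels carry zero heat capacity and zero face conductance, which makes
their tridiagonal rows identity rows; the kernels therefore sweep the full
grid without masking.  ``ich2`` is 1/(rho c_p h^2) per voxel (zero on air),
``cx/cy/cz`` are harmonic-mean face conductivities (W/(m K), zero toward
air), and ``rx/ry/rz`` are the per-axis Robin sink coefficients
h_amb * n_air_faces / (rho c_p h), 1/s.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def apply_ops(T, cx, cy, cz, rx, ry, rz, ich2, Ax, Ay, Az):
    """Per-axis diffusion (+Robin) operators applied to T."""
    nx, ny, nz = T.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                t = T[i, j, k]
                c = ich2[i, j, k]
                ax = 0.0
                if i > 0:
                    ax += cx[i - 1, j, k] * (T[i - 1, j, k] - t)
                if i < nx - 1:
                    ax += cx[i, j, k] * (T[i + 1, j, k] - t)
                Ax[i, j, k] = c * ax - rx[i, j, k] * t
                ay = 0.0
                if j > 0:
                    ay += cy[i, j - 1, k] * (T[i, j - 1, k] - t)
                if j < ny - 1:
                    ay += cy[i, j, k] * (T[i, j + 1, k] - t)
                Ay[i, j, k] = c * ay - ry[i, j, k] * t
                az = 0.0
                if k > 0:
                    az += cz[i, j, k - 1] * (T[i, j, k - 1] - t)
                if k < nz - 1:
                    az += cz[i, j, k] * (T[i, j, k + 1] - t)
                Az[i, j, k] = c * az - rz[i, j, k] * t
    return


@njit(cache=True, fastmath=True)
def solve_x(R, cx, rx, ich2, theta_dt, out):
    """(I - theta_dt * A_x) out = R, Thomas sweeps along axis 0."""
    nx, ny, nz = R.shape
    cp = np.empty(nx)
    dp = np.empty(nx)
    for j in range(ny):
        for k in range(nz):
            for i in range(nx):
                c = ich2[i, j, k]
                clo = cx[i - 1, j, k] if i > 0 else 0.0
                chi = cx[i, j, k] if i < nx - 1 else 0.0
                diag = 1.0 + theta_dt * (c * (clo + chi) + rx[i, j, k])
                sub = -theta_dt * c * clo
                sup = -theta_dt * c * chi
                if i == 0:
                    cp[0] = sup / diag
                    dp[0] = R[0, j, k] / diag
                else:
                    m = diag - sub * cp[i - 1]
                    cp[i] = sup / m
                    dp[i] = (R[i, j, k] - sub * dp[i - 1]) / m
            out[nx - 1, j, k] = dp[nx - 1]
            for i in range(nx - 2, -1, -1):
                out[i, j, k] = dp[i] - cp[i] * out[i + 1, j, k]
    return


@njit(cache=True, fastmath=True)
def solve_y(R, cy, ry, ich2, theta_dt, out):
    """(I - theta_dt * A_y) out = R, Thomas sweeps along axis 1."""
    nx, ny, nz = R.shape
    cp = np.empty(ny)
    dp = np.empty(ny)
    for i in range(nx):
        for k in range(nz):
            for j in range(ny):
                c = ich2[i, j, k]
                clo = cy[i, j - 1, k] if j > 0 else 0.0
                chi = cy[i, j, k] if j < ny - 1 else 0.0
                diag = 1.0 + theta_dt * (c * (clo + chi) + ry[i, j, k])
                sub = -theta_dt * c * clo
                sup = -theta_dt * c * chi
                if j == 0:
                    cp[0] = sup / diag
                    dp[0] = R[i, 0, k] / diag
                else:
                    m = diag - sub * cp[j - 1]
                    cp[j] = sup / m
                    dp[j] = (R[i, j, k] - sub * dp[j - 1]) / m
            out[i, ny - 1, k] = dp[ny - 1]
            for j in range(ny - 2, -1, -1):
                out[i, j, k] = dp[j] - cp[j] * out[i, j + 1, k]
    return


@njit(cache=True, fastmath=True)
def solve_z(R, cz, rz, ich2, theta_dt, out):
    """(I - theta_dt * A_z) out = R, Thomas sweeps along axis 2."""
    nx, ny, nz = R.shape
    cp = np.empty(nz)
    dp = np.empty(nz)
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                c = ich2[i, j, k]
                clo = cz[i, j, k - 1] if k > 0 else 0.0
                chi = cz[i, j, k] if k < nz - 1 else 0.0
                diag = 1.0 + theta_dt * (c * (clo + chi) + rz[i, j, k])
                sub = -theta_dt * c * clo
                sup = -theta_dt * c * chi
                if k == 0:
                    cp[0] = sup / diag
                    dp[0] = R[i, j, 0] / diag
                else:
                    m = diag - sub * cp[k - 1]
                    cp[k] = sup / m
                    dp[k] = (R[i, j, k] - sub * dp[k - 1]) / m
            out[i, j, nz - 1] = dp[nz - 1]
            for k in range(nz - 2, -1, -1):
                out[i, j, k] = dp[k] - cp[k] * out[i, j, k + 1]
    return


@njit(cache=True, fastmath=True)
def reaction_source(T, hb0_ic, pmet_ic, pem_ic, inv_db, cap, lmet_log, out):
    """Lagged nonlinear terms: out = (-L_B h_b0 T + (1.1^T - 1) P_met0 + P_em)/(rho c_p).

    ``hb0_ic``, ``pmet_ic`` and ``pem_ic`` are already divided by rho c_p;
    ``cap`` is the per-voxel perfusion multiplier cap; ``inv_db`` = 1/Delta_B;
    ``lmet_log`` = ln(1.1).
    """
    nx, ny, nz = T.shape
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                t = T[i, j, k]
                if t > 0.0:
                    lb = 2.0 ** (t * inv_db)
                    if lb > cap[i, j, k]:
                        lb = cap[i, j, k]
                    lmet = np.exp(lmet_log * t) - 1.0
                else:
                    lb = 1.0
                    lmet = np.exp(lmet_log * t) - 1.0
                out[i, j, k] = (
                    -lb * hb0_ic[i, j, k] * t
                    + lmet * pmet_ic[i, j, k]
                    + pem_ic[i, j, k]
                )
    return
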