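import numpy as np
import pytest

from conftest import disk_model
from implantheat import eddy
from implantheat.gradients import CoilModel, HarmonicSet, Harmonics
from implantheat.properties import COCRMO

SIGMA = COCRMO.sigma


def disk_power(radius, thickness, sigma, omega, b):
    """Analytic resistive-limit power of a thin disk under uniform axial B."""
    return sigma * omega**2 * b**2 * np.pi * thickness * radius**4 / 16


class TestHarmonicSolver:
    def test_disk_oracle_coarse(self):
        a, t, h = 0.030, 0.008, 0.002
        model = disk_model(a, t, h)
        B, f = 5e-3, 1e3
        sol = eddy.solve_eddy_harmonic(model, f, eddy.uniform_b_potential(B))
        ref = disk_power(a, t, SIGMA, 2 * np.pi * f, B)
        assert sol.total_power() == pytest.approx(ref, rel=0.10)

    def test_zero_source_gives_zero_currents(self):
        model = disk_model(0.02, 0.008, 0.002)
        sol = eddy.solve_eddy_harmonic(model, 1e3, eddy.uniform_b_potential(0.0))
        assert np.allclose(sol.J, 0)
        assert sol.total_power() == 0.0

    def test_power_quadratic_in_amplitude(self):
        model = disk_model(0.02, 0.008, 0.002)
        p1 = eddy.solve_eddy_harmonic(model, 1e3, eddy.uniform_b_potential(1e-3)).total_power()
        p2 = eddy.solve_eddy_harmonic(model, 1e3, eddy.uniform_b_potential(2e-3)).total_power()
        assert p2 == pytest.approx(4 * p1, rel=1e-9)

    def test_power_quadratic_in_frequency(self):
        model = disk_model(0.02, 0.008, 0.002)
        p1 = eddy.solve_eddy_harmonic(model, 500.0, eddy.uniform_b_potential(1e-3)).total_power()
        p2 = eddy.solve_eddy_harmonic(model, 1000.0, eddy.uniform_b_potential(1e-3)).total_power()
        assert p2 == pytest.approx(4 * p1, rel=1e-9)

    def test_charge_conservation_residual(self):
        model = disk_model(0.02, 0.008, 0.002)
        sol = eddy.solve_eddy_harmonic(model, 1e3, eddy.uniform_b_potential(1e-3))
        assert sol.residual < 1e-10

    def test_currents_zero_outside_metal(self):
        model = disk_model(0.02, 0.008, 0.002)
        sol = eddy.solve_eddy_harmonic(model, 1e3, eddy.uniform_b_potential(1e-3))
        grid = sol.current_density_grid()
        outside = ~model.metal_mask()
        assert np.allclose(grid[outside], 0)

    def test_empty_metal_rejected(self):
        model = disk_model(0.02, 0.008, 0.002)
        model.labels[:] = 0
        model.implant_mask[:] = False
        with pytest.raises(ValueError):
            eddy.solve_eddy_harmonic(model, 1e3, eddy.uniform_b_potential(1e-3))

    def test_skin_depth_value(self):
        # CoCrMo at 1 kHz: ~14.8 mm penetration
        assert eddy.skin_depth(SIGMA, 1e3) == pytest.approx(14.8e-3, rel=0.01)


def _single_tone_harmonics(dt, n, delta, freq_coeff_per_axis):
    """HarmonicSet with one full-interval subsignal per axis."""
    per_axis = []
    for axis in range(3):
        entries = freq_coeff_per_axis.get(axis, [])
        if entries:
            f = np.array([e[0] for e in entries], dtype=float)
            c = np.array([e[1] for e in entries], dtype=complex)
            per_axis.append([Harmonics(f, c, n, dt, 1.0, start=0)])
        else:
            per_axis.append([])
    return HarmonicSet(per_axis=per_axis, dt=dt, delta_interval=delta)


@pytest.fixture(scope="module")
def setup():
    model = disk_model(0.02, 0.008, 0.002)
    basis = eddy.solve_eddy_basis(model, CoilModel())
    return model, basis


class TestReconstruction:

    def test_single_harmonic_average_is_half_peak(self, setup):
        """Sinusoidal single-axis drive: <P(t)> = peak/2 per voxel."""
        model, basis = setup
        f0, amp = 1e3, 10e-3  # 10 mT/m on the z coil
        n = 1000
        dt = 1.0 / (f0 * n) * 50  # 20 samples per cycle, 50 cycles
        delta = n * dt
        hs = _single_tone_harmonics(dt, n, delta, {2: [(f0, amp)]})
        t = np.linspace(0, delta, 4001, endpoint=False)
        P = eddy.reconstruct_power(basis, hs, t)
        assert np.allclose(P.mean(axis=0), P.max(axis=0) / 2, rtol=1e-3, atol=1e-12)
        avg = eddy.mean_power_map(basis, hs)
        assert np.allclose(P.mean(axis=0), avg, rtol=1e-3, atol=1e-12)

    def test_two_axis_contributions_superpose_before_squaring(self, setup):
        """P(x+y drive) differs from P(x) + P(y): the current densities add
        vectorially.  Cross-checked against brute-force phasor evaluation."""
        model, basis = setup
        f0, amp = 1e3, 10e-3
        n = 1000
        dt = 1.0 / (f0 * 20)
        delta = n * dt
        both = _single_tone_harmonics(dt, n, delta, {0: [(f0, amp)], 1: [(f0, 1j * amp)]})
        only_x = _single_tone_harmonics(dt, n, delta, {0: [(f0, amp)]})
        only_y = _single_tone_harmonics(dt, n, delta, {1: [(f0, 1j * amp)]})
        t = np.linspace(0, 1 / f0, 64, endpoint=False)
        P_both = eddy.reconstruct_power(basis, both, t)
        P_x = eddy.reconstruct_power(basis, only_x, t)
        P_y = eddy.reconstruct_power(basis, only_y, t)
        assert not np.allclose(P_both, P_x + P_y, rtol=1e-3)

        # brute force: J(t) = -sigma (F_x Re[dG_x] + F_y Re[dG_y])
        omega = 2 * np.pi * f0
        dgx = np.real(1j * omega * amp * np.exp(1j * omega * t))
        dgy = np.real(1j * omega * 1j * amp * np.exp(1j * omega * t))
        J = -(basis.sigma[None, :, None]
              * (basis.F[0][None] * dgx[:, None, None]
                 + basis.F[1][None] * dgy[:, None, None]))
        P_ref = np.sum(J**2, axis=2) / basis.sigma[None, :]
        assert np.allclose(P_both, P_ref, rtol=1e-9, atol=1e-12)

    def test_all_zero_gradients_give_zero_power(self, setup):
        model, basis = setup
        hs = _single_tone_harmonics(4e-6, 100, 4e-4, {})
        P = eddy.reconstruct_power(basis, hs, np.linspace(0, 4e-4, 11))
        assert np.all(P == 0)

    def test_energy_bookkeeping_against_time_integral(self, setup):
        """Delta-averaged power map equals the fine time integral (Parseval)."""
        model, basis = setup
        f0 = 1e3
        n = 2000
        dt = 1.0 / (f0 * 20)
        delta = n * dt
        hs = _single_tone_harmonics(
            dt, n, delta,
            {0: [(f0, 5e-3), (3 * f0, 2e-3)], 2: [(2 * f0, 4e-3)]},
        )
        t = (np.arange(8000) + 0.5) * (delta / 8000)
        P_t = eddy.reconstruct_power(basis, hs, t)
        avg = eddy.mean_power_map(basis, hs)
        total_t = P_t.mean(axis=0).sum()
        assert total_t == pytest.approx(avg.sum(), rel=1e-6)
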