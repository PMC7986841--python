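import numpy as np
import pytest
from scipy.optimize import brentq

from conftest import uniform_block
from implantheat.bioheat import (
    BioheatSolver,
    ThermoregulationModel,
    thermoreg_multipliers,
)
from implantheat.phantom import TissueModel
from implantheat.power import PowerMap
from implantheat.properties import LABEL_FAT, LABEL_MUSCLE, FAT, MUSCLE

LINEAR = ThermoregulationModel(L_B_cap_default=1.0, L_B_cap_skin=1.0,
                               metabolic_base=1.0)  # thermoregulation disabled


def steady_power_map(P, n_steps, dt):
    return PowerMap("P1", P, np.ones(n_steps), dt)


class TestThermoregMultipliers:
    def test_rest_state(self):
        assert thermoreg_multipliers(0.0) == (1.0, 0.0)

    def test_doubling_at_delta_b(self):
        L_B, _ = thermoreg_multipliers(1.6)
        assert L_B == 2.0

    def test_cap_engages_above_limit(self):
        # 2^(6.5/1.6) = 16.7 > 15: the generic cap engages
        L_B, _ = thermoreg_multipliers(6.5)
        assert L_B == 15.0
        L_B_skin, _ = thermoreg_multipliers(6.5, is_skin=True)
        assert L_B_skin == pytest.approx(2 ** (6.5 / 1.6))
        assert thermoreg_multipliers(9.0, is_skin=True)[0] == 32.0

    def test_no_perfusion_reduction_on_cooling(self):
        L_B, L_met = thermoreg_multipliers(-2.0)
        assert L_B == 1.0
        assert L_met == pytest.approx(1.1**-2 - 1)

    def test_metabolic_factor(self):
        _, L_met = thermoreg_multipliers(3.0)
        assert L_met == pytest.approx(1.1**3 - 1)


class TestStep:
    def test_zero_power_keeps_zero_field(self):
        block = uniform_block((8, 8, 8), air_margin=1)
        solver = BioheatSolver(block)
        T = solver.step(np.zeros(block.shape), 0.1, np.zeros(block.shape))
        assert np.all(T == 0)

    def test_nonnegative_under_nonnegative_power(self):
        block = uniform_block((10, 10, 10), air_margin=1)
        solver = BioheatSolver(block)
        rng = np.random.default_rng(1)
        P = rng.uniform(0, 1e4, block.shape) * block.body_mask()
        T = np.zeros(block.shape)
        for _ in range(20):
            T = solver.step(T, 0.5, P)
        assert T.min() >= -1e-12

    def test_invalid_dt_rejected(self):
        block = uniform_block((4, 4, 4))
        solver = BioheatSolver(block)
        with pytest.raises(ValueError):
            solver.step(np.zeros(block.shape), 0.0, np.zeros(block.shape))


class TestSteadyStateOracle:
    def test_uniform_perfusion_nonlinear_root(self):
        """h_b0 = P_em = 2700 W/(m^3 K), W/m^3: steady DT solves
        2^(x/1.6) x = 1, x ~= 0.729 K."""
        props = MUSCLE.with_(h_b0=2700.0, P_met0=0.0)
        block = uniform_block((5, 5, 5), props=props)  # no air: no Robin loss
        solver = BioheatSolver(block)
        P = np.full(block.shape, 2700.0)
        res = solver.solve(steady_power_map(P, 4000, 2.0), 8000.0)
        root = brentq(lambda x: 2 ** (x / 1.6) * x - 1, 0, 1)
        assert res.final.delta_T.max() == pytest.approx(root, rel=0.005)
        assert res.final.delta_T.min() == pytest.approx(root, rel=0.005)

    def test_perfusion_cap_engages_at_high_power(self):
        """P = 15 * h_b0 * 7: capped steady state is exactly 7 K, whereas the
        uncapped response would settle near 6.7 K."""
        props = MUSCLE.with_(h_b0=2700.0, P_met0=0.0)
        block = uniform_block((4, 4, 4), props=props)
        solver = BioheatSolver(block)
        P = np.full(block.shape, 15.0 * 2700.0 * 7.0)
        res = solver.solve(steady_power_map(P, 5000, 2.0), 10000.0)
        assert res.final.delta_T.max() == pytest.approx(7.0, rel=0.01)

    def test_monotone_relaxation_toward_steady_state(self):
        block = uniform_block((8, 8, 8), air_margin=1)
        solver = BioheatSolver(block)
        P = np.full(block.shape, 5e4) * block.body_mask()
        res = solver.solve(steady_power_map(P, 100, 1.0), 100.0)
        assert np.all(np.diff(res.max_history) >= -1e-12)

    def test_zero_duration_returns_initial_state(self):
        block = uniform_block((4, 4, 4))
        solver = BioheatSolver(block)
        res = solver.solve(steady_power_map(np.zeros(block.shape), 1, 1.0), 0.0)
        assert res.final.time == 0.0
        assert np.all(res.final.delta_T == 0)


def euler_reference(model, thermo, P, duration, dt, h_amb=7.0):
    """Independent explicit-Euler stepper (plain numpy) for cross-checking."""
    h = model.spacing
    lam = model.field_grid("lambda_th")
    body = model.body_mask()
    cap_vol = model.field_grid("rho") * model.field_grid("c_p")
    inv_cap = np.where(body, 1.0 / np.where(cap_vol > 0, cap_vol, 1.0), 0.0)
    hb0 = model.field_grid("h_b0")
    pmet = model.field_grid("P_met0")
    caps = np.where(model.skin_mask(), thermo.L_B_cap_skin, thermo.L_B_cap_default)
    T = np.zeros(model.shape)
    n = int(round(duration / dt))
    for _ in range(n):
        div = np.zeros(model.shape)
        for d in range(3):
            lo = [slice(None)] * 3
            hi = [slice(None)] * 3
            lo[d] = slice(None, -1)
            hi[d] = slice(1, None)
            lo, hi = tuple(lo), tuple(hi)
            cond = np.where(
                body[lo] & body[hi],
                2 * lam[lo] * lam[hi] / (lam[lo] + lam[hi] + 1e-300), 0.0)
            flux = cond * (T[hi] - T[lo]) / h**2
            div[lo] += flux
            div[hi] -= flux
            robin_lo = body[lo] & ~body[hi]
            robin_hi = body[hi] & ~body[lo]
            d_lo = np.zeros(model.shape)
            d_lo[lo] = robin_lo * T[lo]
            d_hi = np.zeros(model.shape)
            d_hi[hi] = robin_hi * T[hi]
            div -= h_amb / h * (d_lo + d_hi)
        L_B = np.where(T > 0, np.minimum(caps, 2 ** (np.maximum(T, 0) / thermo.delta_B)), 1.0)
        react = -L_B * hb0 * T + (thermo.metabolic_base**T - 1) * pmet + P
        T = T + dt * inv_cap * (div + react)
        T[~body] = 0.0
    return T


class TestAgainstExplicitEuler:
    def test_heterogeneous_grid_matches_fine_euler(self):
        """Douglas-Gunn at dt=0.5 s vs explicit Euler at dt/100 after 60 s."""
        from scipy.ndimage import gaussian_filter

        shape = (20, 20, 20)
        labels = np.zeros(shape, dtype=np.int16)
        labels[1:-1, 1:-1, 1:-1] = LABEL_MUSCLE
        labels[4:10, 4:10, 4:16] = LABEL_FAT
        model = TissueModel(
            spacing=0.002, labels=labels,
            implant_mask=np.zeros(shape, bool),
            property_table={LABEL_MUSCLE: MUSCLE, LABEL_FAT: FAT},
        )
        rng = np.random.default_rng(42)
        P = gaussian_filter(rng.uniform(0, 1, shape), 2.0)
        P = 2e5 * P * model.body_mask()
        thermo = ThermoregulationModel()
        solver = BioheatSolver(model, thermo)
        res = solver.solve(steady_power_map(P, 120, 0.5), 60.0)
        ref = euler_reference(model, thermo, P, 60.0, 0.005)
        scale = np.abs(ref).max()
        assert scale > 0.5  # the comparison exercises a K-scale field
        assert np.abs(res.final.delta_T - ref).max() / scale < 0.01


class TestRobinSlabOracle:
    def test_linear_steady_profile_matches_closed_form(self):
        """1D slab, constant source, linear perfusion, Robin at both faces."""
        N, h = 50, 0.001
        lam, hb, P, h_amb = MUSCLE.lambda_th, 2700.0, 5e4, 7.0
        props = MUSCLE.with_(h_b0=hb, P_met0=0.0)
        labels = np.zeros((N + 2, 1, 1), dtype=np.int16)
        labels[1:-1, 0, 0] = LABEL_MUSCLE
        model = TissueModel(spacing=h, labels=labels,
                            implant_mask=np.zeros(labels.shape, bool),
                            property_table={LABEL_MUSCLE: props})
        solver = BioheatSolver(model, LINEAR, h_amb=h_amb)
        Pgrid = np.full(labels.shape, P) * model.body_mask()
        res = solver.solve(steady_power_map(Pgrid, 2500, 5.0), 12500.0)
        T = res.final.delta_T[1:-1, 0, 0]

        L = N * h
        k = np.sqrt(hb / lam)
        x = (np.arange(N) + 0.5) * h  # voxel centers; faces at 0 and L
        A = -(h_amb * P / hb) / (lam * k * np.sinh(k * L / 2)
                                 + h_amb * np.cosh(k * L / 2))
        T_ref = P / hb + A * np.cosh(k * (x - L / 2))
        assert np.abs(T - T_ref).max() / T_ref.max() < 0.005

    def test_discrete_energy_balance_at_steady_state(self):
        """Deposited power = perfusion removal + Robin boundary flux."""
        N, h = 30, 0.002
        hb, P, h_amb = 2700.0, 5e4, 7.0
        props = MUSCLE.with_(h_b0=hb, P_met0=0.0)
        labels = np.zeros((N + 2, 1, 1), dtype=np.int16)
        labels[1:-1, 0, 0] = LABEL_MUSCLE
        model = TissueModel(spacing=h, labels=labels,
                            implant_mask=np.zeros(labels.shape, bool),
                            property_table={LABEL_MUSCLE: props})
        solver = BioheatSolver(model, LINEAR, h_amb=h_amb)
        Pgrid = np.full(labels.shape, P) * model.body_mask()
        res = solver.solve(steady_power_map(Pgrid, 2000, 5.0), 10000.0)
        T = res.final.delta_T[1:-1, 0, 0]
        vv = h**3
        deposited = P * N * vv
        perfusion = hb * T.sum() * vv
        robin = h_amb * (T[0] + T[-1]) * h**2
        assert deposited == pytest.approx(perfusion + robin, rel=0.01)


class TestTimeAccuracy:
    def test_second_order_in_time_by_richardson(self):
        """Pure diffusion of a smooth blob: halving dt divides the error ~4x.

        Perfusion is removed: the lagged reaction term is deliberately
        first-order, so second-order behavior belongs to the split diffusion
        operator alone.
        """
        shape = (12, 12, 12)
        block = uniform_block(shape, spacing=0.002,
                              props=MUSCLE.with_(h_b0=0.0, P_met0=0.0))
        solver = BioheatSolver(block, LINEAR)
        x = np.arange(12) - 5.5
        X, Y, Z = np.meshgrid(x, x, x, indexing="ij")
        T0 = np.exp(-(X**2 + Y**2 + Z**2) / 8.0)
        zero_P = np.zeros(shape)

        def run(dt, t_end=40.0):
            T = T0.copy()
            for _ in range(int(round(t_end / dt))):
                T = solver.step(T, dt, zero_P)
            return T

        ref = run(0.3125)
        errs = [np.abs(run(dt) - ref).max() for dt in (10.0, 5.0, 2.5)]
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert orders.min() > 1.6


class TestSolveBookkeeping:
    def test_snapshots_and_crossing_times(self):
        props = MUSCLE.with_(h_b0=0.0, P_met0=0.0)
        block = uniform_block((4, 4, 4), props=props)
        solver = BioheatSolver(block, LINEAR)
        # adiabatic uniform heating: dT/dt = P / (rho c_p), linear ramp
        rate = 0.01  # K/s
        P = np.full(block.shape, rate * MUSCLE.rho * MUSCLE.c_p)
        res = solver.solve(steady_power_map(P, 400, 0.5), 200.0,
                           snapshot_times=(50.0, 200.0), thresholds=(1.0,))
        assert set(res.snapshots) == {50.0, 200.0}
        assert res.snapshots[50.0].max() == pytest.approx(0.5, rel=1e-6)
        ct = res.crossing_time[1.0]
        assert np.allclose(ct[block.body_mask()], 100.0, rtol=1e-6)

    def test_power_map_shorter_than_duration_rejected(self):
        block = uniform_block((4, 4, 4))
        solver = BioheatSolver(block)
        with pytest.raises(ValueError, match="power map"):
            solver.solve(steady_power_map(np.zeros(block.shape), 10, 0.5), 100.0)
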