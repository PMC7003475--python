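import math

import numpy as np
import pytest
from scipy.interpolate import CubicSpline

from coroflow.boundaries import InflowWaveform, make_terminal_bed
from coroflow.geometry import build_network
from coroflow.solver1d import (
    BoundaryConditions,
    ResistorOutlet,
    Solver1D,
    SolverConfig,
    SolverError,
    run_to_periodic,
    steady_solve,
)
from coroflow.units import mmhg_to_cgs
from coroflow.wall_model import WallParams, reference_wave_speed

from conftest import uniform_segment

P0 = mmhg_to_cgs(74.0)
FC = 22.0 * 0.04 * math.pi  # friction coefficient * mu * pi


def quiet_inflow(period=1.0):
    return InflowWaveform(period, np.full(11, 1e-12), "resting", 0.4)


def gaussian_pulse_solver(wall, L=8.0, amp_mmhg=2.0, dx=0.05, dt=2e-5,
                          center=3.0, width=0.6, picard_tol=1e-9):
    """Single vessel carrying a forward-matched Gaussian pressure pulse."""
    D = 0.3
    A0 = math.pi * (D / 2) ** 2
    net = build_network([uniform_segment("v", L, D, "a", "b")], {})
    c0 = reference_wave_speed(D, wall)
    z0 = wall.rho * c0 / A0
    bc = BoundaryConditions(quiet_inflow(), {"v": ResistorOutlet(z0, P0)})
    cfg = SolverConfig(dt=dt, target_dx=dx, include_wall_viscosity=False,
                       picard_tol=picard_tol)
    s = Solver1D(net, wall, bc, cfg)
    m = s.meshes["v"]
    bump = mmhg_to_cgs(amp_mmhg) * np.exp(-(((m.xc - center) / width) ** 2))
    s.y[m.iP] = P0 + bump
    xf = np.arange(m.n_cells + 1) * m.dx
    bump_f = mmhg_to_cgs(amp_mmhg) * np.exp(-(((xf - center) / width) ** 2))
    s.y[m.iQ] = bump_f * A0 / (wall.rho * c0)
    return s, m, c0


class TestEquilibrium:
    def test_fixed_point(self, wall, single_vessel):
        bc = BoundaryConditions(quiet_inflow(), {"v": ResistorOutlet(1e5, P0)})
        s = Solver1D(single_vessel, wall, bc, SolverConfig(dt=1e-3, target_dx=0.25))
        for _ in range(30):
            s.step()
        assert np.max(np.abs(s.y[s.meshes["v"].iP] - P0)) < 1e-6
        assert np.max(np.abs(s.y[s.meshes["v"].iQ])) < 1e-10

    def test_missing_outlet_rejected(self, wall, single_vessel):
        with pytest.raises(SolverError, match="outlet"):
            Solver1D(single_vessel, wall,
                     BoundaryConditions(quiet_inflow(), {}), SolverConfig())


class TestSteadyState:
    def test_poiseuille_drop(self, stiff_wall, single_vessel):
        # rigid-limit uniform tube: dP/dx = -22 mu pi Q / A^2
        A0 = math.pi * 0.15**2
        res = steady_solve(single_vessel, stiff_wall, 1.0,
                           {"v": ResistorOutlet(1e5, P0)},
                           SolverConfig(target_dx=0.05))
        P = res.segments["v"].P[0]
        x = res.segments["v"].x_cells
        drop_full = (P[0] - P[-1]) * 5.0 / (x[-1] - x[0])
        analytic = FC * 1.0 * 5.0 / A0**2
        assert drop_full == pytest.approx(analytic, rel=0.01)

    def test_zero_flow_uniform_pressure(self, wall, single_vessel):
        res = steady_solve(single_vessel, wall, 1e-12,
                           {"v": ResistorOutlet(1e5, P0)})
        P = res.segments["v"].P[0]
        assert np.max(np.abs(P - P0)) < 1.0  # dyn/cm^2

    def test_bifurcation_flow_split_circuit_oracle(self, stiff_wall):
        # rigid linear limit: flows split inversely to series resistance sums
        segs = [
            uniform_segment("p", 3.0, 0.35, "n0", "n1"),
            uniform_segment("a", 2.0, 0.25, "n1", "n2"),
            uniform_segment("b", 4.0, 0.20, "n1", "n3"),
        ]
        net = build_network(segs, {"p": ["a", "b"]})
        r_out = {"a": 2.0e4, "b": 3.0e4}
        outlets = {k: ResistorOutlet(r, P0) for k, r in r_out.items()}
        res = steady_solve(net, stiff_wall, 1.0, outlets,
                           SolverConfig(target_dx=0.02))
        q_a = res.segments["a"].Q[0, -1]
        q_b = res.segments["b"].Q[0, -1]
        r_seg = {
            "a": FC * 2.0 / (math.pi * 0.125**2) ** 2,
            "b": FC * 4.0 / (math.pi * 0.10**2) ** 2,
        }
        ratio_oracle = (r_seg["b"] + r_out["b"]) / (r_seg["a"] + r_out["a"])
        assert q_a / q_b == pytest.approx(ratio_oracle, rel=0.01)
        assert q_a + q_b == pytest.approx(1.0, rel=1e-8)

    def test_infinite_resistance_starves_daughter(self, stiff_wall, twin_tree):
        outlets = {"d1": ResistorOutlet(1e5, P0), "d2": ResistorOutlet(1e18, P0)}
        res = steady_solve(twin_tree, stiff_wall, 1.0, outlets)
        assert res.segments["d1"].Q[0, -1] == pytest.approx(1.0, rel=1e-6)
        assert abs(res.segments["d2"].Q[0, -1]) < 1e-6


class TestJunctions:
    def test_twin_daughters_split_equally(self, wall, twin_tree):
        t = np.linspace(0, 0.8, 81)
        q = 2.0 + 1.5 * np.sin(2 * np.pi * t / 0.8)
        bc = BoundaryConditions(
            InflowWaveform(0.8, q),
            {"d1": ResistorOutlet(4e4, P0), "d2": ResistorOutlet(4e4, P0)},
        )
        s = Solver1D(twin_tree, wall, bc, SolverConfig(dt=5e-4, target_dx=0.1))
        for _ in range(400):
            s.step()
            q1 = s.y[s.meshes["d1"].iQ]
            q2 = s.y[s.meshes["d2"].iQ]
            np.testing.assert_allclose(q1, q2, rtol=1e-8, atol=1e-12)
            qp_end = s.y[s.meshes["p"].iQ[-1]]
            # junction balance residual
            assert abs(qp_end - (q1[0] + q2[0])) <= 1e-10 * max(abs(qp_end), 1.0)

    def test_pressure_continuity(self, wall, twin_tree):
        t = np.linspace(0, 0.8, 81)
        q = 2.0 + 1.5 * np.sin(2 * np.pi * t / 0.8)
        bc = BoundaryConditions(
            InflowWaveform(0.8, q),
            {"d1": ResistorOutlet(4e4, P0), "d2": ResistorOutlet(4e4, P0)},
        )
        s = Solver1D(twin_tree, wall, bc, SolverConfig(dt=5e-4, target_dx=0.05))
        for _ in range(600):
            s.step()
        # extrapolated end pressures of parent and daughters agree at the node
        mp, md = s.meshes["p"], s.meshes["d1"]
        p_end = s.y[mp.iP[-1]] + 0.5 * (s.y[mp.iP[-1]] - s.y[mp.iP[-2]])
        p_start = s.y[md.iP[0]] - 0.5 * (s.y[md.iP[1]] - s.y[md.iP[0]])
        assert abs(p_end - p_start) / abs(p_end) < 2e-3


class TestWavePropagation:
    def test_pulse_speed_matches_c0(self, wall):
        s, m, c0 = gaussian_pulse_solver(wall, L=20.0, amp_mmhg=1.0,
                                         center=4.0, width=0.8)
        times, peaks = [], []
        for k in range(500):
            s.step()
            if k % 50 == 49:
                times.append(s.t)
                peaks.append(m.xc[np.argmax(s.y[m.iP])])
        speed = np.polyfit(times, peaks, 1)[0]
        assert speed == pytest.approx(c0, rel=0.02)


class TestConvergenceOrder:
    def run_pulse(self, wall, dx, dt, t_end):
        s, m, _ = gaussian_pulse_solver(wall, dx=dx, dt=dt, picard_tol=1e-12)
        for _ in range(int(round(t_end / dt))):
            s.step()
        return m.xc, s.y[m.iP].copy()

    def test_order_in_space(self, wall):
        t_end, dt0 = 2e-3, 2.5e-6
        xr, pr = self.run_pulse(wall, 0.0125, dt0, t_end)
        ref = CubicSpline(xr, pr)
        errs = []
        for dx in (0.2, 0.1, 0.05):
            x, p = self.run_pulse(wall, dx, dt0, t_end)
            errs.append(np.sqrt(np.mean((p - ref(x)) ** 2)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 1.9)

    def test_order_in_time(self, wall):
        t_end, dxf = 2e-3, 0.025
        _, pr = self.run_pulse(wall, dxf, 2.5e-6, t_end)
        errs = []
        for dt in (8e-5, 4e-5, 2e-5):
            _, p = self.run_pulse(wall, dxf, dt, t_end)
            errs.append(np.sqrt(np.mean((p - pr) ** 2)))
        orders = np.log2(np.array(errs[:-1]) / np.array(errs[1:]))
        assert np.all(orders >= 1.9)


class TestRunToPeriodic:
    def make_bc(self, period=0.8, r_total=6e4):
        t = np.linspace(0, period, 81)
        q = 2.5 + 2.0 * np.sin(2 * np.pi * t / period) ** 2
        q[-1] = q[0]
        wave = InflowWaveform(period, q)
        return wave

    def test_rc_response_analytic_oracle(self, wall, single_vessel):
        # 0D oracle: tube compliance C + outlet resistor R form an RC circuit;
        # for sinusoidal inflow the periodic solution is the phasor response.
        period, q0, q1 = 0.8, 2.5, 0.5
        t = np.linspace(0, period, 161)
        omega = 2 * np.pi / period
        q = q0 + q1 * np.sin(omega * t)
        q[-1] = q[0]
        wave = InflowWaveform(period, q)
        R = 5e4
        pv = P0
        bc = BoundaryConditions(wave, {"v": ResistorOutlet(R, pv)})
        cfg = SolverConfig(dt=2.5e-4, target_dx=0.1, max_cycles=10,
                           periodic_tolerance=1e-5)
        res = run_to_periodic(single_vessel, wall, bc, cfg)

        from coroflow.wall_model import compliance, inverse_area, stiffness_exponent

        A0 = math.pi * 0.15**2
        c0 = reference_wave_speed(0.3, wall)
        b = stiffness_exponent(c0, wall)
        p_mean = pv + R * q0
        a_mean = inverse_area(p_mean, A0, c0, b, wall)
        C = compliance(a_mean, A0, c0, b, wall) * 5.0  # tube-integrated
        phasor = R / (1.0 + 1j * omega * R * C)
        p_oracle = (
            pv + R * q0
            + q1 * np.imag(phasor * np.exp(1j * omega * res.t))
            + FC * 5.0 * res.field_at("v", 0.0, "Q") / A0**2
        )
        p_in = res.field_at("v", 0.0, "P")
        scale = float(np.max(np.abs(p_in)))
        assert np.max(np.abs(p_in - p_oracle)) / scale < 0.01

    def test_mass_balance_over_cycle(self, wall, twin_tree):
        wave = self.make_bc()
        outlets = {"d1": make_terminal_bed(8e4), "d2": make_terminal_bed(1.2e5)}
        cfg = SolverConfig(dt=1e-3, target_dx=0.1, max_cycles=12,
                           periodic_tolerance=1e-4)
        res = run_to_periodic(twin_tree, wall, BoundaryConditions(wave, outlets), cfg)
        assert res.metadata["converged"]
        assert res.metadata["mass_balance_error"] < 1e-3

    def test_idempotent_after_convergence(self, wall, single_vessel):
        wave = self.make_bc()
        bc = BoundaryConditions(wave, {"v": ResistorOutlet(5e4, P0)})
        cfg = SolverConfig(dt=1e-3, target_dx=0.2, max_cycles=6,
                           periodic_tolerance=1e-4)
        res1 = run_to_periodic(single_vessel, wall, bc, cfg)
        bc2 = BoundaryConditions(wave, {"v": ResistorOutlet(5e4, P0)})
        cfg2 = SolverConfig(dt=1e-3, target_dx=0.2, max_cycles=12,
                            periodic_tolerance=1e-4)
        res2 = run_to_periodic(single_vessel, wall, bc2, cfg2)
        p1 = res1.field_at("v", 0.5, "P")
        p2 = res2.field_at("v", 0.5, "P")
        assert np.max(np.abs(p1 - p2)) / np.max(np.abs(p1)) < 1e-3

    def test_positive_area_and_energy_dissipation(self, wall, twin_tree):
        wave = self.make_bc()
        outlets = {"d1": make_terminal_bed(8e4), "d2": make_terminal_bed(1.2e5)}
        cfg = SolverConfig(dt=1e-3, target_dx=0.1, max_cycles=10,
                           periodic_tolerance=1e-3)
        res = run_to_periodic(twin_tree, wall, BoundaryConditions(wave, outlets), cfg)
        for f in res.segments.values():
            assert np.all(f.A > 0)
        # energy flux in >= out over the converged cycle
        e_in = np.trapezoid(res.segments["p"].P[:, 0] * res.segments["p"].Q[:, 0],
                            res.t)
        e_out = sum(
            np.trapezoid(res.segments[s].P[:, -1] * res.segments[s].Q[:, -1], res.t)
            for s in ("d1", "d2")
        )
        assert e_in >= e_out

    def test_nonconvergence_recorded_not_fatal(self, wall, single_vessel):
        wave = self.make_bc()
        bc = BoundaryConditions(wave, {"v": ResistorOutlet(5e4, P0)})
        cfg = SolverConfig(dt=1e-3, target_dx=0.2, max_cycles=2,
                           periodic_tolerance=1e-12)
        res = run_to_periodic(single_vessel, wall, bc, cfg)
        assert not res.metadata["converged"]
        assert "warning" in res.metadata


class TestResultContainer:
    def test_hdf5_roundtrip(self, wall, single_vessel, tmp_path):
        wave = TestRunToPeriodic().make_bc()
        bc = BoundaryConditions(wave, {"v": ResistorOutlet(5e4, P0)})
        cfg = SolverConfig(dt=1e-3, target_dx=0.2, max_cycles=3)
        res = run_to_periodic(single_vessel, wall, bc, cfg)
        path = tmp_path / "res.h5"
        res.save_hdf5(path)
        from coroflow.solver1d import SimulationResult

        back = SimulationResult.load_hdf5(path)
        np.testing.assert_array_equal(back.t, res.t)
        np.testing.assert_array_equal(back.segments["v"].P, res.segments["v"].P)
        assert back.wall == res.wall

    def test_probe_summary_columns(self, wall, single_vessel):
        wave = TestRunToPeriodic().make_bc()
        bc = BoundaryConditions(wave, {"v": ResistorOutlet(5e4, P0)})
        res = run_to_periodic(single_vessel, wall, bc,
                              SolverConfig(dt=1e-3, target_dx=0.2, max_cycles=2))
        df = res.probe_summary()
        assert {"t_s", "v_P_prox", "v_P_dist", "v_Q_prox", "v_Q_dist"} <= set(df.columns)
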