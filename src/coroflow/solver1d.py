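"""Implicit 1D pressure-flow solver on coronary networks.

Discretization: per segment, a staggered control-volume (subdomain
collocation) grid -- pressures at cell centres, flows at cell faces -- with
a theta = 1/2 (Crank-Nicolson) time discretization.  The scheme is
second-order in space and time on smooth problems; the nonlinearity (area,
compliance and advection coefficients) is resolved by Picard iteration on
midpoint-frozen coefficients, so each iteration solves one sparse linear
system over the whole network.

Junctions impose exact flow balance and a single shared static pressure;
terminals are closed by lumped coronary beds (with intramyocardial
pressure) or plain resistors; the root carries a prescribed flow.

Governing equations (CGS):

    Ca dP/dt + dQ/dx = 0
    (rho/A) dQ/dt + (rho/A) d(Q^2/A)/dx + dP/dx = -f_c mu pi Q / A^2

with f_c = 22 (coronary-fit viscous coefficient); friction opposes flow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .boundaries import InflowWaveform, TerminalBed, VentricularPressureTraces
from .geometry import CoronaryNetwork
from .wall_model import (
    WallParams,
    compliance,
    inverse_area,
    reference_wave_speed,
    stiffness_exponent,
    wall_viscosity,
)

__all__ = [
    "SolverConfig",
    "SolverError",
    "ResistorOutlet",
    "BoundaryConditions",
    "SegmentFields",
    "SimulationResult",
    "Solver1D",
    "run_to_periodic",
    "steady_solve",
]


class SolverError(RuntimeError):
    """Solver failure (non-convergence, negative area) with location info."""


@dataclass
class SolverConfig:
    target_dx: float = 0.05          # cm
    dt: float = 2.5e-4               # s
    theta: float = 0.5
    periodic_tolerance: float = 1e-3
    max_cycles: int = 20
    picard_tol: float = 1e-9
    max_picard_iters: int = 60
    startup_ramp_cycles: float = 0.5  # smooth inflow ramp-in (robustness only)
    output_dt: float = 1e-3          # probe/field sampling interval
    friction_coefficient: float = 22.0
    include_wall_viscosity: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.target_dx <= 0:
            raise ValueError("dt and target_dx must be positive")
        if self.periodic_tolerance <= 0 or self.picard_tol <= 0:
            raise ValueError("tolerances must be positive")


@dataclass
class ResistorOutlet:
    """Pure resistive terminal closure: P_face = Pv + R*Q."""

    R: float
    Pv: float = 0.0


@dataclass
class BoundaryConditions:
    """Root inflow plus one outlet closure per terminal segment."""

    inflow: InflowWaveform
    outlets: dict[str, TerminalBed | ResistorOutlet]
    ventricular: VentricularPressureTraces | None = None
    pim_right_scale: float = 0.5

    def pim(self, t: float, side: str) -> float:
        if self.ventricular is None:
            return 0.0
        return self.ventricular.pim(t, side, self.pim_right_scale)


class _SegmentMesh:
    """Per-segment discretization and wall coefficient tables."""

    def __init__(self, seg, wall: WallParams, cfg: SolverConfig, offset: int):
        self.id = seg.id
        self.n_cells = max(2, int(round(seg.length / cfg.target_dx)))
        self.dx = seg.length / self.n_cells
        xc = (np.arange(self.n_cells) + 0.5) * self.dx
        xf = np.arange(self.n_cells + 1) * self.dx
        x_prof = seg.x
        self.A0c = np.interp(xc, x_prof, seg.area_profile)
        self.A0f = np.interp(xf, x_prof, seg.area_profile)
        self.xc = xc
        D0c = 2.0 * np.sqrt(self.A0c / math.pi)
        self.c0 = reference_wave_speed(D0c, wall)
        self.b = stiffness_exponent(self.c0, wall)
        self.gamma = wall_viscosity(D0c, wall) if cfg.include_wall_viscosity else np.zeros_like(D0c)
        # global indices
        self.iP = offset + np.arange(self.n_cells)
        self.iQ = offset + self.n_cells + np.arange(self.n_cells + 1)
        self.size = 2 * self.n_cells + 1


@dataclass
class SegmentFields:
    """Sampled solution fields on one segment: shapes (Nt, Nc) / (Nt, Nc+1)."""

    x_cells: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    A: np.ndarray


@dataclass
class SimulationResult:
    """Final-cycle (or transient) fields for every segment."""

    t: np.ndarray
    segments: dict[str, SegmentFields]
    period: float
    wall: dict
    config: dict
    metadata: dict = field(default_factory=dict)

    def pressure(self, segment_id: str, fraction: float) -> np.ndarray:
        return self.field_at(segment_id, fraction, "P")

    def field_at(self, segment_id: str, fraction: float, name: str = "P") -> np.ndarray:
        """Trace of P, Q or A at a fractional position along a segment."""
        f = self.segments[segment_id]
        arr = getattr(f, name)
        if name == "Q":
            xs = np.linspace(0.0, f.x_cells[-1] + f.x_cells[0], arr.shape[1])
        else:
            xs = f.x_cells
        xq = fraction * (f.x_cells[-1] + f.x_cells[0])
        j = np.searchsorted(xs, xq)
        j = min(max(j, 1), len(xs) - 1)
        w = (xq - xs[j - 1]) / (xs[j] - xs[j - 1])
        return (1.0 - w) * arr[:, j - 1] + w * arr[:, j]

    def save_hdf5(self, path) -> None:
        import h5py
        import json as _json

        with h5py.File(path, "w") as h5:
            h5.attrs["period"] = self.period
            h5.attrs["wall"] = _json.dumps(self.wall)
            h5.attrs["config"] = _json.dumps(self.config)
            h5.attrs["metadata"] = _json.dumps(self.metadata)
            h5.create_dataset("t", data=self.t)
            for sid, f in self.segments.items():
                g = h5.create_group(f"segments/{sid}")
                g.create_dataset("x", data=f.x_cells)
                for name in ("P", "Q", "A"):
                    g.create_dataset(name, data=getattr(f, name))

    @classmethod
    def load_hdf5(cls, path) -> "SimulationResult":
        import h5py
        import json as _json

        with h5py.File(path, "r") as h5:
            segs = {}
            for sid, g in h5["segments"].items():
                segs[sid] = SegmentFields(
                    x_cells=g["x"][:], P=g["P"][:], Q=g["Q"][:], A=g["A"][:]
                )
            return cls(
                t=h5["t"][:],
                segments=segs,
                period=float(h5.attrs["period"]),
                wall=_json.loads(h5.attrs["wall"]),
                config=_json.loads(h5.attrs["config"]),
                metadata=_json.loads(h5.attrs["metadata"]),
            )

    def probe_summary(self):
        """DataFrame of proximal/distal pressure and flow traces per segment."""
        import pandas as pd

        cols = {"t_s": self.t}
        for sid, f in self.segments.items():
            cols[f"{sid}_P_prox"] = f.P[:, 0]
            cols[f"{sid}_P_dist"] = f.P[:, -1]
            cols[f"{sid}_Q_prox"] = f.Q[:, 0]
            cols[f"{sid}_Q_dist"] = f.Q[:, -1]
        return pd.DataFrame(cols)


class Solver1D:
    """Network assembler and time stepper."""

    def __init__(
        self,
        network: CoronaryNetwork,
        wall: WallParams,
        boundaries: BoundaryConditions,
        config: SolverConfig | None = None,
    ):
        self.network = network
        self.wall = wall
        self.bc = boundaries
        self.cfg = config or SolverConfig()

        missing = [t for t in network.terminal_segment_ids if t not in boundaries.outlets]
        if missing:
            raise SolverError(f"no outlet closure for terminal segment(s) {missing!r}")

        self.meshes: dict[str, _SegmentMesh] = {}
        offset = 0
        for sid, seg in network.segments.items():
            m = _SegmentMesh(seg, wall, self.cfg, offset)
            self.meshes[sid] = m
            offset += m.size
        self.junction_index: dict[str, int] = {}
        for parent in network.junctions:
            self.junction_index[parent] = offset
            offset += 1
        self.bed_index: dict[str, int] = {}
        for term in network.terminal_segment_ids:
            if isinstance(boundaries.outlets[term], TerminalBed):
                self.bed_index[term] = offset
                offset += 2
        self.n = offset

        self.y = np.empty(self.n)
        self.t = 0.0
        self.initialize(wall.P0)

        self._flux_in = 0.0
        self._flux_out = {t: 0.0 for t in network.terminal_segment_ids}

    # -- state management -------------------------------------------------

    def initialize(self, pressure: float) -> None:
        """Uniform-pressure, zero-flow initial state."""
        y = self.y
        for m in self.meshes.values():
            y[m.iP] = pressure
            y[m.iQ] = 0.0
        for idx in self.junction_index.values():
            y[idx] = pressure
        for term, idx in self.bed_index.items():
            bed = self.bc.outlets[term]
            bed.initialize(pressure)
            y[idx] = pressure
            y[idx + 1] = pressure
        self.t = 0.0

    def areas(self, y: np.ndarray | None = None) -> dict[str, np.ndarray]:
        y = self.y if y is None else y
        out = {}
        for sid, m in self.meshes.items():
            out[sid] = inverse_area(y[m.iP], m.A0c, m.c0, m.b, self.wall)
        return out

    # -- assembly ---------------------------------------------------------

    def _assemble(self, y_old: np.ndarray, y_mid: np.ndarray, dt: float,
                  t_new: float, steady: bool):
        cfg = self.cfg
        th = 1.0 if steady else cfg.theta
        omth = 1.0 - th
        rho = self.wall.rho
        fc = cfg.friction_coefficient * self.wall.mu * math.pi
        inv_dt = 0.0 if steady else 1.0 / dt

        rows: list[np.ndarray] = []
        cols: list[np.ndarray] = []
        vals: list[np.ndarray] = []
        rhs = np.zeros(self.n)

        def add(r, c, v):
            rows.append(np.atleast_1d(np.asarray(r, dtype=np.int64)))
            cols.append(np.atleast_1d(np.asarray(c, dtype=np.int64)))
            vals.append(np.atleast_1d(np.asarray(v, dtype=float)))

        cell_cache: dict[str, tuple] = {}
        for sid, m in self.meshes.items():
            P_mid = y_mid[m.iP]
            Q_mid = y_mid[m.iQ]
            P_old = y_old[m.iP]
            Q_old = y_old[m.iQ]
            # clamped tube-law inversion: intermediate Picard iterates may
            # overshoot the collapse limit; the accepted state is re-checked
            # strictly in step()
            arg = 1.0 + m.b * (P_mid - self.wall.P0 - self.wall.Pext) / (
                2.0 * self.wall.rho * m.c0**2
            )
            A = m.A0c * np.clip(arg, 1e-3, None) ** (2.0 / m.b)
            Ca = compliance(A, m.A0c, m.c0, m.b, self.wall)
            kap = np.zeros_like(A) if steady else m.gamma * Ca / (m.A0c * np.sqrt(A)) * inv_dt
            Qc = 0.5 * (Q_mid[:-1] + Q_mid[1:])
            beta = Qc / A
            cell_cache[sid] = (A, Ca, kap, beta)

            dx = m.dx
            # mass: Ca/dt * (P' - P) + (Q'_{j+1} - Q'_j)^theta / dx = 0
            add(m.iP, m.iP, Ca * inv_dt)
            add(m.iP, m.iQ[1:], np.full(m.n_cells, th / dx))
            add(m.iP, m.iQ[:-1], np.full(m.n_cells, -th / dx))
            rhs[m.iP] += (
                Ca * inv_dt * P_old
                - omth / dx * (Q_old[1:] - Q_old[:-1])
            )

            if m.n_cells >= 2:
                # interior faces f = 1..n_cells-1, cells L = f-1, R = f
                fi = np.arange(1, m.n_cells)
                Af = 0.5 * (A[:-1] + A[1:])
                bL, bR = beta[:-1], beta[1:]
                qcL, qcR = Qc[:-1], Qc[1:]
                kL, kR = kap[:-1], kap[1:]
                ra = rho / Af
                # tangent linearization of (Q^2/A): beta*(Q_f + Q_f+1) - beta*Qc_mid
                adv = ra / dx
                diag = ra * inv_dt + th * adv * (bR - bL) + th * fc / Af**2
                add(m.iQ[fi], m.iQ[fi], diag)
                add(m.iQ[fi], m.iQ[fi + 1], th * adv * bR)
                add(m.iQ[fi], m.iQ[fi - 1], -th * adv * bL)
                add(m.iQ[fi], m.iP[fi], (th + kR) / dx)
                add(m.iQ[fi], m.iP[fi - 1], -(th + kL) / dx)
                rhs[m.iQ[fi]] += (
                    ra * inv_dt * Q_old[fi]
                    + adv * (bR * qcR - bL * qcL)
                    - omth * (
                        adv * (bR * (Q_old[fi] + Q_old[fi + 1])
                               - bL * (Q_old[fi - 1] + Q_old[fi]))
                        + fc * Q_old[fi] / Af**2
                    )
                    - ((omth - kR) * P_old[fi] - (omth - kL) * P_old[fi - 1]) / dx
                )

        def boundary_face(m, end: bool, closure: list[tuple[int, float]],
                          p_const: float, extra_cells: tuple):
            """One-sided momentum balance at a segment's first or last face.

            ``closure`` lists (column, coefficient-at-theta) pairs making up
            the face pressure (beyond its constant part ``p_const``); the
            old-time face-pressure value is reconstructed from the same
            coefficients against ``y_old``.
            """
            A, Ca, kap, beta = extra_cells
            dx2 = 2.0 / m.dx  # 1/(dx/2)
            if end:
                fq, adjq, ic, sgn = m.iQ[-1], m.iQ[-2], m.n_cells - 1, 1.0
                Af = A[-1] * m.A0f[-1] / m.A0c[-1]
            else:
                fq, adjq, ic, sgn = m.iQ[0], m.iQ[1], 0, -1.0
                Af = A[0] * m.A0f[0] / m.A0c[0]
            Qf_mid = y_mid[fq]
            qc_mid = 0.5 * (y_mid[fq] + y_mid[adjq])
            bcell = beta[ic]
            kcell = kap[ic]
            ra = rho / Af
            # advection: sgn * ((Q^2/A)_face - (Q^2/A)_cell) * dx2, each Q^2/A
            # tangent-linearized around the midpoint iterate
            diag = (
                ra * inv_dt
                + th * sgn * ra * dx2 * (2.0 * Qf_mid / Af - bcell)
                + th * fc / Af**2
            )
            entries = [(fq, diag), (adjq, -th * sgn * ra * dx2 * bcell)]
            # pressure: sgn * (P_face - P_cell) * dx2
            entries.append((m.iP[ic], -sgn * (th + kcell) * dx2))
            for col, coef in closure:
                entries.append((col, sgn * th * coef * dx2))
            for col, coef in entries:
                add(fq, col, coef)
            p_face_old = p_const + sum(coef * y_old[col] for col, coef in closure)
            rhs[fq] += (
                ra * inv_dt * y_old[fq]
                + sgn * ra * dx2 * (Qf_mid**2 / Af - bcell * qc_mid)
                - omth * (
                    sgn * ra * dx2 * ((2.0 * Qf_mid / Af) * y_old[fq]
                                      - bcell * (y_old[fq] + y_old[adjq]))
                    + fc * y_old[fq] / Af**2
                )
                - sgn * dx2 * (omth * p_face_old + p_const * th)
                + sgn * (omth - kcell) * dx2 * y_old[m.iP[ic]]
            )

        # root inlet: prescribed flow (with optional smooth startup ramp)
        root = self.meshes[self.network.root_segment_id]
        q_in = float(self.bc.inflow(t_new)) if not steady else float(self.bc.inflow(0.0))
        t_ramp = cfg.startup_ramp_cycles * self.bc.inflow.period
        if not steady and t_ramp > 0 and t_new < t_ramp:
            q_in *= 0.5 - 0.5 * math.cos(math.pi * t_new / t_ramp)
        add(root.iQ[0], root.iQ[0], 1.0)
        rhs[root.iQ[0]] += q_in

        # junctions: parent end face + child start faces + mass balance
        for parent, children in self.network.junctions.items():
            jid = self.junction_index[parent]
            pm = self.meshes[parent]
            boundary_face(pm, True, [(jid, 1.0)], 0.0, cell_cache[parent])
            add(jid, pm.iQ[-1], 1.0)
            for child in children:
                cm = self.meshes[child]
                boundary_face(cm, False, [(jid, 1.0)], 0.0, cell_cache[child])
                add(jid, cm.iQ[0], -1.0)
            rhs[jid] += 0.0

        # terminals
        for term in self.network.terminal_segment_ids:
            m = self.meshes[term]
            outlet = self.bc.outlets[term]
            if isinstance(outlet, ResistorOutlet):
                boundary_face(
                    m, True, [(m.iQ[-1], outlet.R)], outlet.Pv, cell_cache[term]
                )
                continue
            ib = self.bed_index[term]
            boundary_face(
                m, True, [(ib, 1.0), (m.iQ[-1], outlet.Ra)], 0.0, cell_cache[term]
            )
            # node 1: Ca_bed dP1/dt = Q - (P1-P2)/Rm
            cb = 0.0 if steady else outlet.Ca_bed / dt
            add(ib, ib, cb + th / outlet.Rm)
            add(ib, ib + 1, -th / outlet.Rm)
            add(ib, m.iQ[-1], -th)
            rhs[ib] += (
                cb * y_old[ib]
                + omth * y_old[m.iQ[-1]]
                - omth * (y_old[ib] - y_old[ib + 1]) / outlet.Rm
            )
            # node 2: Cim d(P2 - Pim)/dt = (P1-P2)/Rm - (P2-Pv)/Rv
            ci = 0.0 if steady else outlet.Cim / dt
            add(ib + 1, ib + 1, ci + th / outlet.Rm + th / outlet.Rv)
            add(ib + 1, ib, -th / outlet.Rm)
            pim_old = self.bc.pim(self.t, outlet.side)
            pim_new = self.bc.pim(t_new, outlet.side)
            rhs[ib + 1] += (
                ci * y_old[ib + 1]
                + omth * (y_old[ib] - y_old[ib + 1]) / outlet.Rm
                - omth * (y_old[ib + 1] - outlet.Pv) / outlet.Rv
                + th * outlet.Pv / outlet.Rv
                + (0.0 if steady else outlet.Cim * (pim_new - pim_old) / dt)
            )

        mat = sp.csc_matrix(
            (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
            shape=(self.n, self.n),
        )
        return mat, rhs

    # -- stepping ---------------------------------------------------------

    def _solve_step(self, dt: float) -> np.ndarray:
        cfg = self.cfg
        y_old = self.y
        y_new = y_old.copy()
        t_new = self.t + dt
        scale = max(float(np.max(np.abs(y_old))), 1.0)
        relax = 1.0
        r_prev: np.ndarray | None = None
        for _ in range(cfg.max_picard_iters):
            y_mid = 0.5 * (y_old + y_new)
            mat, rhs = self._assemble(y_old, y_mid, dt, t_new, steady=False)
            y_next = spla.spsolve(mat, rhs)
            r = y_next - y_new
            err = float(np.max(np.abs(r))) / scale
            if err < cfg.picard_tol:
                return y_next
            # Aitken dynamic under-relaxation (damps oscillatory contraction)
            if r_prev is not None:
                dr = r - r_prev
                denom = float(dr @ dr)
                if denom > 0:
                    relax = -relax * float(r_prev @ dr) / denom
                    relax = min(max(relax, 0.1), 1.0)
            y_new = y_new + relax * r
            r_prev = r
        raise SolverError(
            f"Picard iteration did not converge at t={t_new:.6g} "
            f"(residual {err:.3g})"
        )

    def step(self, dt: float | None = None, _depth: int = 0) -> None:
        """Advance the whole network by one time step (with sub-step fallback)."""
        dt = self.cfg.dt if dt is None else dt
        try:
            y_new = self._solve_step(dt)
        except SolverError:
            if _depth >= 3:
                raise
            self.step(dt / 2.0, _depth + 1)
            self.step(dt / 2.0, _depth + 1)
            return
        # accepted state must lie strictly inside the tube-law domain
        for sid, m in self.meshes.items():
            try:
                inverse_area(y_new[m.iP], m.A0c, m.c0, m.b, self.wall)
            except ValueError as exc:
                raise SolverError(
                    f"segment {sid!r} at t={self.t + dt:.6g}: {exc}"
                ) from exc
        # flux bookkeeping at theta-midpoint (consistent with the scheme)
        root = self.meshes[self.network.root_segment_id]
        self._flux_in += dt * 0.5 * (self.y[root.iQ[0]] + y_new[root.iQ[0]])
        for term in self.network.terminal_segment_ids:
            m = self.meshes[term]
            self._flux_out[term] += dt * 0.5 * (self.y[m.iQ[-1]] + y_new[m.iQ[-1]])
        # sync bed objects
        for term, ib in self.bed_index.items():
            bed = self.bc.outlets[term]
            bed.P1, bed.P2 = float(y_new[ib]), float(y_new[ib + 1])
        self.y = y_new
        self.t += dt

    def reset_flux_accumulators(self) -> None:
        self._flux_in = 0.0
        self._flux_out = {t: 0.0 for t in self._flux_out}

    @property
    def cycle_fluxes(self) -> tuple[float, dict[str, float]]:
        return self._flux_in, dict(self._flux_out)

    # -- recording --------------------------------------------------------

    def snapshot(self) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
        areas = self.areas()
        return {
            sid: (self.y[m.iP].copy(), self.y[m.iQ].copy(), areas[sid])
            for sid, m in self.meshes.items()
        }


def run_to_periodic(
    network: CoronaryNetwork,
    wall: WallParams,
    boundaries: BoundaryConditions,
    config: SolverConfig | None = None,
) -> SimulationResult:
    """Run whole cardiac cycles until the pressure field is cycle-periodic.

    Convergence: max relative change of every segment-end pressure trace
    between consecutive cycles below ``periodic_tolerance``.  The returned
    result holds the final cycle sampled at ``output_dt``; convergence
    status, cycle count and the cycle mass-balance error are recorded in
    ``metadata``.
    """
    cfg = config or SolverConfig()
    T = boundaries.inflow.period
    n_steps = max(1, int(round(T / cfg.dt)))
    dt = T / n_steps
    stride = max(1, int(round(cfg.output_dt / dt)))

    solver = Solver1D(network, wall, boundaries, cfg)
    prev_trace = None
    converged = False
    cycles_run = 0
    history: list[dict] = []

    for cycle in range(cfg.max_cycles):
        solver.reset_flux_accumulators()
        rec_t, rec_snaps = [], []
        for k in range(n_steps):
            solver.step(dt)
            if (k + 1) % stride == 0 or k == n_steps - 1:
                rec_t.append(solver.t)
                rec_snaps.append(solver.snapshot())
        cycles_run = cycle + 1
        trace = np.stack(
            [
                np.array([snap[sid][0][j] for snap in rec_snaps])
                for sid in solver.meshes
                for j in (0, -1)
            ]
        )
        flux_in, flux_out = solver.cycle_fluxes
        history.append({"flux_in": flux_in, "flux_out": sum(flux_out.values())})
        if prev_trace is not None and trace.shape == prev_trace.shape:
            denom = max(float(np.max(np.abs(prev_trace))), 1e-300)
            change = float(np.max(np.abs(trace - prev_trace))) / denom
            if change < cfg.periodic_tolerance:
                converged = True
                break
        prev_trace = trace

    flux_in, flux_out = solver.cycle_fluxes
    total_out = sum(flux_out.values())
    mass_err = abs(flux_in - total_out) / max(abs(flux_in), 1e-300)
    metadata = {
        "converged": converged,
        "cycles_run": cycles_run,
        "cycle_inflow_volume": flux_in,
        "cycle_outflow_volume": total_out,
        "mass_balance_error": mass_err,
    }
    if not converged:
        metadata["warning"] = (
            f"periodicity tolerance {cfg.periodic_tolerance} not reached "
            f"within {cfg.max_cycles} cycles"
        )

    t_out = np.array(rec_t) - (solver.t - T)
    segs = {}
    for sid, m in solver.meshes.items():
        P = np.stack([snap[sid][0] for snap in rec_snaps])
        Q = np.stack([snap[sid][1] for snap in rec_snaps])
        A = np.stack([snap[sid][2] for snap in rec_snaps])
        segs[sid] = SegmentFields(x_cells=m.xc, P=P, Q=Q, A=A)
    return SimulationResult(
        t=t_out,
        segments=segs,
        period=T,
        wall=wall.to_dict(),
        config=asdict(cfg),
        metadata=metadata,
    )


def steady_solve(
    network: CoronaryNetwork,
    wall: WallParams,
    inflow_q: float,
    outlets: dict[str, TerminalBed | ResistorOutlet],
    config: SolverConfig | None = None,
    max_iters: int = 60,
    tol: float = 1e-11,
) -> SimulationResult:
    """Time-independent solution for a constant inflow.

    Solves the steady (d/dt = 0) network equations by Picard iteration on
    the same spatial discretization as the transient scheme.
    """
    cfg = config or SolverConfig()
    T = 1.0
    n = 16
    wave = InflowWaveform(T, np.full(n, float(inflow_q)), "resting", 0.4)
    bc = BoundaryConditions(inflow=wave, outlets=outlets)
    solver = Solver1D(network, wall, bc, cfg)
    y = solver.y.copy()
    scale = max(float(np.max(np.abs(y))), 1.0)
    for _ in range(max_iters):
        mat, rhs = solver._assemble(y, y, 1.0, 0.0, steady=True)
        y_new = spla.spsolve(mat, rhs)
        err = float(np.max(np.abs(y_new - y))) / scale
        y = y_new
        if err < tol:
            break
    else:
        raise SolverError(f"steady solve did not converge (residual {err:.3g})")
    solver.y = y
    snap = solver.snapshot()
    segs = {
        sid: SegmentFields(
            x_cells=solver.meshes[sid].xc,
            P=snap[sid][0][None, :],
            Q=snap[sid][1][None, :],
            A=snap[sid][2][None, :],
        )
        for sid in solver.meshes
    }
    return SimulationResult(
        t=np.array([0.0]),
        segments=segs,
        period=T,
        wall=wall.to_dict(),
        config=asdict(cfg),
        metadata={"steady": True},
    )
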