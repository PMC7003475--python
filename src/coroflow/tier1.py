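"""Closed-loop 0D circulation used to generate coronary inflow waveforms.

A deliberately small stand-in for a full heart-circulation network: two
time-varying-elastance chambers, systemic and pulmonary Windkessel
compartments, and one aggregate coronary branch per side.  Its only job is
to produce (a) periodic left/right coronary inflow waveforms, (b) left and
right ventricular pressure traces for the terminal beds, and (c) the
hyperaemia transform (coronary bed resistance x 0.22 plus recalibration),
all matched to population-average pressure / cardiac-output / heart-rate
targets.

The aggregate coronary branch per side is a conduit (epicardial) resistance
in series with the microvascular bed resistance and a storage node biased by
ventricular pressure; hyperaemia scales only the bed part.  All blood volume
is conserved exactly by construction (every flow leaves one compartment and
enters another).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .boundaries import InflowWaveform, VentricularPressureTraces
from .units import lmin_to_mls, mmhg_to_cgs, cgs_to_mmhg

__all__ = [
    "PhysiologicalState",
    "RESTING",
    "HYPERAEMIC",
    "ClosedLoopModel",
    "simulate_closed_loop",
    "calibrate",
    "hyperaemia_transform",
    "waveforms_from_simulation",
]

HYPERAEMIC_RESISTANCE_FACTOR = 0.22  # 78% coronary bed resistance reduction


@dataclass(frozen=True)
class PhysiologicalState:
    """Population-average parameter set for one physiological condition."""

    label: str
    systolic: float            # mmHg
    diastolic: float           # mmHg
    cardiac_output: float      # L/min
    heart_rate: float          # bpm
    coronary_resistance_factor: float = 1.0

    def __post_init__(self) -> None:
        if not self.systolic > self.diastolic > 0:
            raise ValueError("need systolic > diastolic > 0")
        if not 30 <= self.heart_rate <= 200:
            raise ValueError("heart rate outside [30, 200] bpm")
        if not 0 < self.coronary_resistance_factor <= 1:
            raise ValueError("coronary_resistance_factor must be in (0, 1]")

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    @property
    def mean_pressure(self) -> float:
        """(systolic + 2*diastolic)/3, mmHg."""
        return self.systolic / 3.0 + 2.0 * self.diastolic / 3.0


RESTING = PhysiologicalState("resting", 115.0, 74.0, 5.19, 65.0, 1.0)
HYPERAEMIC = PhysiologicalState(
    "hyperaemic", 115.0, 70.0, 7.6, 90.0, HYPERAEMIC_RESISTANCE_FACTOR
)


def _activation(tau: np.ndarray, sys_frac: float) -> np.ndarray:
    """Normalized double-Hill activation on tau in [0, 1), peak 1."""
    a1 = 0.6 * sys_frac
    a2 = sys_frac
    h1 = (tau / a1) ** 1.9
    h2 = (tau / a2) ** 21.9
    a = h1 / (1.0 + h1) / (1.0 + h2)
    return a / a.max()


@dataclass
class ClosedLoopModel:
    """Parameters and state of the 0D closed loop (all CGS)."""

    heart_rate: float = 65.0
    # left / right ventricles (time-varying elastance, dyn/cm^2 per cm^3)
    Emax_l: float = 4000.0
    Emin_l: float = 107.0
    Emax_r: float = 730.0
    Emin_r: float = 67.0
    V0_l: float = 10.0
    V0_r: float = 10.0
    # valves and filling resistances, dyn.s/cm^5
    R_av: float = 8.0
    R_mv: float = 25.0
    R_pv: float = 12.0
    R_tv: float = 20.0
    # systemic / pulmonary Windkessels
    C_sa: float = 1.4e-3
    R_sys: float = 1250.0
    C_sv: float = 0.03
    C_pa: float = 3.5e-3
    R_pul: float = 90.0
    C_pv: float = 0.02
    # aggregate coronary branches: conduit + bed split, per side
    R_cor_left: float = 48000.0     # total resting left-branch resistance
    R_cor_right: float = 112000.0   # total resting right-branch resistance
    epicardial_fraction: float = 0.07
    coronary_factor: float = 1.0    # bed-resistance multiplier (0.22 hyperaemic)
    tau_cor: float = 0.15           # storage time constant of the coronary node, s
    pim_left_scale: float = 0.75    # fraction of P_LV squeezing the left bed
    pim_right_scale: float = 0.5
    # Bazett-like systolic-duration law: t_sys = sys_coeff * sqrt(T)
    sys_coeff: float = 0.36
    # initial state
    V_lv: float = 120.0
    V_rv: float = 120.0
    P_sa: float = mmhg_to_cgs(90.0)
    P_sv: float = mmhg_to_cgs(6.0)
    P_pa: float = mmhg_to_cgs(15.0)
    P_pv: float = mmhg_to_cgs(8.0)
    u_cl: float = mmhg_to_cgs(60.0)   # coronary node pressures net of Pim bias
    u_cr: float = mmhg_to_cgs(60.0)

    @property
    def period(self) -> float:
        return 60.0 / self.heart_rate

    def coronary_split(self, side: str) -> tuple[float, float, float]:
        """(R_in, R_out, C_node) of one aggregate coronary branch.

        The conduit part stays fixed under hyperaemia; the bed part scales
        with ``coronary_factor``.  The bed is split evenly around the node.
        """
        r_total = self.R_cor_left if side == "left" else self.R_cor_right
        r_epi = self.epicardial_fraction * r_total
        r_bed = (1.0 - self.epicardial_fraction) * r_total * self.coronary_factor
        r_in = r_epi + 0.5 * r_bed
        r_out = 0.5 * r_bed
        return r_in, r_out, self.tau_cor / r_out

    def total_volume(self) -> float:
        """Conserved volume functional (chamber volumes + C*P storage)."""
        return (
            self.V_lv + self.V_rv
            + self.C_sa * self.P_sa + self.C_sv * self.P_sv
            + self.C_pa * self.P_pa + self.C_pv * self.P_pv
            + (self.tau_cor / self.coronary_split("left")[1]) * self.u_cl
            + (self.tau_cor / self.coronary_split("right")[1]) * self.u_cr
        )


def simulate_closed_loop(
    model: ClosedLoopModel,
    n_cycles: int = 12,
    dt: float = 2.0e-4,
    record_cycles: int = 1,
) -> dict:
    """Integrate the loop and return the last ``record_cycles`` of traces.

    Returns a dict of uniformly sampled arrays (t, P_lv, P_rv, P_sa, Q_av,
    Q_cor_left, Q_cor_right) plus summary scalars: systolic/diastolic aortic
    pressure (mmHg), cardiac output (L/min), mean coronary inflow per side
    (cm^3/s), diastole onset fraction, and relative volume drift.
    """
    T = model.period
    n_per = int(round(T / dt))
    dt = T / n_per
    tau = (np.arange(n_per) + 0.5) / n_per
    sys_frac = model.sys_coeff * math.sqrt(T) / T
    act = _activation(tau, sys_frac)

    El = model.Emin_l + (model.Emax_l - model.Emin_l) * act
    Er = model.Emin_r + (model.Emax_r - model.Emin_r) * act

    rl_in, rl_out, c_cl = model.coronary_split("left")
    rr_in, rr_out, c_cr = model.coronary_split("right")

    v_lv, v_rv = model.V_lv, model.V_rv
    p_sa, p_sv = model.P_sa, model.P_sv
    p_pa, p_pv = model.P_pa, model.P_pv
    u_cl, u_cr = model.u_cl, model.u_cr

    vol0 = model.total_volume()

    n_rec = record_cycles * n_per
    rec = {k: np.empty(n_rec) for k in
           ("t", "P_lv", "P_rv", "P_sa", "Q_av", "Q_cor_left", "Q_cor_right")}
    rec_start = n_cycles * n_per - n_rec
    j = 0

    for step in range(n_cycles * n_per):
        i = step % n_per
        el, er = El[i], Er[i]
        p_lv = el * (v_lv - model.V0_l)
        p_rv = er * (v_rv - model.V0_r)
        pim_l = model.pim_left_scale * p_lv
        pim_r = model.pim_right_scale * p_rv
        p_cl = u_cl + pim_l
        p_cr = u_cr + pim_r

        q_av = max(p_lv - p_sa, 0.0) / model.R_av
        q_mv = max(p_pv - p_lv, 0.0) / model.R_mv
        q_pvv = max(p_rv - p_pa, 0.0) / model.R_pv
        q_tv = max(p_sv - p_rv, 0.0) / model.R_tv
        q_sys = (p_sa - p_sv) / model.R_sys
        q_pul = (p_pa - p_pv) / model.R_pul
        q_cl_in = (p_sa - p_cl) / rl_in
        q_cl_out = (p_cl - p_sv) / rl_out
        q_cr_in = (p_sa - p_cr) / rr_in
        q_cr_out = (p_cr - p_sv) / rr_out

        if step >= rec_start:
            rec["t"][j] = (step - rec_start) * dt
            rec["P_lv"][j] = p_lv
            rec["P_rv"][j] = p_rv
            rec["P_sa"][j] = p_sa
            rec["Q_av"][j] = q_av
            rec["Q_cor_left"][j] = q_cl_in
            rec["Q_cor_right"][j] = q_cr_in
            j += 1

        v_lv += dt * (q_mv - q_av)
        v_rv += dt * (q_tv - q_pvv)
        p_sa += dt * (q_av - q_sys - q_cl_in - q_cr_in) / model.C_sa
        p_sv += dt * (q_sys + q_cl_out + q_cr_out - q_tv) / model.C_sv
        p_pa += dt * (q_pvv - q_pul) / model.C_pa
        p_pv += dt * (q_pul - q_mv) / model.C_pv
        u_cl += dt * (q_cl_in - q_cl_out) / c_cl
        u_cr += dt * (q_cr_in - q_cr_out) / c_cr

    model.V_lv, model.V_rv = v_lv, v_rv
    model.P_sa, model.P_sv = p_sa, p_sv
    model.P_pa, model.P_pv = p_pa, p_pv
    model.u_cl, model.u_cr = u_cl, u_cr

    drift = abs(model.total_volume() - vol0) / vol0

    q_av_trace = rec["Q_av"]
    co_mls = float(q_av_trace.mean())
    # diastole onset: aortic valve closure = first zero of Q_av after its peak
    ipk = int(np.argmax(q_av_trace[:n_per]))
    closed = np.nonzero(q_av_trace[ipk:n_per] <= 0.0)[0]
    t_d = (ipk + (closed[0] if closed.size else n_per - ipk)) * dt

    return {
        **rec,
        "period": T,
        "dt": dt,
        "systolic_mmhg": cgs_to_mmhg(float(rec["P_sa"].max())),
        "diastolic_mmhg": cgs_to_mmhg(float(rec["P_sa"].min())),
        "mean_aortic_mmhg": cgs_to_mmhg(float(rec["P_sa"].mean())),
        "cardiac_output_lmin": co_mls * 60.0 / 1000.0,
        "mean_coronary_left": float(rec["Q_cor_left"].mean()),
        "mean_coronary_right": float(rec["Q_cor_right"].mean()),
        "diastole_onset_fraction": t_d / T,
        "volume_drift": drift,
    }


def calibrate(
    model: ClosedLoopModel,
    state: PhysiologicalState,
    tolerance: float = 0.02,
    max_iters: int = 40,
    coronary_flow_fraction: float = 0.04,
    coronary_left_fraction: float = 0.7,
    n_cycles: int = 10,
    dt: float = 2.0e-4,
) -> tuple[ClosedLoopModel, dict]:
    """Scale model parameters until the state's targets are met within tolerance.

    Damped fixed-point updates: Emax_l tracks systolic pressure, C_sa pulse
    pressure, R_sys cardiac output, circulating volume mean pressure.  On the
    first pass the coronary branch resistances are set so that resting
    coronary flow is ``coronary_flow_fraction`` of cardiac output, split
    left/right; for a hyperaemic state only the bed multiplier (already in
    ``model.coronary_factor``) differs.  Deterministic.

    Returns the calibrated model and the last simulation summary.  Raises
    ``RuntimeError`` listing the missed targets if not converged.
    """
    m = replace(model, heart_rate=state.heart_rate,
                coronary_factor=state.coronary_resistance_factor)

    if state.coronary_resistance_factor == 1.0:
        # anchor branch totals to the resting targets
        map_cgs = mmhg_to_cgs(state.mean_pressure)
        q_cor = coronary_flow_fraction * lmin_to_mls(state.cardiac_output)
        m.R_cor_left = map_cgs / (coronary_left_fraction * q_cor)
        m.R_cor_right = map_cgs / ((1.0 - coronary_left_fraction) * q_cor)

    sys_t, dia_t = state.systolic, state.diastolic
    pp_t = sys_t - dia_t
    map_t = state.mean_pressure
    co_t = state.cardiac_output
    damp = 0.7
    out = simulate_closed_loop(m, n_cycles=n_cycles, dt=dt)
    for _ in range(max_iters):
        errs = {
            "systolic": out["systolic_mmhg"] / sys_t - 1.0,
            "diastolic": out["diastolic_mmhg"] / dia_t - 1.0,
            "cardiac_output": out["cardiac_output_lmin"] / co_t - 1.0,
        }
        if max(abs(e) for e in errs.values()) < tolerance:
            return m, out
        m.Emax_l *= (sys_t / out["systolic_mmhg"]) ** damp
        m.R_sys *= (dia_t / out["diastolic_mmhg"]) ** damp
        m.C_sa *= ((out["systolic_mmhg"] - out["diastolic_mmhg"]) / pp_t) ** damp
        # gentle preload (circulating volume) nudge to close the CO error
        m.P_sv += mmhg_to_cgs(1.0) * (co_t - out["cardiac_output_lmin"])
        out = simulate_closed_loop(m, n_cycles=n_cycles, dt=dt)
    missed = {k: round(v, 4) for k, v in errs.items() if abs(v) >= tolerance}
    raise RuntimeError(f"calibration did not converge; missed targets: {missed}")


def hyperaemia_transform(
    resting_model: ClosedLoopModel,
    state: PhysiologicalState = HYPERAEMIC,
    **calibrate_kwargs,
) -> tuple[ClosedLoopModel, dict]:
    """Build the hyperaemic model from a calibrated resting one.

    Applies the bed-resistance factor (0.22, i.e. a 78% reduction), switches
    the heart rate, and recalibrates the systemic side to the hyperaemic
    targets.  Conduit (epicardial) coronary resistance is left untouched.
    """
    m = replace(resting_model)
    return calibrate(m, state, **calibrate_kwargs)


def waveforms_from_simulation(
    summary: dict, state_label: str
) -> tuple[InflowWaveform, InflowWaveform, VentricularPressureTraces]:
    """Package simulation traces as boundary-condition objects.

    Returns (left inflow, right inflow, ventricular pressures); inflow
    sample arrays are closed periodically (first == last).
    """
    T = summary["period"]

    def close(arr: np.ndarray) -> np.ndarray:
        return np.append(arr, arr[0])

    t = np.append(summary["t"], T)
    d_frac = float(summary["diastole_onset_fraction"])
    left = InflowWaveform(T, close(summary["Q_cor_left"]), state_label, d_frac)
    right = InflowWaveform(T, close(summary["Q_cor_right"]), state_label, d_frac)
    vent = VentricularPressureTraces(
        T, t, close(summary["P_lv"]), close(summary["P_rv"])
    )
    return left, right, vent
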