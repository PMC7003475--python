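"""Inlet waveform and lumped coronary outlet (terminal bed) boundary models.

Each 1D terminal is closed by a five-element coronary bed,

    inlet --Ra--> node1 [Ca_bed] --Rm--> node2 [Cim biased by Pim(t)] --Rv--> Pv

where Pim(t) is the intramyocardial (ventricular) external pressure that
produces the characteristic systolic impediment of coronary flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .units import mmhg_to_cgs

__all__ = [
    "InflowWaveform",
    "TerminalBed",
    "VentricularPressureTraces",
    "total_branch_resistance",
    "distribute_resistance_murray",
    "make_terminal_bed",
    "bed_update",
    "simulate_bed",
]

#: default split of a terminal's total resistance across Ra : Rm : Rv
DEFAULT_RESISTANCE_SPLIT = (0.32, 0.52, 0.16)


@dataclass
class InflowWaveform:
    """Periodic prescribed inflow Q(t) at the tree root.

    ``samples`` live on a uniform time grid covering one period, with the
    first and last samples equal (periodicity).  ``diastole_onset_fraction``
    marks aortic valve closure as a fraction of the period.
    """

    period: float
    samples: np.ndarray
    state: str = "resting"
    diastole_onset_fraction: float = 0.4

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.samples.size < 3:
            raise ValueError("waveform needs at least 3 samples")
        if abs(self.samples[0] - self.samples[-1]) > 1e-9 * max(
            1.0, float(np.max(np.abs(self.samples)))
        ):
            raise ValueError("waveform must be periodic (first sample == last)")
        if self.mean_flow <= 0:
            raise ValueError("mean inflow must be positive")
        if not 0.0 < self.diastole_onset_fraction < 1.0:
            raise ValueError("diastole_onset_fraction must be in (0, 1)")

    @property
    def times(self) -> np.ndarray:
        return np.linspace(0.0, self.period, self.samples.size)

    @property
    def mean_flow(self) -> float:
        """Cycle-mean flow, cm^3/s (trapezoid over the uniform grid)."""
        return float(np.trapezoid(self.samples, self.times) / self.period)

    def __call__(self, t) -> np.ndarray | float:
        """Interpolated flow at time t (periodically wrapped)."""
        tau = np.mod(t, self.period)
        out = np.interp(tau, self.times, self.samples)
        return float(out) if np.ndim(t) == 0 else out

    def scaled(self, factor: float) -> "InflowWaveform":
        return InflowWaveform(
            period=self.period,
            samples=self.samples * factor,
            state=self.state,
            diastole_onset_fraction=self.diastole_onset_fraction,
        )


@dataclass
class VentricularPressureTraces:
    """Periodic left/right ventricular pressure traces (dyn/cm^2)."""

    period: float
    times: np.ndarray
    p_lv: np.ndarray
    p_rv: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.p_lv = np.asarray(self.p_lv, dtype=float)
        self.p_rv = np.asarray(self.p_rv, dtype=float)
        if not (self.times.size == self.p_lv.size == self.p_rv.size):
            raise ValueError("trace arrays must share one time grid")
        if not float(np.max(self.p_lv)) > float(np.max(self.p_rv)) > 0:
            raise ValueError("expected max P_LV > max P_RV > 0")

    def pim(self, t, side: str, right_scale: float = 0.5) -> float:
        """Intramyocardial pressure for a bed on the given side at time t."""
        tau = np.mod(t, self.period)
        trace = self.p_lv if side == "left" else right_scale * self.p_rv
        out = np.interp(tau, self.times, trace)
        return float(out) if np.ndim(t) == 0 else out


@dataclass
class TerminalBed:
    """Five-element lumped coronary outlet with ventricular external pressure."""

    Ra: float
    Rm: float
    Rv: float
    Ca_bed: float
    Cim: float
    Pv: float = mmhg_to_cgs(5.0)
    side: str = "left"
    # state: pressures at the two storage nodes, dyn/cm^2
    P1: float = 0.0
    P2: float = 0.0

    def __post_init__(self) -> None:
        if min(self.Ra, self.Rm, self.Rv) <= 0:
            raise ValueError("all bed resistances must be positive")
        if self.Ca_bed <= 0 or self.Cim < 0:
            raise ValueError("bed compliances must be non-negative (Ca_bed > 0)")

    @property
    def total_resistance(self) -> float:
        return self.Ra + self.Rm + self.Rv

    def initialize(self, pressure: float) -> None:
        """Start both storage nodes at the given (diastolic) pressure."""
        self.P1 = pressure
        self.P2 = pressure


def total_branch_resistance(systolic_mmhg: float, diastolic_mmhg: float,
                            q_branch: float) -> float:
    """Total resistance of a coronary branch, dyn.s/cm^5.

    R = (systolic/3 + 2*diastolic/3) / Q with the pressure estimate converted
    from mmHg; ``q_branch`` is the branch's cycle-mean inflow in cm^3/s.
    """
    if q_branch <= 0:
        raise ValueError("branch flow must be positive")
    if systolic_mmhg <= 0 or diastolic_mmhg <= 0:
        raise ValueError("pressures must be positive")
    mean_p = mmhg_to_cgs(systolic_mmhg / 3.0 + 2.0 * diastolic_mmhg / 3.0)
    return mean_p / q_branch


def distribute_resistance_murray(
    r_branch: float, terminal_diameters, power: float = 2.27
):
    """Split a branch resistance over terminals by the d^power Murray weighting.

    Returns per-terminal resistances whose parallel combination equals
    ``r_branch`` exactly; larger terminals receive lower resistance.
    """
    d = np.asarray(terminal_diameters, dtype=float)
    if d.size == 0:
        raise ValueError("no terminal diameters given")
    if np.any(d <= 0):
        raise ValueError("terminal diameters must be positive")
    weights = d**power
    return r_branch * weights.sum() / weights


def make_terminal_bed(
    r_total: float,
    side: str = "left",
    split: tuple[float, float, float] = DEFAULT_RESISTANCE_SPLIT,
    tau_a: float = 0.25,
    tau_im: float = 0.04,
    pv: float = mmhg_to_cgs(5.0),
) -> TerminalBed:
    """Build a bed from its total resistance with default compliance scaling.

    Compliances are set from fixed time constants (``Ca_bed = tau_a/r_total``,
    ``Cim = tau_im/r_total``) so that beds of different resistance share the
    same dynamics.
    """
    fa, fm, fv = split
    if abs(fa + fm + fv - 1.0) > 1e-9:
        raise ValueError("resistance split fractions must sum to 1")
    return TerminalBed(
        Ra=fa * r_total,
        Rm=fm * r_total,
        Rv=fv * r_total,
        Ca_bed=tau_a / r_total,
        Cim=tau_im / r_total,
        Pv=pv,
        side=side,
    )


def bed_update(bed: TerminalBed, q_in: float, pim_old: float, pim_new: float,
               dt: float) -> float:
    """Advance the bed ODEs one step (Crank-Nicolson) for a given inlet flow.

    Returns the new inlet pressure P_in = P1 + Ra*q_in.  The node2 balance
    carries the intramyocardial bias term Cim * dPim/dt.
    """
    a11 = bed.Ca_bed / dt + 0.5 / bed.Rm
    a12 = -0.5 / bed.Rm
    a21 = -0.5 / bed.Rm
    a22 = bed.Cim / dt + 0.5 / bed.Rm + 0.5 / bed.Rv
    b1 = (
        bed.Ca_bed / dt * bed.P1
        + q_in
        - 0.5 * (bed.P1 - bed.P2) / bed.Rm
    )
    b2 = (
        bed.Cim / dt * bed.P2
        + 0.5 * (bed.P1 - bed.P2) / bed.Rm
        - 0.5 * (bed.P2 - bed.Pv) / bed.Rv
        + 0.5 * bed.Pv / bed.Rv
        + bed.Cim * (pim_new - pim_old) / dt
    )
    det = a11 * a22 - a12 * a21
    if det == 0:
        raise FloatingPointError("singular bed update (dt too large?)")
    p1_new = (b1 * a22 - a12 * b2) / det
    p2_new = (a11 * b2 - a21 * b1) / det
    if not (np.isfinite(p1_new) and np.isfinite(p2_new)):
        raise FloatingPointError("terminal bed update diverged (reduce dt)")
    bed.P1, bed.P2 = float(p1_new), float(p2_new)
    return bed.P1 + bed.Ra * q_in


def simulate_bed(bed: TerminalBed, q_of_t, pim_of_t, t_end: float, dt: float):
    """Drive a bed with prescribed inlet flow and Pim; return (t, P_in) arrays.

    Convenience harness for unit testing the bed in isolation.
    """
    n = int(round(t_end / dt))
    t = np.arange(n + 1) * dt
    p_in = np.empty(n + 1)
    p_in[0] = bed.P1 + bed.Ra * float(q_of_t(0.0))
    for i in range(n):
        q = float(q_of_t(t[i + 1]))
        p_in[i + 1] = bed_update(
            bed, q, float(pim_of_t(t[i])), float(pim_of_t(t[i + 1])), dt
        )
    return t, p_in
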