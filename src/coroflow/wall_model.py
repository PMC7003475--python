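"""Viscoelastic tube law closing the 1D pressure-flow system.

The wall model is an algebraic pressure-area relation

    P - P0 - Pext = (2 rho c0^2 / b) * ((A/A0)^(b/2) - 1) + P_visc

with a diameter-dependent reference wave speed

    c0(D0) = sqrt( (2 / (3 rho)) * (k1 * exp(k2 * D0 / 2) + k3) )

a stiffness exponent b = 2 rho c0^2 / (P0 - Pcollapse), and a rate-dependent
(viscoelastic) pressure contribution P_visc = Gamma / (A0 sqrt(A)) * dA/dt
with Gamma = gamma_slope * D + gamma_intercept.

Note on the stiffness constants: the physiological defaults are
k1 = 2e7 g/s^2/cm, k2 = -22.5 1/cm, k3 = 8.65e5 g/s^2/cm, which give
reference wave speeds of several m/s for coronary calibres.  All three are
plain configuration values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .units import mmhg_to_cgs

__all__ = [
    "WallParams",
    "reference_wave_speed",
    "stiffness_exponent",
    "elastic_pressure",
    "inverse_area",
    "compliance",
    "wall_viscosity",
    "viscoelastic_pressure",
]


@dataclass
class WallParams:
    """Wall material and reference-state parameters (CGS units).

    ``P0`` should be bound to the diastolic pressure of the physiological
    state being simulated; ``Pext`` is the external pressure seen by the
    vessel wall (0 for epicardial segments -- ventricular pressure acts on
    the terminal beds, not on the 1D segments).
    """

    rho: float = 1.05                      # g/cm^3
    mu: float = 0.04                       # Poise; used by the solver friction term
    k1: float = 2.0e7                      # g/s^2/cm
    k2: float = -22.5                      # 1/cm
    k3: float = 8.65e5                     # g/s^2/cm
    P0: float = mmhg_to_cgs(74.0)          # dyn/cm^2 (diastolic reference)
    Pcollapse: float = mmhg_to_cgs(-10.0)  # dyn/cm^2
    Pext: float = 0.0                      # dyn/cm^2
    gamma_slope: float = 100.0             # Gamma = gamma_slope*D + gamma_intercept
    gamma_intercept: float = 400.0

    def __post_init__(self) -> None:
        if self.rho <= 0:
            raise ValueError("rho must be positive")
        if self.P0 <= self.Pcollapse:
            raise ValueError("P0 must exceed Pcollapse")
        if self.k1 <= 0 or self.k3 <= 0:
            raise ValueError("k1 and k3 must be positive")
        if self.k2 >= 0:
            raise ValueError("k2 must be negative")

    def to_dict(self) -> dict:
        return asdict(self)


def reference_wave_speed(D0, params: WallParams):
    """Reference pulse-wave speed c0 (cm/s) from the reference diameter (cm).

    Empirical exponential-plus-offset fit; monotonically decreasing in D0
    for k2 < 0.
    """
    D0 = np.asarray(D0, dtype=float)
    if np.any(D0 <= 0):
        raise ValueError("reference diameter must be positive")
    stiff = params.k1 * np.exp(params.k2 * D0 / 2.0) + params.k3
    out = np.sqrt(2.0 * stiff / (3.0 * params.rho))
    return float(out) if out.ndim == 0 else out


def stiffness_exponent(c0, params: WallParams):
    """Tube-law exponent b = 2 rho c0^2 / (P0 - Pcollapse)."""
    if params.P0 <= params.Pcollapse:
        raise ValueError("P0 must exceed Pcollapse")
    c0 = np.asarray(c0, dtype=float)
    out = 2.0 * params.rho * c0**2 / (params.P0 - params.Pcollapse)
    return float(out) if out.ndim == 0 else out


def elastic_pressure(A, A0, c0, b, params: WallParams):
    """Elastic transmural pressure P(A) (dyn/cm^2); strictly increasing in A."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0) or np.any(np.asarray(A0) <= 0):
        raise ValueError("areas must be positive")
    out = params.P0 + params.Pext + (2.0 * params.rho * np.asarray(c0) ** 2 / b) * (
        (A / A0) ** (np.asarray(b) / 2.0) - 1.0
    )
    return float(out) if out.ndim == 0 else out


def inverse_area(P, A0, c0, b, params: WallParams):
    """Invert the elastic tube law: area A(P) (cm^2).

    Raises if the pressure lies below the collapse branch of the law
    (argument of the power non-positive).
    """
    P = np.asarray(P, dtype=float)
    arg = 1.0 + np.asarray(b) * (P - params.P0 - params.Pext) / (
        2.0 * params.rho * np.asarray(c0) ** 2
    )
    if np.any(arg <= 0):
        raise ValueError("pressure below collapse limit of the tube law")
    out = np.asarray(A0) * arg ** (2.0 / np.asarray(b))
    return float(out) if out.ndim == 0 else out


def compliance(A, A0, c0, b, params: WallParams):
    """Analytic compliance Ca = dA/dP of the elastic law (cm^2 per dyn/cm^2)."""
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0) or np.any(np.asarray(A0) <= 0):
        raise ValueError("areas must be positive")
    out = np.asarray(A0) / (params.rho * np.asarray(c0) ** 2) * (A / A0) ** (
        1.0 - np.asarray(b) / 2.0
    )
    return float(out) if out.ndim == 0 else out


def wall_viscosity(D, params: WallParams):
    """Wall viscous coefficient Gamma(D) = slope*D + intercept (linear in D)."""
    D = np.asarray(D, dtype=float)
    out = params.gamma_slope * D + params.gamma_intercept
    return float(out) if out.ndim == 0 else out


def viscoelastic_pressure(A, dA_dt, A0, gamma):
    """Rate-dependent pressure contribution Gamma/(A0 sqrt(A)) * dA/dt.

    Zero in steady state; dissipative (same sign as dA/dt).
    """
    A = np.asarray(A, dtype=float)
    if np.any(A <= 0):
        raise ValueError("area must be positive")
    out = np.asarray(gamma) / (np.asarray(A0) * np.sqrt(A)) * np.asarray(dA_dt)
    return float(out) if out.ndim == 0 else out
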