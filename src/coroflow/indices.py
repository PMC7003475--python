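"""Pressure-ratio indices (cFFR, ciFR), wave-free window, wave separation.

cFFR is the cycle mean of the instantaneous distal/proximal pressure ratio
under hyperaemia; ciFR is the same ratio at rest averaged over the diastolic
wave-free window only.  Both use the mean-of-ratio convention (not ratio of
means), per their literal definitions.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from . import tier1
from .boundaries import (
    make_terminal_bed,
    distribute_resistance_murray,
    total_branch_resistance,
)
from .geometry import CoronaryNetwork, StenosisSpec, apply_stenosis
from .solver1d import (
    BoundaryConditions,
    SimulationResult,
    SolverConfig,
    run_to_periodic,
)
from .units import cgs_to_mmhg
from .wall_model import WallParams, mmhg_to_cgs

__all__ = [
    "ProbePair",
    "IndexResult",
    "DiagnosticRecord",
    "wave_free_window",
    "compute_cffr",
    "compute_cifr",
    "separate_waves",
    "detect_diastole_onset",
    "probe_pair_for_stenosis",
    "build_boundaries",
    "run_case",
]

GREY_ZONE = (0.86, 0.93)


@dataclass(frozen=True)
class ProbePair:
    """Proximal and distal pressure-probe locations (segment id, fraction)."""

    proximal_segment: str
    proximal_fraction: float
    distal_segment: str
    distal_fraction: float


@dataclass
class IndexResult:
    value: float
    mean_pd_mmhg: float
    mean_pp_mmhg: float
    window: tuple[float, float]


@dataclass
class DiagnosticRecord:
    """One patient-equivalent case: both indices plus provenance."""

    case_id: str
    cffr: float
    cifr: float
    wave_free_window: tuple[float, float]
    probes: ProbePair
    metadata: dict = field(default_factory=dict)

    @property
    def cifr_zone(self) -> str:
        lo, hi = GREY_ZONE
        if self.cifr < lo:
            return "treat"
        if self.cifr <= hi:
            return "grey"
        return "defer"

    def to_json(self) -> str:
        doc = asdict(self)
        doc["cifr_zone"] = self.cifr_zone
        return json.dumps(doc, default=lambda o: list(o) if isinstance(o, tuple) else str(o))

    @classmethod
    def from_json(cls, text: str) -> "DiagnosticRecord":
        doc = json.loads(text)
        doc.pop("cifr_zone", None)
        doc["probes"] = ProbePair(**doc["probes"])
        doc["wave_free_window"] = tuple(doc["wave_free_window"])
        return cls(**doc)


def wave_free_window(diastole_onset: float, period: float) -> tuple[float, float]:
    """Diastolic wave-free window: from 1/5 into diastole to end of cycle."""
    if not 0.0 < diastole_onset < period:
        raise ValueError("diastole onset must lie inside the cycle")
    t_start = diastole_onset + 0.2 * (period - diastole_onset)
    if period - t_start < 0.05 * period:
        raise ValueError("degenerate wave-free window (< 5% of the cycle)")
    return (t_start, period)


def _mean_ratio(t: np.ndarray, pd: np.ndarray, pp: np.ndarray,
                window: tuple[float, float] | None) -> IndexResult:
    if np.any(pp <= 0):
        raise ValueError("proximal pressure crosses zero; ratio undefined")
    if window is not None:
        mask = (t >= window[0]) & (t <= window[1])
        if mask.sum() < 2:
            raise ValueError("wave-free window contains too few samples")
        t, pd, pp = t[mask], pd[mask], pp[mask]
        span = (window[0], window[1])
    else:
        span = (float(t[0]), float(t[-1]))
    ratio = pd / pp
    value = float(np.trapezoid(ratio, t) / (t[-1] - t[0]))
    return IndexResult(
        value=value,
        mean_pd_mmhg=cgs_to_mmhg(float(np.trapezoid(pd, t) / (t[-1] - t[0]))),
        mean_pp_mmhg=cgs_to_mmhg(float(np.trapezoid(pp, t) / (t[-1] - t[0]))),
        window=span,
    )


def compute_cffr(result: SimulationResult, probes: ProbePair) -> IndexResult:
    """Cycle mean of Pd/Pp from a converged hyperaemic simulation."""
    pd = result.field_at(probes.distal_segment, probes.distal_fraction, "P")
    pp = result.field_at(probes.proximal_segment, probes.proximal_fraction, "P")
    return _mean_ratio(result.t, pd, pp, window=None)


def compute_cifr(result: SimulationResult, probes: ProbePair,
                 diastole_onset: float) -> IndexResult:
    """Mean of Pd/Pp over the wave-free window from a resting simulation."""
    window = wave_free_window(diastole_onset, result.period)
    pd = result.field_at(probes.distal_segment, probes.distal_fraction, "P")
    pp = result.field_at(probes.proximal_segment, probes.proximal_fraction, "P")
    return _mean_ratio(result.t, pd, pp, window=window)


def detect_diastole_onset(t: np.ndarray, p: np.ndarray) -> float:
    """Fallback dicrotic-notch detector: local minimum of dP/dt after the peak.

    For externally supplied pressure traces where the valve-closure time is
    unknown.
    """
    dp = np.gradient(p, t)
    ipk = int(np.argmax(p))
    if ipk >= len(t) - 2:
        raise ValueError("pressure peak at trace end; cannot locate diastole")
    seg = dp[ipk:]
    return float(t[ipk + int(np.argmin(seg))])


def separate_waves(p: np.ndarray, q: np.ndarray, a: np.ndarray,
                   c: np.ndarray, rho: float) -> dict[str, np.ndarray]:
    """Forward/backward pressure-wave separation via the water-hammer relation.

    dP+- = (dP +- rho c dU)/2 with U = Q/A; returns the incremental and
    cumulative components.  dP+ + dP- = dP identically.
    """
    u = q / a
    dp = np.diff(p)
    du = np.diff(u)
    zc = rho * c[:-1] * du
    dp_f = 0.5 * (dp + zc)
    dp_b = 0.5 * (dp - zc)
    return {
        "dP_forward": dp_f,
        "dP_backward": dp_b,
        "P_forward": np.concatenate(([0.0], np.cumsum(dp_f))),
        "P_backward": np.concatenate(([0.0], np.cumsum(dp_b))),
    }


def probe_pair_for_stenosis(
    network: CoronaryNetwork,
    stenosis: StenosisSpec | None,
    distal_offset_cm: float = 1.0,
    distal_offset_diameters: float = 3.0,
) -> ProbePair:
    """Default probe placement: root inlet proximal, distal of the throat.

    The distal probe sits max(1 cm, 3 distal diameters) beyond the stenosis
    throat, clamped to the stenosed segment; without a stenosis it sits at
    the root's distal end.
    """
    root = network.root_segment_id
    if stenosis is None:
        return ProbePair(root, 0.0, root, 1.0)
    seg = network.segments[stenosis.segment_id]
    offset = max(distal_offset_cm, distal_offset_diameters * seg.distal_diameter)
    x = min(stenosis.center_fraction * seg.length + offset, seg.length)
    return ProbePair(root, 0.0, stenosis.segment_id, x / seg.length)


def build_boundaries(
    network: CoronaryNetwork,
    inflow,
    ventricular,
    state: "tier1.PhysiologicalState",
    murray_power: float = 2.27,
    pim_right_scale: float = 0.5,
    bed_kwargs: dict | None = None,
) -> BoundaryConditions:
    """Second-tier boundary assembly for one physiological state.

    The branch's total resistance comes from the mean-pressure/mean-flow
    relation with the state's cuff pressures and the tier-1 branch inflow;
    it is then distributed over the terminals by the proximal-diameter
    Murray weighting (power 2.27) and wrapped into coronary beds.
    """
    r_branch = total_branch_resistance(
        state.systolic, state.diastolic, inflow.mean_flow
    )
    terms = network.terminal_segment_ids
    diameters = [network.segments[t].proximal_diameter for t in terms]
    r_terms = distribute_resistance_murray(r_branch, diameters, power=murray_power)
    outlets = {
        t: make_terminal_bed(r, side=network.side, **(bed_kwargs or {}))
        for t, r in zip(terms, r_terms)
    }
    return BoundaryConditions(
        inflow=inflow,
        outlets=outlets,
        ventricular=ventricular,
        pim_right_scale=pim_right_scale,
    )


def run_case(
    network: CoronaryNetwork,
    stenosis: StenosisSpec | None,
    tier1_outputs: dict,
    case_id: str = "case",
    solver_config: SolverConfig | None = None,
    probes: ProbePair | None = None,
) -> DiagnosticRecord:
    """One patient-equivalent pipeline pass: geometry -> both indices.

    ``tier1_outputs`` maps state label -> (state, inflow, ventricular
    traces) as produced by the tier-1 closed loop; the same geometry and
    per-state waveforms feed both the resting and hyperaemic runs, so only
    geometry and downstream resistance differ between the two indices.
    """
    net = apply_stenosis(network, stenosis) if stenosis is not None else network
    if probes is None:
        probes = probe_pair_for_stenosis(net, stenosis)

    results: dict[str, SimulationResult] = {}
    onsets: dict[str, float] = {}
    for label in ("resting", "hyperaemic"):
        state, inflow, vent = tier1_outputs[label]
        wall = WallParams(P0=mmhg_to_cgs(state.diastolic))
        bc = build_boundaries(net, inflow, vent, state)
        try:
            results[label] = run_to_periodic(net, wall, bc, solver_config)
        except Exception as exc:
            raise RuntimeError(f"stage solver1d[{label}] failed: {exc}") from exc
        onsets[label] = inflow.diastole_onset_fraction * inflow.period

    cffr = compute_cffr(results["hyperaemic"], probes)
    cifr = compute_cifr(results["resting"], probes, onsets["resting"])
    return DiagnosticRecord(
        case_id=case_id,
        cffr=cffr.value,
        cifr=cifr.value,
        wave_free_window=cifr.window,
        probes=probes,
        metadata={
            "stenosis": None if stenosis is None else vars(stenosis).copy(),
            "resting": results["resting"].metadata,
            "hyperaemic": results["hyperaemic"].metadata,
            "mean_pp_mmhg": cffr.mean_pp_mmhg,
            "mean_pd_mmhg": cffr.mean_pd_mmhg,
        },
    )
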