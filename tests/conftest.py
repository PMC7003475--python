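"""Shared fixtures: geometries, wall parameters, cached tier-1 outputs."""

from __future__ import annotations

import math

import numpy as np
import pytest

from coroflow import tier1
from coroflow.geometry import VesselSegment, build_network
from coroflow.units import mmhg_to_cgs
from coroflow.wall_model import WallParams


@pytest.fixture
def wall() -> WallParams:
    return WallParams(P0=mmhg_to_cgs(74.0))


@pytest.fixture
def stiff_wall() -> WallParams:
    """Nearly rigid wall (k3 scaled up 1000x -> c0 ~ 30x) for steady oracles."""
    return WallParams(P0=mmhg_to_cgs(74.0), k3=8.65e8)


def uniform_segment(sid: str, length: float, diameter: float,
                    prox: str, dist: str, n_points: int = 5) -> VesselSegment:
    area = math.pi * (diameter / 2.0) ** 2
    return VesselSegment(sid, length, np.full(n_points, area), prox, dist)


@pytest.fixture
def single_vessel():
    """One uniform D=0.3 cm, L=5 cm vessel."""
    return build_network([uniform_segment("v", 5.0, 0.3, "a", "b")], {})


@pytest.fixture
def twin_tree():
    """Symmetric bifurcation: one parent, two identical daughters."""
    segs = [
        uniform_segment("p", 3.0, 0.35, "n0", "n1"),
        uniform_segment("d1", 2.0, 0.25, "n1", "n2"),
        uniform_segment("d2", 2.0, 0.25, "n1", "n3"),
    ]
    return build_network(segs, {"p": ["d1", "d2"]})


@pytest.fixture(scope="session")
def tier1_calibrated():
    """Calibrated resting and hyperaemic closed-loop models (slow; shared)."""
    m_rest, out_rest = tier1.calibrate(tier1.ClosedLoopModel(), tier1.RESTING)
    m_hyp, out_hyp = tier1.hyperaemia_transform(m_rest)
    return {"resting": (m_rest, out_rest), "hyperaemic": (m_hyp, out_hyp)}


@pytest.fixture(scope="session")
def tier1_outputs(tier1_calibrated):
    """{state label: (state, left inflow, ventricular traces)} for run_case."""
    out = {}
    for label, state in (("resting", tier1.RESTING), ("hyperaemic", tier1.HYPERAEMIC)):
        _, summary = tier1_calibrated[label]
        left, _right, vent = tier1.waveforms_from_simulation(summary, label)
        out[label] = (state, left, vent)
    return out
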