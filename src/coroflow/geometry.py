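"""Coronary tree geometry: segments, networks, stenoses, synthetic trees, I/O.

A network is a rooted tree of tapering 1D segments.  Axial coordinate x runs
proximal -> distal within each segment; positive flow is proximal -> distal.
Areas are cm^2, lengths cm.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "NetworkValidationError",
    "VesselSegment",
    "StenosisSpec",
    "CoronaryNetwork",
    "build_network",
    "apply_stenosis",
    "generate_synthetic_tree",
    "read_network",
    "write_network",
]

SCHEMA_VERSION = "1"


class NetworkValidationError(ValueError):
    """Raised when a network description is structurally invalid."""


@dataclass
class VesselSegment:
    """One tapering 1D vessel with a reference area profile A0(x).

    ``area_profile`` holds A0 sampled uniformly on [0, length] at
    ``n_points`` stations (including both ends).
    """

    id: str
    length: float
    area_profile: np.ndarray
    proximal_node: str
    distal_node: str

    def __post_init__(self) -> None:
        self.area_profile = np.asarray(self.area_profile, dtype=float)
        if self.length <= 0:
            raise NetworkValidationError(f"segment {self.id!r}: length must be > 0")
        if self.area_profile.ndim != 1 or self.area_profile.size < 2:
            raise NetworkValidationError(
                f"segment {self.id!r}: area profile needs >= 2 samples"
            )
        if np.any(self.area_profile <= 0):
            raise NetworkValidationError(f"segment {self.id!r}: areas must be > 0")

    @property
    def n_points(self) -> int:
        return int(self.area_profile.size)

    @property
    def x(self) -> np.ndarray:
        """Axial sample positions, cm."""
        return np.linspace(0.0, self.length, self.n_points)

    @property
    def diameter_profile(self) -> np.ndarray:
        """Reference diameters D0(x) = 2 sqrt(A0/pi), cm."""
        return 2.0 * np.sqrt(self.area_profile / math.pi)

    @property
    def proximal_diameter(self) -> float:
        return float(self.diameter_profile[0])

    @property
    def distal_diameter(self) -> float:
        return float(self.diameter_profile[-1])

    def area_at(self, fraction: float) -> float:
        """Interpolated A0 at a fractional position along the axis."""
        return float(np.interp(fraction * self.length, self.x, self.area_profile))

    def copy(self) -> "VesselSegment":
        return VesselSegment(
            id=self.id,
            length=self.length,
            area_profile=self.area_profile.copy(),
            proximal_node=self.proximal_node,
            distal_node=self.distal_node,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VesselSegment):
            return NotImplemented
        return (
            self.id == other.id
            and self.length == other.length
            and self.proximal_node == other.proximal_node
            and self.distal_node == other.distal_node
            and self.area_profile.shape == other.area_profile.shape
            and bool(np.all(self.area_profile == other.area_profile))
        )


@dataclass
class StenosisSpec:
    """Focal or diffuse lumen narrowing applied to one segment.

    ``area_reduction`` is the fractional A0 reduction at the throat;
    ``shape`` is 'cosine' (C1 bell, focal) or 'trapezoid' (diffuse).
    """

    segment_id: str
    center_fraction: float
    stenosed_length: float
    area_reduction: float
    shape: str = "cosine"

    def __post_init__(self) -> None:
        if not 0.0 < self.center_fraction < 1.0:
            raise ValueError("center_fraction must be in (0, 1)")
        if not 0.0 <= self.area_reduction < 1.0:
            raise ValueError("area_reduction must be in [0, 1)")
        if self.stenosed_length <= 0:
            raise ValueError("stenosed_length must be > 0")
        if self.shape not in ("cosine", "trapezoid"):
            raise ValueError(f"unknown stenosis shape {self.shape!r}")


@dataclass
class CoronaryNetwork:
    """Rooted tree of vessel segments with junction connectivity."""

    segments: dict[str, VesselSegment]
    junctions: dict[str, list[str]]
    root_segment_id: str
    terminal_segment_ids: list[str]
    side: str = "left"
    metadata: dict = field(default_factory=dict)

    def children_of(self, segment_id: str) -> list[str]:
        return self.junctions.get(segment_id, [])

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CoronaryNetwork):
            return NotImplemented
        return (
            self.segments == other.segments
            and self.junctions == other.junctions
            and self.root_segment_id == other.root_segment_id
            and self.terminal_segment_ids == other.terminal_segment_ids
            and self.side == other.side
        )


def build_network(
    segments: list[VesselSegment],
    connectivity: dict[str, list[str]],
    side: str = "left",
    metadata: dict | None = None,
) -> CoronaryNetwork:
    """Assemble and validate a rooted tree from segments and connectivity.

    ``connectivity`` maps each junction's parent segment id to the ordered
    list of child segment ids.  Raises :class:`NetworkValidationError` on
    cycles, orphans, duplicate or unknown ids, or multiple roots.
    """
    if side not in ("left", "right"):
        raise NetworkValidationError(f"side must be 'left' or 'right', got {side!r}")
    seg_map: dict[str, VesselSegment] = {}
    for seg in segments:
        if seg.id in seg_map:
            raise NetworkValidationError(f"duplicate segment id {seg.id!r}")
        seg_map[seg.id] = seg

    parent_of: dict[str, str] = {}
    for parent, children in connectivity.items():
        if parent not in seg_map:
            raise NetworkValidationError(f"junction parent {parent!r} is not a segment")
        if len(children) < 1:
            raise NetworkValidationError(f"junction at {parent!r} has no children")
        for child in children:
            if child not in seg_map:
                raise NetworkValidationError(f"junction child {child!r} is not a segment")
            if child in parent_of:
                raise NetworkValidationError(f"segment {child!r} has multiple parents")
            parent_of[child] = parent

    roots = [sid for sid in seg_map if sid not in parent_of]
    if not roots:
        raise NetworkValidationError("cycle detected: no root segment exists")
    if len(roots) > 1:
        raise NetworkValidationError(
            f"multiple roots: {sorted(roots)!r} are not reachable from a single inlet"
        )
    root = roots[0]

    # DFS from the root: every segment must be reached exactly once.
    visited: set[str] = set()
    stack = [root]
    while stack:
        sid = stack.pop()
        if sid in visited:
            raise NetworkValidationError(f"cycle detected at segment {sid!r}")
        visited.add(sid)
        stack.extend(connectivity.get(sid, []))
    orphans = set(seg_map) - visited
    if orphans:
        raise NetworkValidationError(
            f"orphan segment(s) not reachable from root: {sorted(orphans)!r}"
        )

    # Node consistency: each child's proximal node is its parent's distal node.
    for parent, children in connectivity.items():
        for child in children:
            if seg_map[child].proximal_node != seg_map[parent].distal_node:
                raise NetworkValidationError(
                    f"segment {child!r} proximal node does not match "
                    f"distal node of its parent {parent!r}"
                )

    terminals = [sid for sid in seg_map if sid not in connectivity]
    return CoronaryNetwork(
        segments=seg_map,
        junctions={p: list(c) for p, c in connectivity.items()},
        root_segment_id=root,
        terminal_segment_ids=terminals,
        side=side,
        metadata=dict(metadata or {}),
    )


def _stenosis_factor(x: np.ndarray, spec: StenosisSpec, length: float) -> np.ndarray:
    xc = spec.center_fraction * length
    half = spec.stenosed_length / 2.0
    lo, hi = xc - half, xc + half
    if lo < -1e-12 or hi > length + 1e-12:
        raise ValueError(
            f"stenosis window [{lo:.3g}, {hi:.3g}] exceeds segment bounds "
            f"[0, {length:.3g}] on {spec.segment_id!r}"
        )
    factor = np.ones_like(x)
    inside = (x >= lo) & (x <= hi)
    if spec.shape == "cosine":
        # C1 bell: full reduction at the throat, smoothly zero at the edges.
        factor[inside] = 1.0 - spec.area_reduction * 0.5 * (
            1.0 + np.cos(2.0 * math.pi * (x[inside] - xc) / spec.stenosed_length)
        )
    else:  # trapezoid: 25% linear ramps, 50% flat throat
        ramp = 0.25 * spec.stenosed_length
        xi = x[inside]
        depth = np.ones_like(xi)
        left = xi < lo + ramp
        right = xi > hi - ramp
        depth[left] = (xi[left] - lo) / ramp
        depth[right] = (hi - xi[right]) / ramp
        factor[inside] = 1.0 - spec.area_reduction * depth
    return factor


def apply_stenosis(network: CoronaryNetwork, spec: StenosisSpec) -> CoronaryNetwork:
    """Return a new network whose segment A0 profile is narrowed per ``spec``.

    Reductions from stacked specs compose multiplicatively; areas outside the
    stenosed window are untouched.
    """
    if spec.segment_id not in network.segments:
        raise NetworkValidationError(f"unknown segment {spec.segment_id!r}")
    segments = [s.copy() for s in network.segments.values()]
    for seg in segments:
        if seg.id == spec.segment_id:
            factor = _stenosis_factor(seg.x, spec, seg.length)
            seg.area_profile = seg.area_profile * factor
    out = build_network(
        segments, network.junctions, side=network.side, metadata=dict(network.metadata)
    )
    stenoses = list(out.metadata.get("stenoses", []))
    stenoses.append(vars(spec).copy())
    out.metadata["stenoses"] = stenoses
    return out


def generate_synthetic_tree(
    seed: int,
    n_generations: int,
    root_diameter: float = 0.35,
    gamma: float = 2.27,
    root_length: float | None = None,
    length_range: tuple[float, float] = (1.0, 4.0),
    taper_range: tuple[float, float] = (0.85, 1.0),
    split_asymmetry: float = 0.15,
    target_dx: float = 0.05,
    side: str = "left",
) -> CoronaryNetwork:
    """Generate a deterministic binary tree emulating segmented CCTA output.

    Daughter diameters satisfy d_parent^gamma = sum d_child^gamma exactly at
    every junction (generalized Murray relation); lengths and taper factors
    are drawn uniformly from the stated ranges, which are recorded in the
    network metadata.  Fully deterministic for a fixed seed.
    """
    if n_generations < 1:
        raise ValueError("n_generations must be >= 1")
    if not 0.1 <= root_diameter <= 0.6:
        raise ValueError("root_diameter outside plausible coronary range [0.1, 0.6] cm")
    rng = np.random.default_rng(seed)

    segments: list[VesselSegment] = []
    connectivity: dict[str, list[str]] = {}
    node_counter = [0]

    def new_node() -> str:
        node_counter[0] += 1
        return f"n{node_counter[0]}"

    def make_segment(sid: str, d_prox: float, prox_node: str, first: bool) -> VesselSegment:
        if first and root_length is not None:
            length = float(root_length)
        else:
            length = float(rng.uniform(*length_range))
        taper = float(rng.uniform(*taper_range))
        n_pts = max(2, int(round(length / target_dx)) + 1)
        d = np.linspace(d_prox, d_prox * taper, n_pts)
        area = math.pi * (d / 2.0) ** 2
        return VesselSegment(
            id=sid,
            length=length,
            area_profile=area,
            proximal_node=prox_node,
            distal_node=new_node(),
        )

    root = make_segment("s0", root_diameter, new_node(), first=True)
    segments.append(root)
    frontier = [(root, 1)]
    counter = 1
    while frontier:
        parent, gen = frontier.pop(0)
        if gen >= n_generations:
            continue
        # Split the gamma-power "budget" of the parent's distal diameter.
        w = float(rng.uniform(0.5 - split_asymmetry, 0.5 + split_asymmetry))
        dp = parent.distal_diameter
        d_children = [dp * w ** (1.0 / gamma), dp * (1.0 - w) ** (1.0 / gamma)]
        child_ids = []
        for dc in d_children:
            sid = f"s{counter}"
            counter += 1
            child = make_segment(sid, dc, parent.distal_node, first=False)
            segments.append(child)
            child_ids.append(sid)
            frontier.append((child, gen + 1))
        connectivity[parent.id] = child_ids

    metadata = {
        "generator": "generate_synthetic_tree",
        "seed": int(seed),
        "n_generations": int(n_generations),
        "root_diameter_cm": float(root_diameter),
        "gamma": float(gamma),
        "length_range_cm": list(length_range),
        "taper_range": list(taper_range),
        "split_asymmetry": float(split_asymmetry),
        "target_dx_cm": float(target_dx),
    }
    return build_network(segments, connectivity, side=side, metadata=metadata)


def _network_to_dict(network: CoronaryNetwork) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "segments": [
            {
                "id": s.id,
                "length_cm": s.length,
                "n_points": s.n_points,
                "area_profile_cm2": s.area_profile.tolist(),
                "proximal_node": s.proximal_node,
                "distal_node": s.distal_node,
            }
            for s in network.segments.values()
        ],
        "junctions": network.junctions,
        "root": network.root_segment_id,
        "side": network.side,
        "metadata": network.metadata,
    }


def write_network(network: CoronaryNetwork, path: str | Path) -> None:
    """Serialize a network to the versioned JSON format."""
    Path(path).write_text(json.dumps(_network_to_dict(network), indent=1))


def read_network(path: str | Path) -> CoronaryNetwork:
    """Read a network from JSON, validating schema version and structure."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise NetworkValidationError(f"malformed network file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise NetworkValidationError(
            f"unsupported schema version {version!r} (expected {SCHEMA_VERSION!r})"
        )
    segments = []
    for i, rec in enumerate(doc.get("segments", [])):
        for key in ("id", "length_cm", "area_profile_cm2", "proximal_node", "distal_node"):
            if key not in rec:
                raise NetworkValidationError(
                    f"segment entry {i}: missing field {key!r}"
                )
        segments.append(
            VesselSegment(
                id=rec["id"],
                length=float(rec["length_cm"]),
                area_profile=np.asarray(rec["area_profile_cm2"], dtype=float),
                proximal_node=rec["proximal_node"],
                distal_node=rec["distal_node"],
            )
        )
    return build_network(
        segments,
        {p: list(c) for p, c in doc.get("junctions", {}).items()},
        side=doc.get("side", "left"),
        metadata=doc.get("metadata", {}),
    )
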