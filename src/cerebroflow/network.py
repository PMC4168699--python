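"""Core domain types for the cerebral pipe-network model.

The vasculature is represented as a graph of nodes (junctions, inflow
points, and the outer low-pressure boundary) joined by rigid cylindrical
pipes.  Each pipe obeys the laminar Hagen–Poiseuille law, so the whole
network behaves as a linear resistance network: the hydraulic analogue of
a DC circuit, with pressure playing the role of voltage and volumetric
flow the role of current.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np

from .units import mm_to_m

__all__ = [
    "InvalidGeometryError",
    "NetworkError",
    "NetworkNode",
    "VesselSegment",
    "VascularNetwork",
    "BoundaryConditions",
    "FlowSolution",
    "poiseuille_resistance",
    "SEGMENT_CATEGORIES",
    "TERRITORIES",
]

SEGMENT_CATEGORIES = frozenset(
    {"cow", "trunk", "cortical", "la_inter", "la_intra", "drain"}
)
TERRITORIES = frozenset(
    {"MCA-R", "MCA-L", "ACA-R", "ACA-L", "PCA-R", "PCA-L", "none"}
)


class NetworkError(ValueError):
    """Structural problem with a vascular network or its boundary data."""


class InvalidGeometryError(NetworkError):
    """Non-physical vessel geometry (non-positive length/diameter/viscosity)."""


def poiseuille_resistance(length_mm: float, diameter_mm: float, viscosity: float) -> float:
    """Hydraulic resistance of a cylindrical pipe under laminar flow.

    R = 128 μ L / (π d⁴), the Hagen–Poiseuille law.

    Parameters
    ----------
    length_mm, diameter_mm:
        Pipe length and internal diameter in millimetres.
    viscosity:
        Dynamic viscosity in Pa·s.

    Returns
    -------
    float
        Resistance in Pa·s/m³, strictly positive.
    """
    if length_mm <= 0 or diameter_mm <= 0 or viscosity <= 0:
        raise InvalidGeometryError(
            "length, diameter and viscosity must all be positive "
            f"(got L={length_mm} mm, d={diameter_mm} mm, mu={viscosity} Pa.s)"
        )
    length = mm_to_m(length_mm)
    diameter = mm_to_m(diameter_mm)
    return 128.0 * viscosity * length / (math.pi * diameter**4)


@dataclass(frozen=True)
class NetworkNode:
    """A junction, inflow point or outer-boundary reservoir.

    ``kind`` is one of ``junction`` (interior mass-balance node), ``inlet``
    (a prescribed-inflow node: ICA or basilar origin) or ``outlet`` (the
    fixed-pressure outer boundary the drainage pipes empty into).
    """

    id: str
    kind: str = "junction"
    label: str | None = None
    position: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in {"junction", "inlet", "outlet"}:
            raise NetworkError(f"unknown node kind {self.kind!r} for node {self.id!r}")


@dataclass
class VesselSegment:
    """One cylindrical pipe: an artery segment, an anastomosis, or a drain.

    The pair (``from_node``, ``to_node``) fixes the reference orientation;
    solved flows are signed positive along it.
    """

    id: str
    from_node: str
    to_node: str
    length: float  # mm
    diameter: float  # mm
    name: str | None = None
    category: str = "cortical"
    territory: str = "none"
    branch_order: int = 0
    occluded: bool = False

    def __post_init__(self) -> None:
        if self.name is None:
            self.name = self.id
        if self.length <= 0 or self.diameter <= 0:
            raise InvalidGeometryError(
                f"segment {self.id!r}: length and diameter must be positive "
                f"(got L={self.length}, d={self.diameter})"
            )
        if self.from_node == self.to_node:
            raise NetworkError(f"segment {self.id!r} is a self-loop at {self.from_node!r}")
        if self.category not in SEGMENT_CATEGORIES:
            raise NetworkError(f"segment {self.id!r}: unknown category {self.category!r}")
        if self.territory not in TERRITORIES:
            raise NetworkError(f"segment {self.id!r}: unknown territory {self.territory!r}")
        if not 0 <= int(self.branch_order) <= 5:
            raise NetworkError(
                f"segment {self.id!r}: branch_order {self.branch_order} outside 0–5"
            )

    def resistance(self, viscosity: float) -> float:
        """Hagen–Poiseuille resistance of this pipe, Pa·s/m³."""
        return poiseuille_resistance(self.length, self.diameter, viscosity)


class VascularNetwork:
    """A node/segment graph with named anatomical roles.

    Thin container over dictionaries keyed by id; ``to_multigraph`` exposes
    the topology as a :class:`networkx.MultiGraph` (parallel pipes between
    the same node pair are legal and occur for multi-stem arteries and
    test fixtures).
    """

    def __init__(
        self,
        nodes: Iterable[NetworkNode],
        segments: Iterable[VesselSegment],
        validate: bool = True,
    ) -> None:
        self.nodes: dict[str, NetworkNode] = {}
        for node in nodes:
            if node.id in self.nodes:
                raise NetworkError(f"duplicate node id {node.id!r}")
            self.nodes[node.id] = node
        self.segments: dict[str, VesselSegment] = {}
        for seg in segments:
            if seg.id in self.segments:
                raise NetworkError(f"duplicate segment id {seg.id!r}")
            self.segments[seg.id] = seg
        if validate:
            self.validate()

    # -- construction helpers -------------------------------------------------

    def copy(self) -> "VascularNetwork":
        return VascularNetwork(
            self.nodes.values(),
            (replace(s) for s in self.segments.values()),
            validate=False,
        )

    def validate(self) -> None:
        for seg in self.segments.values():
            for nid in (seg.from_node, seg.to_node):
                if nid not in self.nodes:
                    raise NetworkError(
                        f"segment {seg.id!r} references unknown node {nid!r}"
                    )
        degree: dict[str, int] = {nid: 0 for nid in self.nodes}
        for seg in self.segments.values():
            degree[seg.from_node] += 1
            degree[seg.to_node] += 1
        for nid, node in self.nodes.items():
            if node.kind in {"inlet", "outlet"} and degree[nid] == 0:
                raise NetworkError(f"{node.kind} node {nid!r} touches no segment")
        for seg in self.segments.values():
            if seg.category == "drain":
                ends = {self.nodes[seg.from_node].kind, self.nodes[seg.to_node].kind}
                if "outlet" not in ends:
                    raise NetworkError(
                        f"drain segment {seg.id!r} does not terminate at an outlet node"
                    )

    # -- queries ---------------------------------------------------------------

    @property
    def inlet_nodes(self) -> list[NetworkNode]:
        return [n for n in self.nodes.values() if n.kind == "inlet"]

    @property
    def outlet_nodes(self) -> list[NetworkNode]:
        return [n for n in self.nodes.values() if n.kind == "outlet"]

    def segments_by_name(self) -> dict[str, VesselSegment]:
        return {s.name: s for s in self.segments.values()}

    def to_multigraph(self, include_occluded: bool = True):
        """Topology as a networkx MultiGraph; segment ids are edge keys."""
        import networkx as nx

        g = nx.MultiGraph()
        for node in self.nodes.values():
            g.add_node(node.id, kind=node.kind, label=node.label or "")
        for seg in self.segments.values():
            if seg.occluded and not include_occluded:
                continue
            g.add_edge(
                seg.from_node,
                seg.to_node,
                key=seg.id,
                name=seg.name,
                length=seg.length,
                diameter=seg.diameter,
                category=seg.category,
                territory=seg.territory,
                branch_order=seg.branch_order,
                occluded=seg.occluded,
            )
        return g

    def with_occlusions(self, segment_names: Iterable[str]) -> "VascularNetwork":
        """Copy of the network with the named segments marked occluded."""
        by_name = {s.name: s.id for s in self.segments.values()}
        net = self.copy()
        for name in segment_names:
            sid = by_name.get(name, name if name in net.segments else None)
            if sid is None:
                raise NetworkError(f"unknown segment name {name!r}")
            net.segments[sid].occluded = True
        return net

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<VascularNetwork: {len(self.nodes)} nodes, "
            f"{len(self.segments)} segments>"
        )


@dataclass(frozen=True)
class BoundaryConditions:
    """Inflow partition and outer-boundary pressure.

    Defaults follow the model's stated conditions: 75% of total inflow
    through the two internal carotids (split equally) and 25% through the
    basilar, a 5 kPa pressure over the outer boundary, and Newtonian blood
    of viscosity 3.5 mPa·s.
    """

    total_inflow: float = 750.0  # mL/min; results are % of baseline, so cancels
    inflow_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"R-ICA": 0.375, "L-ICA": 0.375, "BA": 0.25}
    )
    outlet_pressure: float = 5000.0  # Pa
    viscosity: float = 3.5e-3  # Pa·s

    def __post_init__(self) -> None:
        if self.total_inflow <= 0:
            raise NetworkError("total_inflow must be positive")
        if self.outlet_pressure <= 0:
            raise NetworkError("outlet_pressure must be positive")
        if self.viscosity <= 0:
            raise NetworkError("viscosity must be positive")
        total = math.fsum(self.inflow_fractions.values())
        if abs(total - 1.0) > 1e-12:
            raise NetworkError(
                f"inflow fractions must sum to 1 (got {total!r})"
            )
        if any(f < 0 for f in self.inflow_fractions.values()):
            raise NetworkError("inflow fractions must be non-negative")

    def inflow_for(self, node: NetworkNode) -> float:
        """Prescribed inflow for an inlet node, mL/min (keyed by label or id)."""
        key = node.label if node.label in self.inflow_fractions else node.id
        try:
            return self.total_inflow * self.inflow_fractions[key]
        except KeyError:
            raise NetworkError(
                f"no inflow fraction for inlet node {node.id!r} (label {node.label!r})"
            ) from None


@dataclass
class FlowSolution:
    """Solved steady state: signed per-segment flows and nodal pressures.

    Flows are mL/min, positive along each segment's reference orientation;
    pressures are Pa.  Nodes in islands cut off from every inlet and outlet
    carry the NaN sentinel pressure and zero incident flow.
    """

    segment_flow: dict[str, float]
    node_pressure: dict[str, float]
    residual_norm: float

    def flow_by_name(self, network: VascularNetwork) -> dict[str, float]:
        return {
            seg.name: self.segment_flow[sid]
            for sid, seg in network.segments.items()
        }

    def pressure(self, node_id: str) -> float:
        return self.node_pressure[node_id]

    def junction_imbalances(self, network: VascularNetwork) -> dict[str, float]:
        """Net signed flow at each junction node (should be ~0), mL/min."""
        net: dict[str, float] = {
            nid: 0.0 for nid, n in network.nodes.items() if n.kind == "junction"
        }
        for sid, seg in network.segments.items():
            q = self.segment_flow[sid]
            if seg.from_node in net:
                net[seg.from_node] -= q
            if seg.to_node in net:
                net[seg.to_node] += q
        return net

    def total_drain_outflow(self, network: VascularNetwork) -> float:
        """Flow delivered into the outer boundary through drain pipes, mL/min."""
        total = 0.0
        for sid, seg in network.segments.items():
            if seg.category != "drain":
                continue
            q = self.segment_flow[sid]
            # drains are oriented tip -> outlet; count flow into the outlet
            if network.nodes[seg.to_node].kind == "outlet":
                total += q
            else:
                total -= q
        return total

    def as_array(self, segment_ids: list[str]) -> np.ndarray:
        return np.array([self.segment_flow[sid] for sid in segment_ids])
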