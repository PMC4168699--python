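"""Analytic and randomized test networks, plus independent oracles.

The closed-form fixtures (single pipe, series chain, parallel pair,
Y-junction, Wheatstone bridge) carry their expected solutions, so solver
properties are testable without the canonical anatomy.  The brute-force
solver re-derives nodal analysis with dense linear algebra and its own
breadth-first component search, sharing no code path with the sparse
solver; the reachability oracle checks topology-forced zeros by graph
search alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .network import (
    BoundaryConditions,
    FlowSolution,
    NetworkError,
    NetworkNode,
    VascularNetwork,
    VesselSegment,
)
from .units import m3s_to_mlmin, mlmin_to_m3s

__all__ = [
    "FixtureSpec",
    "Fixture",
    "make_fixture",
    "brute_force_solve",
    "reachability_oracle",
]

_KINDS = {"single", "series", "parallel", "wye", "bridge", "random"}


@dataclass(frozen=True)
class FixtureSpec:
    """Recipe for a test network."""

    kind: str
    n: int = 3  # series length / random node count
    seed: int = 0
    length: float = 10.0  # mm
    diameter: float = 1.0  # mm
    total_inflow: float = 60.0  # mL/min

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise NetworkError(f"unknown fixture kind {self.kind!r}")


@dataclass
class Fixture:
    network: VascularNetwork
    bc: BoundaryConditions
    #: closed-form expected segment flows (mL/min); empty for random networks
    expected_flow: dict[str, float] = field(default_factory=dict)
    #: closed-form expected pressures (Pa) where simple to state
    expected_pressure: dict[str, float] = field(default_factory=dict)


def _bc(spec: FixtureSpec) -> BoundaryConditions:
    return BoundaryConditions(
        total_inflow=spec.total_inflow, inflow_fractions={"SRC": 1.0}
    )


def _inlet() -> NetworkNode:
    return NetworkNode("SRC", kind="inlet", label="SRC")


def _outlet() -> NetworkNode:
    return NetworkNode("SNK", kind="outlet", label="sink")


def make_fixture(spec: FixtureSpec) -> Fixture:
    """Build the requested fixture network (seeded and reproducible)."""
    bc = _bc(spec)
    Q = spec.total_inflow
    q_si = mlmin_to_m3s(Q)

    def pipe(i, u, v, d=None, L=None):
        return VesselSegment(
            id=f"p{i}", from_node=u, to_node=v,
            length=L if L is not None else spec.length,
            diameter=d if d is not None else spec.diameter,
        )

    if spec.kind == "single":
        seg = pipe(0, "SRC", "SNK")
        net = VascularNetwork([_inlet(), _outlet()], [seg])
        r = seg.resistance(bc.viscosity)
        return Fixture(
            net, bc,
            expected_flow={"p0": Q},
            expected_pressure={"SRC": bc.outlet_pressure + q_si * r,
                               "SNK": bc.outlet_pressure},
        )

    if spec.kind == "series":
        n = max(2, spec.n)
        nodes = [_inlet()] + [NetworkNode(f"j{i}") for i in range(1, n)] + [_outlet()]
        ids = [node.id for node in nodes]
        segs = [pipe(i, ids[i], ids[i + 1]) for i in range(n)]
        net = VascularNetwork(nodes, segs)
        r = segs[0].resistance(bc.viscosity)
        pressures = {
            ids[i]: bc.outlet_pressure + (n - i) * q_si * r for i in range(n)
        }
        pressures["SNK"] = bc.outlet_pressure
        return Fixture(net, bc, {s.id: Q for s in segs}, pressures)

    if spec.kind == "parallel":
        # feeder, then two pipes of equal length with diameters d and 2d:
        # conductance ratio 1:16
        segs = [
            pipe(0, "SRC", "j1"),
            pipe(1, "j1", "SNK", d=spec.diameter),
            pipe(2, "j1", "SNK", d=2 * spec.diameter),
        ]
        net = VascularNetwork([_inlet(), NetworkNode("j1"), _outlet()], segs)
        return Fixture(
            net, bc,
            expected_flow={"p0": Q, "p1": Q / 17.0, "p2": 16.0 * Q / 17.0},
        )

    if spec.kind == "wye":
        segs = [
            pipe(0, "SRC", "j1"),
            pipe(1, "j1", "SNK"),
            pipe(2, "j1", "SNK"),
        ]
        net = VascularNetwork([_inlet(), NetworkNode("j1"), _outlet()], segs)
        return Fixture(net, bc, {"p0": Q, "p1": Q / 2.0, "p2": Q / 2.0})

    if spec.kind == "bridge":
        # balanced Wheatstone bridge: identical arms, so the bridging pipe
        # carries no flow and each side splits the inflow evenly
        nodes = [_inlet(), NetworkNode("a"), NetworkNode("b"), NetworkNode("m"),
                 _outlet()]
        segs = [
            pipe(0, "SRC", "m"),
            pipe(1, "m", "a"),
            pipe(2, "m", "b"),
            pipe(3, "a", "SNK"),
            pipe(4, "b", "SNK"),
            pipe(5, "a", "b", d=0.5 * spec.diameter),  # the bridge
        ]
        net = VascularNetwork(nodes, segs)
        return Fixture(
            net, bc,
            expected_flow={"p0": Q, "p1": Q / 2, "p2": Q / 2,
                           "p3": Q / 2, "p4": Q / 2, "p5": 0.0},
        )

    # random: connected by construction (random spanning tree + chords)
    rng = np.random.default_rng(spec.seed)
    n = max(3, spec.n)
    names = ["SRC"] + [f"j{i}" for i in range(1, n - 1)] + ["SNK"]
    nodes = [_inlet()] + [NetworkNode(nm) for nm in names[1:-1]] + [_outlet()]
    segs = []
    order = list(rng.permutation(n))
    for k in range(1, n):
        u = names[order[k]]
        v = names[order[int(rng.integers(0, k))]]
        segs.append(
            VesselSegment(
                id=f"p{len(segs)}", from_node=u, to_node=v,
                length=float(rng.uniform(5.0, 50.0)),
                diameter=float(rng.uniform(0.5, 4.0)),
            )
        )
    n_chords = int(rng.integers(1, max(2, n // 2)))
    for _ in range(n_chords):
        u, v = rng.choice(n, size=2, replace=False)
        segs.append(
            VesselSegment(
                id=f"p{len(segs)}", from_node=names[int(u)], to_node=names[int(v)],
                length=float(rng.uniform(5.0, 50.0)),
                diameter=float(rng.uniform(0.5, 4.0)),
            )
        )
    net = VascularNetwork(nodes, segs)
    return Fixture(net, _bc(spec))


# ---------------------------------------------------------------------------
# independent dense oracle


def _adjacency(network: VascularNetwork, include_occluded: bool = False):
    adj: dict[str, list[str]] = {nid: [] for nid in network.nodes}
    for seg in network.segments.values():
        if seg.occluded and not include_occluded:
            continue
        adj[seg.from_node].append(seg.to_node)
        adj[seg.to_node].append(seg.from_node)
    return adj


def _bfs_components(network: VascularNetwork) -> list[set[str]]:
    adj = _adjacency(network)
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in network.nodes:
        if start in seen:
            continue
        comp = {start}
        queue = [start]
        seen.add(start)
        while queue:
            u = queue.pop()
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    comp.add(v)
                    queue.append(v)
        comps.append(comp)
    return comps


def brute_force_solve(
    network: VascularNetwork, bc: BoundaryConditions
) -> FlowSolution:
    """Dense nodal-analysis oracle; same contract as the sparse solver.

    Assembles the full conductance matrix with plain numpy and solves it
    with LAPACK; components cut off from every outlet get NaN pressures,
    zero flows, and dropped inflows, exactly as the production solver
    specifies.
    """
    pressures = {nid: math.nan for nid in network.nodes}
    flows = {sid: 0.0 for sid in network.segments}
    residual = 0.0

    for comp in _bfs_components(network):
        outlets = [n for n in comp if network.nodes[n].kind == "outlet"]
        if not outlets:
            continue  # stranded: NaN pressures, zero flows, inflow dropped
        ids = sorted(comp)
        idx = {nid: i for i, nid in enumerate(ids)}
        n = len(ids)
        a = np.zeros((n, n))
        b = np.zeros(n)
        fixed = set(outlets)
        for nid in fixed:
            a[idx[nid], idx[nid]] = 1.0
            b[idx[nid]] = bc.outlet_pressure
        for seg in network.segments.values():
            if seg.occluded or seg.from_node not in idx or seg.to_node not in idx:
                continue
            g = 1.0 / seg.resistance(bc.viscosity)
            iu, iv = idx[seg.from_node], idx[seg.to_node]
            if seg.from_node not in fixed:
                a[iu, iu] += g
                a[iu, iv] -= g
            if seg.to_node not in fixed:
                a[iv, iv] += g
                a[iv, iu] -= g
        for nid in ids:
            node = network.nodes[nid]
            if node.kind == "inlet":
                b[idx[nid]] = mlmin_to_m3s(bc.inflow_for(node))
        p = np.linalg.solve(a, b)
        residual = max(
            residual,
            float(np.abs(a @ p - b).max()) / max(float(np.abs(b).max()), 1e-30),
        )
        for nid in ids:
            pressures[nid] = float(p[idx[nid]])

    for sid, seg in network.segments.items():
        if seg.occluded:
            continue
        pu, pv = pressures[seg.from_node], pressures[seg.to_node]
        if math.isnan(pu) or math.isnan(pv):
            continue
        g = 1.0 / seg.resistance(bc.viscosity)
        flows[sid] = m3s_to_mlmin(g * (pu - pv))
    return FlowSolution(flows, pressures, residual)


def reachability_oracle(
    network: VascularNetwork, occlusions: Iterable[str] = ()
) -> set[str]:
    """Segments that can carry flow, by graph search alone.

    A segment can carry nonzero steady flow only if it lies on some simple
    path from an inflow node to the outer boundary (conservation forces
    dead ends and stranded islands to zero).  Equivalently: join every
    inlet to a virtual source, every outlet to a virtual sink, add a
    virtual source–sink edge, and keep exactly the segments sharing a
    biconnected component with that edge (two edges of a graph lie on a
    common cycle iff they share a biconnected component).  Returns the ids
    of flow-capable segments; everything else is a topology-forced zero.
    """
    import networkx as nx

    occluded_names = set(occlusions)
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    # expand each segment through a midpoint node so parallel pipes keep
    # distinct identities in a simple graph
    for sid, seg in network.segments.items():
        if seg.occluded or seg.name in occluded_names or sid in occluded_names:
            continue
        mid = ("seg", sid)
        g.add_edge(seg.from_node, mid)
        g.add_edge(mid, seg.to_node)
    for nid, node in network.nodes.items():
        if node.kind == "inlet":
            g.add_edge("SOURCE*", nid)
        elif node.kind == "outlet":
            g.add_edge(nid, "SINK*")
    if "SOURCE*" not in g or "SINK*" not in g:
        return set()
    g.add_edge("SOURCE*", "SINK*")
    for comp in nx.biconnected_components(g):
        if "SOURCE*" in comp and "SINK*" in comp:
            return {n[1] for n in comp if isinstance(n, tuple) and n[0] == "seg"}
    return set()
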