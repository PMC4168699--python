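"""Steady laminar flow solver: nodal analysis on the vessel graph.

Unknowns are nodal pressures.  Each junction contributes a mass-balance
(Kirchhoff) equation, each inlet a prescribed-inflow equation of the same
form, and each outlet a fixed-pressure (Dirichlet) equation.  Pipe
conductances are the reciprocal Hagen–Poiseuille resistances; an occluded
pipe has conductance exactly zero, which is flow-equivalent to deleting it.

The assembled system is linear and sparse and is solved directly; the
contract is on the residuals, not on the solution method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .network import (
    BoundaryConditions,
    FlowSolution,
    NetworkError,
    VascularNetwork,
)
from .units import m3s_to_mlmin, mlmin_to_m3s

__all__ = [
    "SolverError",
    "UnconstrainedPressureError",
    "LinearSystem",
    "assemble_system",
    "solve_flow",
    "equivalent_resistance",
    "flow_components",
]


class SolverError(NetworkError):
    """The linear system could not be solved to tolerance."""


class UnconstrainedPressureError(SolverError):
    """No fixed-pressure (outlet) node constrains the system."""


@dataclass
class LinearSystem:
    """Assembled nodal system A·p = b over a fixed node ordering.

    Rows follow ``node_ids``: Laplacian mass-balance rows for junctions and
    inlets (rhs = injected inflow in m³/s), identity rows for outlets
    (rhs = outlet pressure in Pa).
    """

    matrix: sp.csr_matrix
    rhs: np.ndarray
    node_ids: list[str]
    index: dict[str, int]
    conductance: dict[str, float]  # segment id -> S (0 if occluded), m³/(s·Pa)


def _segment_conductances(network: VascularNetwork, viscosity: float) -> dict[str, float]:
    return {
        sid: (0.0 if seg.occluded else 1.0 / seg.resistance(viscosity))
        for sid, seg in network.segments.items()
    }


def flow_components(network: VascularNetwork) -> list[set[str]]:
    """Connected components of the graph with occluded segments removed."""
    import networkx as nx

    g = network.to_multigraph(include_occluded=False)
    return [set(c) for c in nx.connected_components(g)]


def assemble_system(
    network: VascularNetwork,
    bc: BoundaryConditions,
    node_ids: list[str] | None = None,
    effective_inflow: dict[str, float] | None = None,
) -> LinearSystem:
    """Build the sparse nodal system for (a subset of) the network.

    ``node_ids`` restricts assembly to a node subset (used for solving one
    pressure-constrained component at a time); default is every node.
    ``effective_inflow`` overrides prescribed inflows (mL/min) per inlet id.
    """
    if node_ids is None:
        node_ids = list(network.nodes)
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)

    if not any(network.nodes[nid].kind == "outlet" for nid in node_ids):
        raise UnconstrainedPressureError(
            "no outlet node fixes the pressure level; the system is singular"
        )

    cond = _segment_conductances(network, bc.viscosity)
    outlet = {nid for nid in node_ids if network.nodes[nid].kind == "outlet"}

    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []
    b = np.zeros(n)

    for nid in outlet:
        i = index[nid]
        rows.append(i)
        cols.append(i)
        vals.append(1.0)
        b[i] = bc.outlet_pressure

    for sid, seg in network.segments.items():
        g = cond[sid]
        if g == 0.0:
            continue
        u, v = seg.from_node, seg.to_node
        if u not in index or v not in index:
            continue
        iu, iv = index[u], index[v]
        if u not in outlet:
            rows += [iu, iu]
            cols += [iu, iv]
            vals += [g, -g]
        if v not in outlet:
            rows += [iv, iv]
            cols += [iv, iu]
            vals += [g, -g]

    for nid in node_ids:
        node = network.nodes[nid]
        if node.kind == "inlet":
            q = (
                effective_inflow[nid]
                if effective_inflow is not None and nid in effective_inflow
                else bc.inflow_for(node)
            )
            b[index[nid]] = mlmin_to_m3s(q)

    matrix = sp.csr_matrix(
        sp.coo_matrix((vals, (rows, cols)), shape=(n, n))
    )
    return LinearSystem(matrix, b, node_ids, index, cond)


def solve_flow(
    network: VascularNetwork,
    bc: BoundaryConditions,
    tol: float = 1e-9,
) -> FlowSolution:
    """Solve steady flow; returns signed segment flows and nodal pressures.

    Components cut off (by occlusion) from every outlet cannot carry flow:
    their pressures are reported as the NaN sentinel, incident flows as
    exactly zero, and any prescribed inflow at an inlet stranded there is
    dropped (an occluded inflow vessel admits no flow).
    """
    components = flow_components(network)
    pressures: dict[str, float] = {nid: math.nan for nid in network.nodes}
    flows: dict[str, float] = {sid: 0.0 for sid in network.segments}

    active_nodes: list[str] = []
    effective: dict[str, float] = {}
    for comp in components:
        has_outlet = any(network.nodes[nid].kind == "outlet" for nid in comp)
        if has_outlet:
            active_nodes.extend(sorted(comp))
        else:
            for nid in comp:
                if network.nodes[nid].kind == "inlet":
                    effective[nid] = 0.0

    if not active_nodes:
        raise UnconstrainedPressureError(
            "no component of the network contains an outlet node"
        )

    system = assemble_system(network, bc, active_nodes, effective or None)
    try:
        p = spla.spsolve(system.matrix.tocsc(), system.rhs)
    except RuntimeError as exc:  # pragma: no cover - umfpack/superlu failure
        raise SolverError(f"sparse solve failed: {exc}") from exc
    if not np.all(np.isfinite(p)):
        raise SolverError(
            "singular system not attributable to a disconnected component"
        )

    residual = system.matrix @ p - system.rhs
    scale = max(float(np.abs(system.rhs).max()), 1e-30)
    residual_norm = float(np.abs(residual).max()) / scale
    if residual_norm > tol:
        raise SolverError(
            f"residual {residual_norm:.3e} exceeds tolerance {tol:.3e}"
        )

    for nid, i in system.index.items():
        pressures[nid] = float(p[i])

    for sid, seg in network.segments.items():
        g = system.conductance[sid]
        if g == 0.0:
            continue
        pu = pressures.get(seg.from_node, math.nan)
        pv = pressures.get(seg.to_node, math.nan)
        if math.isnan(pu) or math.isnan(pv):
            continue
        flows[sid] = m3s_to_mlmin(g * (pu - pv))

    return FlowSolution(flows, pressures, residual_norm)


def equivalent_resistance(
    network: VascularNetwork,
    viscosity: float,
    node_a: str,
    node_b: str,
) -> float:
    """Two-terminal hydraulic resistance between two nodes, Pa·s/m³.

    Injects a unit flow at ``node_a``, withdraws it at ``node_b`` (held at
    zero pressure) and reads off the pressure at ``node_a``.  A disconnected
    pair returns ``math.inf``.
    """
    if node_a == node_b:
        return 0.0
    comp: set[str] | None = None
    for c in flow_components(network):
        if node_a in c:
            comp = c
            break
    if comp is None or node_b not in comp:
        return math.inf

    cond = _segment_conductances(network, viscosity)
    node_ids = sorted(comp)
    index = {nid: i for i, nid in enumerate(node_ids)}
    n = len(node_ids)
    a = sp.lil_matrix((n, n))
    b = np.zeros(n)
    ib = index[node_b]
    for sid, seg in network.segments.items():
        g = cond[sid]
        if g == 0.0 or seg.from_node not in index or seg.to_node not in index:
            continue
        iu, iv = index[seg.from_node], index[seg.to_node]
        for i, j in ((iu, iv), (iv, iu)):
            if i == ib:
                continue
            a[i, i] += g
            a[i, j] -= g
    a[ib, ib] = 1.0
    b[index[node_a]] = 1.0  # unit flow, m³/s
    p = spla.spsolve(sp.csr_matrix(a).tocsc(), b)
    if not np.all(np.isfinite(p)):  # pragma: no cover - guarded by component check
        return math.inf
    return float(p[index[node_a]])
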