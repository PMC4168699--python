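"""Network file I/O and report writing.

Networks interchange as GraphML (node kinds and every segment attribute
preserved, readable by standard graph tooling); suite reports write as
CSV — one row per named artery, one column per experiment — with a
deterministic metadata header so identical configurations produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import math
from pathlib import Path

import networkx as nx
import pandas as pd

from .network import NetworkError, NetworkNode, VascularNetwork, VesselSegment

__all__ = [
    "write_network_file",
    "read_network_file",
    "write_report",
    "format_percent",
]


def write_network_file(network: VascularNetwork, path: str | Path) -> None:
    """Export a network as GraphML with all segment attributes."""
    g = nx.MultiGraph()
    for node in network.nodes.values():
        g.add_node(node.id, kind=node.kind, label=node.label or "")
    for seg in network.segments.values():
        g.add_edge(
            seg.from_node,
            seg.to_node,
            key=seg.id,
            # orientation is meaningful (signed flows); record it explicitly
            # because GraphML does not promise endpoint order for undirected
            # graphs
            from_node=seg.from_node,
            name=seg.name,
            length=float(seg.length),
            diameter=float(seg.diameter),
            category=seg.category,
            territory=seg.territory,
            branch_order=int(seg.branch_order),
            occluded=bool(seg.occluded),
        )
    nx.write_graphml(g, str(path), named_key_ids=True)


def read_network_file(path: str | Path) -> VascularNetwork:
    """Read a GraphML network file back into a :class:`VascularNetwork`."""
    try:
        g = nx.read_graphml(str(path), force_multigraph=True)
    except Exception as exc:
        raise NetworkError(f"cannot parse network file {path}: {exc}") from exc
    nodes = [
        NetworkNode(nid, kind=data.get("kind", "junction"),
                    label=data.get("label") or None)
        for nid, data in g.nodes(data=True)
    ]
    segments = []
    seen: set[str] = set()
    for u, v, key, data in g.edges(keys=True, data=True):
        if key in seen:
            raise NetworkError(f"duplicate segment id {key!r} in {path}")
        seen.add(key)
        u0 = data.get("from_node", u)
        v0 = v if u0 == u else u
        segments.append(
            VesselSegment(
                id=str(key),
                from_node=u0,
                to_node=v0,
                length=float(data["length"]),
                diameter=float(data["diameter"]),
                name=data.get("name", str(key)),
                category=data.get("category", "cortical"),
                territory=data.get("territory", "none"),
                branch_order=int(data.get("branch_order", 0)),
                occluded=bool(data.get("occluded", False)),
            )
        )
    return VascularNetwork(nodes, segments)


def format_percent(x: float) -> str:
    """1-decimal table formatting; NaN (undefined baseline) prints as NA."""
    return "NA" if isinstance(x, float) and math.isnan(x) else f"{x:.1f}"


def _config_hash(parts: list[str]) -> str:
    return hashlib.sha256("|".join(parts).encode()).hexdigest()[:12]


def write_report(
    table: pd.DataFrame,
    path: str | Path,
    config_description: str = "",
) -> None:
    """Write a percent-flow table as CSV with a metadata header.

    Rows and columns keep their existing (deterministic) order; cells are
    formatted to 1 decimal.  Re-running an identical configuration yields
    a byte-identical file.
    """
    from . import __version__

    header = [
        f"# cerebroflow {__version__}",
        f"# config {config_description}",
        f"# hash {_config_hash([__version__, config_description] + [str(c) for c in table.columns])}",
    ]
    formatted = table.map(format_percent)
    body = formatted.to_csv(index=True, lineterminator="\n")
    Path(path).write_text("\n".join(header) + "\n" + body)
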