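"""Canonical cerebral arterial anatomy.

Builds the model's vascular network — a complete Circle of Willis, the
MCA/ACA/PCA branch trees down to fifth-order cortical tips, multi-stem
cortical origins, terminal drainage pipes — from a declarative geometry
table, and wires leptomeningeal anastomoses (LA) onto it.

Geometry file schema (CSV, one row per segment):

    name, from_node, to_node, length_mm, diameter_mm, category,
    territory, branch_order

Node ids are implicit in the endpoint columns.  ``IN:<label>`` endpoints
are inflow nodes (the label keys the inflow-fraction map), ``OUT`` is the
fixed-pressure outer boundary; everything else is a junction.  The
packaged default geometry carries Rhoton-derived calibers (ICA 4 mm,
M1 3 mm, A1/P1 2.2 mm, Pcom/Acom 1.4 mm, MCA divisions 2 mm, cortical
branches tapering to 0.6 mm fifth-order tips).  Every headline check in
this package is topology-forced and independent of those numbers.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

import pandas as pd
import yaml

from .network import (
    NetworkError,
    NetworkNode,
    VascularNetwork,
    VesselSegment,
)

__all__ = [
    "GeometryError",
    "GeometryTable",
    "LAConfiguration",
    "load_geometry",
    "save_geometry",
    "default_geometry",
    "default_geometry_path",
    "default_wiring",
    "build_canonical_network",
    "attach_leptomeningeal",
    "build_network",
    "multi_stem_arteries",
    "inter_la_arteries",
    "MCA_SUPERIOR",
    "MCA_INFERIOR",
    "MCA_CORTICAL",
]

GEOMETRY_COLUMNS = [
    "name",
    "from_node",
    "to_node",
    "length_mm",
    "diameter_mm",
    "category",
    "territory",
    "branch_order",
]

MCA_SUPERIOR = [
    "orbito-frontal",
    "prefrontal",
    "precentral",
    "central",
    "ant-parietal",
    "post-parietal",
    "angular",
]
MCA_INFERIOR = [
    "temporo-occipital",
    "post-temporal",
    "mid-temporal",
    "ant-temporal",
    "temporopolar",
]
MCA_CORTICAL = MCA_SUPERIOR + MCA_INFERIOR

#: arteries every canonical geometry must contain (both sides where prefixed)
_MANDATORY_SHARED = ["BA", "Acom"]
_MANDATORY_PER_SIDE = (
    ["ICA", "A1", "Pcom", "P1", "M1", "A2", "sup-trunk", "inf-trunk"]
    + MCA_CORTICAL
)


class GeometryError(NetworkError):
    """Geometry table fails schema validation."""


@dataclass
class GeometryTable:
    """Validated table of vessel segments (one row per cylindrical pipe)."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing_cols = [c for c in GEOMETRY_COLUMNS if c not in self.frame.columns]
        if missing_cols:
            raise GeometryError(f"geometry table missing columns {missing_cols}")
        self.frame = self.frame[GEOMETRY_COLUMNS].reset_index(drop=True)
        self.validate()

    def validate(self) -> None:
        f = self.frame
        dup = f["name"][f["name"].duplicated()]
        if not dup.empty:
            raise GeometryError(f"duplicate segment name(s): {sorted(set(dup))}")
        bad = f[(f["length_mm"] <= 0) | (f["diameter_mm"] <= 0)]
        if not bad.empty:
            raise GeometryError(
                f"non-positive dimensions for segment(s): {list(bad['name'])}"
            )
        if (f["branch_order"].astype(int) > 5).any() or (
            f["branch_order"].astype(int) < 0
        ).any():
            raise GeometryError("branch_order must lie in 0–5")
        names = set(f["name"])
        missing = [a for a in _MANDATORY_SHARED if a not in names]
        for side in ("R", "L"):
            missing += [
                f"{side}-{a}" for a in _MANDATORY_PER_SIDE if f"{side}-{a}" not in names
            ]
        if missing:
            raise GeometryError(f"mandatory arteries absent: {missing}")

    @property
    def names(self) -> set[str]:
        return set(self.frame["name"])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeometryTable):
            return NotImplemented
        return self.frame.equals(other.frame)


def load_geometry(path: str | Path) -> GeometryTable:
    """Read and validate a geometry CSV."""
    try:
        frame = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise GeometryError(f"cannot parse geometry file {path}: {exc}") from exc
    return GeometryTable(frame)


def save_geometry(table: GeometryTable, path: str | Path) -> None:
    table.frame.to_csv(path, index=False)


def default_geometry_path() -> Path:
    return Path(resources.files("cerebroflow.data") / "canonical_geometry.csv")


def default_geometry() -> GeometryTable:
    """The packaged canonical geometry."""
    return load_geometry(default_geometry_path())


def _expand_sides(text: str) -> list[str]:
    return [text.format(S=side) for side in ("R", "L")]


def default_wiring() -> dict:
    """Packaged LA wiring, expanded to both sides.

    Returns ``{"inter": [(mca_artery, partner_artery), ...],
    "intra": {territory: [artery, ...]}}``.
    """
    path = resources.files("cerebroflow.data") / "la_wiring.yaml"
    raw = yaml.safe_load(path.read_text())
    inter = [
        (pair[0].format(S=side), pair[1].format(S=side))
        for side in ("R", "L")
        for pair in raw["inter"]
    ]
    intra = {}
    for terr_tpl, chain in raw["intra"].items():
        for side in ("R", "L"):
            intra[terr_tpl.format(S=side)] = [a.format(S=side) for a in chain]
    return {"inter": inter, "intra": intra}


@dataclass(frozen=True)
class LAConfiguration:
    """Leptomeningeal anastomosis calibers.

    A diameter of zero means the corresponding anastomoses are absent (no
    segment is created).  Default pipe length 5 mm.
    """

    intra_diameter: float = 0.0  # mm
    inter_diameter: float = 0.0  # mm
    la_length: float = 5.0  # mm

    def __post_init__(self) -> None:
        if self.intra_diameter < 0 or self.inter_diameter < 0:
            raise GeometryError("LA diameters must be non-negative")
        if self.la_length <= 0:
            raise GeometryError("LA length must be positive")


def build_canonical_network(geometry: GeometryTable | None = None) -> VascularNetwork:
    """Construct the arterial network (no LA) from a geometry table."""
    if geometry is None:
        geometry = default_geometry()
    nodes: dict[str, NetworkNode] = {}
    segments: list[VesselSegment] = []
    for row in geometry.frame.itertuples(index=False):
        for nid in (row.from_node, row.to_node):
            if nid in nodes:
                continue
            if nid.startswith("IN:"):
                nodes[nid] = NetworkNode(nid, kind="inlet", label=nid[3:])
            elif nid == "OUT":
                nodes[nid] = NetworkNode(nid, kind="outlet", label="outer boundary")
            else:
                nodes[nid] = NetworkNode(nid, kind="junction")
        segments.append(
            VesselSegment(
                id=row.name,
                from_node=row.from_node,
                to_node=row.to_node,
                length=float(row.length_mm),
                diameter=float(row.diameter_mm),
                category=row.category,
                territory=row.territory,
                branch_order=int(row.branch_order),
            )
        )
    return VascularNetwork(nodes.values(), segments)


def _tip_node(network: VascularNetwork, artery: str) -> str:
    """Fifth-order tip node of a cortical artery (LA attachment point)."""
    tip = f"{artery}.tip"
    if tip not in network.nodes:
        raise GeometryError(
            f"no fifth-order tip for artery {artery!r}: not in the LA wiring table "
            "or absent from the geometry"
        )
    return tip


def attach_leptomeningeal(
    network: VascularNetwork,
    la: LAConfiguration,
    wiring: dict | None = None,
) -> VascularNetwork:
    """Return a copy of the network with LA pipes added at cortical tips.

    Inter-territorial anastomoses bridge MCA cortical tips to their ACA or
    PCA partner tips; intra-territorial anastomoses chain adjacent cortical
    tips within each territory.  A zero diameter creates nothing.
    """
    if wiring is None:
        wiring = default_wiring()
    net = network.copy()

    def add(seg_id: str, tip_a: str, tip_b: str, diameter: float, category: str,
            territory: str) -> None:
        net.segments[seg_id] = VesselSegment(
            id=seg_id,
            from_node=tip_a,
            to_node=tip_b,
            length=la.la_length,
            diameter=diameter,
            category=category,
            territory=territory,
            branch_order=5,
        )

    if la.inter_diameter > 0:
        for mca_artery, partner in wiring["inter"]:
            add(
                f"LA-inter:{mca_artery}~{partner}",
                _tip_node(net, mca_artery),
                _tip_node(net, partner),
                la.inter_diameter,
                "la_inter",
                "none",
            )
    if la.intra_diameter > 0:
        for territory, chain in wiring["intra"].items():
            for a, b in zip(chain, chain[1:]):
                add(
                    f"LA-intra:{a}~{b}",
                    _tip_node(net, a),
                    _tip_node(net, b),
                    la.intra_diameter,
                    "la_intra",
                    territory,
                )
    net.validate()
    return net


def build_network(
    geometry: GeometryTable | None = None,
    la: LAConfiguration | None = None,
    wiring: dict | None = None,
) -> VascularNetwork:
    """Canonical network with an optional LA configuration applied."""
    net = build_canonical_network(geometry)
    if la is not None and (la.inter_diameter > 0 or la.intra_diameter > 0):
        net = attach_leptomeningeal(net, la, wiring)
    return net


def multi_stem_arteries(geometry: GeometryTable) -> set[str]:
    """Cortical arteries arising from more than one stem of their trunk."""
    names = geometry.frame["name"]
    feeders = names[names.str.contains(r"\.stem-", regex=True)]
    counts: dict[str, int] = {}
    for feeder in feeders:
        artery = feeder.split(".stem-")[0]
        counts[artery] = counts.get(artery, 0) + 1
    return {a for a, n in counts.items() if n >= 2}


def inter_la_arteries(wiring: dict | None = None) -> set[str]:
    """MCA cortical arteries possessing an inter-territorial anastomosis."""
    if wiring is None:
        wiring = default_wiring()
    return {pair[0] for pair in wiring["inter"]}
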