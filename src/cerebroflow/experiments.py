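"""Occlusion experiments, percent-of-baseline reporting, and LA sweeps.

Eleven experiments move a simulated occlusion from the carotid (at the
base of the Circle of Willis) progressively distally through the right
MCA tree.  Each is run under a leptomeningeal-anastomosis (LA)
configuration; flows are reported per named artery as a signed percent of
that artery's baseline (unoccluded) flow, and classified against the
ischemic-adequacy threshold: flow above 30% of baseline is taken as
adequate to prevent ischemia.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .anatomy import GeometryTable, LAConfiguration, build_network, default_wiring
from .network import BoundaryConditions, FlowSolution, NetworkError, VascularNetwork
from .solver import solve_flow

__all__ = [
    "OcclusionScenario",
    "FlowReport",
    "SuiteResult",
    "SweepResult",
    "EXPERIMENT_ORDER",
    "REPORT_ARTERIES",
    "CONDITIONS",
    "ISCHEMIC_THRESHOLD",
    "DEFAULT_SWEEP_GRID",
    "load_scenarios",
    "apply_occlusion",
    "percent_flow",
    "classify_ischemia",
    "run_experiment_suite",
    "la_diameter_sweep",
]

EXPERIMENT_ORDER = ["1", "2", "3", "4a", "4b", "4c", "4d", "4e", "4f", "4g", "4h"]

#: table row order: right CoW outputs, the 12 right MCA cortical arteries,
#: then the mirrored left CoW outputs
REPORT_ARTERIES = (
    ["R-P1", "R-Pcom", "R-A2", "R-M1"]
    + [
        "R-orbito-frontal",
        "R-prefrontal",
        "R-precentral",
        "R-central",
        "R-ant-parietal",
        "R-post-parietal",
        "R-angular",
        "R-temporo-occipital",
        "R-post-temporal",
        "R-mid-temporal",
        "R-ant-temporal",
        "R-temporopolar",
    ]
    + ["L-P1", "L-Pcom", "L-A2", "L-M1"]
)

#: flow above this percent of baseline is adequate to prevent ischemia
ISCHEMIC_THRESHOLD = 30.0

#: the three studied LA configurations: none; intra-dominant (2.0/0.25 mm);
#: inter-dominant (0.25/1.0 mm)
CONDITIONS: dict[str, LAConfiguration] = {
    "1": LAConfiguration(intra_diameter=0.0, inter_diameter=0.0),
    "2a": LAConfiguration(intra_diameter=2.0, inter_diameter=0.25),
    "2b": LAConfiguration(intra_diameter=0.25, inter_diameter=1.0),
}

#: default caliber grid for LA sweeps (mm)
DEFAULT_SWEEP_GRID = [0.0625, 0.125, 0.25, 0.5, 1.0, 2.0]

#: flows smaller than this (mL/min) are treated as structural zeros when
#: forming percentages; well above direct-solver roundoff, far below any
#: physiological flow
_FLOW_ATOL = 1e-7


@dataclass(frozen=True)
class OcclusionScenario:
    """One experiment: a set of simultaneously occluded segments."""

    id: str
    occluded_segments: tuple[str, ...]


class ScenarioError(NetworkError):
    """Scenario references an unknown experiment or segment."""


def load_scenarios(path: str | Path | None = None) -> dict[str, OcclusionScenario]:
    """Read the experiment definitions (packaged file by default)."""
    if path is None:
        path = resources.files("cerebroflow.data") / "scenarios.yaml"
        raw = yaml.safe_load(path.read_text())
    else:
        raw = yaml.safe_load(Path(path).read_text())
    out: dict[str, OcclusionScenario] = {}
    for sid, segs in raw["experiments"].items():
        out[str(sid)] = OcclusionScenario(str(sid), tuple(segs))
    return out


def apply_occlusion(
    network: VascularNetwork, scenario: OcclusionScenario
) -> VascularNetwork:
    """Copy of the network with the scenario's segments occluded."""
    by_name = {s.name for s in network.segments.values()}
    unknown = [n for n in scenario.occluded_segments if n not in by_name]
    if unknown:
        raise ScenarioError(
            f"scenario {scenario.id!r} names unknown segment(s) {unknown}"
        )
    return network.with_occlusions(scenario.occluded_segments)


def _round1(x: float) -> float:
    """Round to 1 decimal, halves away from zero (table convention)."""
    return math.copysign(math.floor(abs(x) * 10.0 + 0.5) / 10.0, x)


@dataclass
class FlowReport:
    """Percent-of-baseline flows for one scenario and LA configuration.

    ``percent`` maps segment name → signed percent rounded to 1 decimal
    (NaN where the baseline itself carried no flow); ``ischemia`` maps
    segment name → {"adequate", "critical", "undefined"} once classified.
    """

    scenario_id: str
    la_config: LAConfiguration
    percent: dict[str, float]
    ischemia: dict[str, str] = field(default_factory=dict)
    threshold: float | None = None


def percent_flow(
    solution: FlowSolution,
    baseline: FlowSolution,
    network: VascularNetwork,
    scenario_id: str = "",
    la_config: LAConfiguration | None = None,
) -> FlowReport:
    """Signed percent of baseline flow per segment, 1-decimal.

    Positive means flow along the baseline direction; negative means
    reversal.  A segment with zero baseline flow reports 0.0 if it is
    still flowless, otherwise the NaN sentinel (percent undefined).
    """
    if set(solution.segment_flow) != set(baseline.segment_flow):
        raise NetworkError("solutions cover different segment sets")
    pct: dict[str, float] = {}
    for sid, seg in network.segments.items():
        q = solution.segment_flow[sid]
        qb = baseline.segment_flow[sid]
        if abs(qb) <= _FLOW_ATOL:
            pct[seg.name] = 0.0 if abs(q) <= _FLOW_ATOL else math.nan
        elif abs(q) <= _FLOW_ATOL:
            pct[seg.name] = 0.0  # structural zero; avoid a noise-signed -0.0
        else:
            # sign is relative to the baseline flow direction
            pct[seg.name] = _round1(100.0 * q / qb)
    return FlowReport(
        scenario_id=scenario_id,
        la_config=la_config if la_config is not None else LAConfiguration(),
        percent=pct,
    )


def classify_ischemia(
    report: FlowReport, threshold: float = ISCHEMIC_THRESHOLD
) -> FlowReport:
    """Label each segment adequate (|%| > threshold) or critical.

    The magnitude rule: reversed flow still perfuses the territory, so a
    large negative percent is adequate.  The inequality is strict, so a
    segment at exactly the threshold is critical.
    """
    classes: dict[str, str] = {}
    for name, p in report.percent.items():
        if math.isnan(p):
            classes[name] = "undefined"
        else:
            classes[name] = "adequate" if abs(p) > threshold else "critical"
    report.ischemia = classes
    report.threshold = threshold
    return report


@dataclass
class SuiteResult:
    """All experiments for one LA configuration.

    ``table`` has one row per named artery and one column per
    experiment, holding 1-decimal percent of baseline.
    """

    la_config: LAConfiguration
    table: pd.DataFrame
    reports: dict[str, FlowReport]
    baseline: FlowSolution
    solutions: dict[str, FlowSolution]
    network: VascularNetwork


def run_experiment_suite(
    geometry: GeometryTable | None = None,
    la_config: LAConfiguration | None = None,
    scenarios: Mapping[str, OcclusionScenario] | None = None,
    bc: BoundaryConditions | None = None,
    arteries: Sequence[str] | None = None,
    threshold: float = ISCHEMIC_THRESHOLD,
) -> SuiteResult:
    """One baseline solve plus one occluded solve per experiment.

    The baseline is the identical network (same LA configuration) with no
    occlusion, so every percentage is normalised within-configuration.
    """
    if la_config is None:
        la_config = LAConfiguration()
    if scenarios is None:
        scenarios = load_scenarios()
    if bc is None:
        bc = BoundaryConditions()
    if arteries is None:
        arteries = REPORT_ARTERIES

    network = build_network(geometry, la_config)
    baseline = solve_flow(network, bc)
    reports: dict[str, FlowReport] = {}
    solutions: dict[str, FlowSolution] = {}
    columns: dict[str, list[float]] = {}
    for sid in sorted(scenarios, key=_experiment_key):
        scenario = scenarios[sid]
        occluded = apply_occlusion(network, scenario)
        sol = solve_flow(occluded, bc)
        report = classify_ischemia(
            percent_flow(sol, baseline, network, sid, la_config), threshold
        )
        reports[sid] = report
        solutions[sid] = sol
        columns[sid] = [report.percent[a] for a in arteries]

    table = pd.DataFrame(columns, index=list(arteries))
    table.index.name = "artery"
    return SuiteResult(la_config, table, reports, baseline, solutions, network)


def _experiment_key(sid: str):
    order = {e: i for i, e in enumerate(EXPERIMENT_ORDER)}
    return (order.get(sid, len(order)), sid)


@dataclass
class SweepResult:
    """LA-diameter sweep for one scenario.

    ``percent``: tidy frame (inter_diameter, intra_diameter, artery,
    percent).  ``delivered``: per grid point, total flow reaching the
    right-MCA drain terminals, mL/min and percent of baseline.
    ``min_adequate_inter``: per (intra_diameter, artery), the smallest
    swept inter diameter at which the artery clears the adequacy
    threshold (inf sentinel if never).
    """

    scenario_id: str
    percent: pd.DataFrame
    delivered: pd.DataFrame
    min_adequate_inter: pd.DataFrame


def _territory_delivery(
    solution: FlowSolution, network: VascularNetwork, territory: str
) -> float:
    total = 0.0
    for sid, seg in network.segments.items():
        if seg.category != "drain" or seg.territory != territory:
            continue
        q = solution.segment_flow[sid]
        total += q if network.nodes[seg.to_node].kind == "outlet" else -q
    return total


def la_diameter_sweep(
    geometry: GeometryTable | None = None,
    scenario: OcclusionScenario | str = "4a",
    inter_range: Sequence[float] | None = None,
    intra_range: Sequence[float] | None = None,
    bc: BoundaryConditions | None = None,
    arteries: Sequence[str] | None = None,
    threshold: float = ISCHEMIC_THRESHOLD,
) -> SweepResult:
    """Sweep LA calibers for one occlusion scenario.

    Each grid point gets its own baseline (same LA configuration,
    unoccluded), matching the within-configuration normalisation of the
    experiment suites.
    """
    if isinstance(scenario, str):
        scenario = load_scenarios()[scenario]
    if inter_range is None:
        inter_range = DEFAULT_SWEEP_GRID
    if intra_range is None:
        intra_range = [0.25]
    if not len(inter_range) or not len(intra_range):
        raise ScenarioError("sweep ranges must be non-empty")
    if min(inter_range) < 0 or min(intra_range) < 0:
        raise ScenarioError("sweep diameters must be non-negative")
    if bc is None:
        bc = BoundaryConditions()
    if arteries is None:
        arteries = REPORT_ARTERIES

    rows = []
    delivered_rows = []
    for intra in intra_range:
        for inter in inter_range:
            la = LAConfiguration(intra_diameter=intra, inter_diameter=inter)
            network = build_network(geometry, la)
            baseline = solve_flow(network, bc)
            sol = solve_flow(apply_occlusion(network, scenario), bc)
            report = percent_flow(sol, baseline, network, scenario.id, la)
            for artery in arteries:
                rows.append(
                    {
                        "inter_diameter": inter,
                        "intra_diameter": intra,
                        "artery": artery,
                        "percent": report.percent[artery],
                    }
                )
            base_del = _territory_delivery(baseline, network, "MCA-R")
            occ_del = _territory_delivery(sol, network, "MCA-R")
            delivered_rows.append(
                {
                    "inter_diameter": inter,
                    "intra_diameter": intra,
                    "mca_r_delivered_mlmin": occ_del,
                    "mca_r_delivered_pct": 100.0 * occ_del / base_del,
                }
            )

    percent = pd.DataFrame(rows)
    delivered = pd.DataFrame(delivered_rows)

    crossing_rows = []
    for intra in intra_range:
        sub = percent[percent["intra_diameter"] == intra]
        for artery in arteries:
            ser = sub[sub["artery"] == artery].sort_values("inter_diameter")
            ok = ser[ser["percent"].abs() > threshold]
            crossing_rows.append(
                {
                    "intra_diameter": intra,
                    "artery": artery,
                    "min_adequate_inter": (
                        float(ok["inter_diameter"].iloc[0]) if not ok.empty else math.inf
                    ),
                }
            )
    min_adequate = pd.DataFrame(crossing_rows)
    return SweepResult(scenario.id, percent, delivered, min_adequate)
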