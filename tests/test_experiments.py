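"""Occlusion experiments: percent flow, classification, suites, sweeps."""

import math

import numpy as np
import pandas as pd
import pytest

import cerebroflow as cf
from cerebroflow.experiments import (
    EXPERIMENT_ORDER,
    REPORT_ARTERIES,
    ScenarioError,
    _round1,
)
from cerebroflow.fixtures import reachability_oracle

MCA_R_CORTICAL = [a for a in REPORT_ARTERIES if a.startswith("R-")][4:]


class TestPercentFlow:
    def test_identical_solutions_give_100(self, canonical, bc, baseline_solution):
        report = cf.percent_flow(baseline_solution, baseline_solution, canonical)
        assert all(p == 100.0 for name, p in report.percent.items()
                   if not math.isnan(p) and name != "Acom")
        # Acom carries no baseline flow (symmetry): flowless vs flowless -> 0.0
        assert report.percent["Acom"] == 0.0

    def test_occluded_segment_reports_exactly_zero(self, canonical, bc, baseline_solution):
        occluded = canonical.with_occlusions(["R-M1"])
        sol = cf.solve_flow(occluded, bc)
        report = cf.percent_flow(sol, baseline_solution, canonical)
        assert report.percent["R-M1"] == 0.0

    def test_reversal_reports_negative_percent(self, canonical, bc, baseline_solution):
        # at baseline the right Pcom feeds the carotid side from the basilar;
        # after M1 occlusion the carotid has surplus and pushes back the other
        # way, so the percent is signed negative
        sol = cf.solve_flow(canonical.with_occlusions(["R-M1"]), bc)
        report = cf.percent_flow(sol, baseline_solution, canonical)
        base = baseline_solution.flow_by_name(canonical)["R-Pcom"]
        now = sol.flow_by_name(canonical)["R-Pcom"]
        assert (now / base) < 0 and report.percent["R-Pcom"] < 0

    def test_mismatched_segment_sets_rejected(self, canonical, bc, baseline_solution):
        from cerebroflow.network import NetworkError

        other = cf.build_network(la=cf.CONDITIONS["2b"])
        sol = cf.solve_flow(other, bc)
        with pytest.raises(NetworkError, match="different segment sets"):
            cf.percent_flow(sol, baseline_solution, other)

    def test_table_rounding_convention(self):
        assert _round1(100.25) == 100.3
        assert _round1(-100.25) == -100.3
        assert _round1(54.44) == 54.4


class TestIschemiaClassification:
    @pytest.mark.parametrize(
        "pct,expected",
        [(40.1, "adequate"), (22.9, "critical"), (30.0, "critical"),
         (30.1, "adequate"), (-50.0, "adequate"), (-10.0, "critical")],
    )
    def test_threshold_rule(self, pct, expected):
        report = cf.FlowReport("x", cf.LAConfiguration(), {"seg": pct})
        assert cf.classify_ischemia(report).ischemia["seg"] == expected

    def test_nan_percent_is_undefined(self):
        report = cf.FlowReport("x", cf.LAConfiguration(), {"seg": math.nan})
        assert cf.classify_ischemia(report).ischemia["seg"] == "undefined"


class TestSuite:
    def test_table_shape_and_order(self, suites):
        table = suites["1"].table
        assert list(table.columns) == EXPERIMENT_ORDER
        assert list(table.index) == REPORT_ARTERIES
        assert len(table.columns) == 11

    def test_no_occlusion_gives_100_everywhere(self):
        scenario = cf.OcclusionScenario("none", ())
        for cond in ("1", "2b"):
            suite = cf.run_experiment_suite(
                la_config=cf.CONDITIONS[cond], scenarios={"none": scenario}
            )
            assert (suite.table["none"] == 100.0).all()

    def test_unknown_segment_in_scenario(self, canonical):
        with pytest.raises(ScenarioError, match="unknown"):
            cf.apply_occlusion(canonical, cf.OcclusionScenario("bad", ("R-XYZ",)))

    def test_condition1_zero_patterns_follow_occlusion_site(self, suites):
        """The region of no flow shrinks as the occlusion moves distally."""
        table = suites["1"].table
        zeros = {
            exp: {a for a in MCA_R_CORTICAL if table.loc[a, exp] == 0.0}
            for exp in EXPERIMENT_ORDER
        }
        assert zeros["4a"] == set(MCA_R_CORTICAL)
        assert zeros["4b"] == {f"R-{a}" for a in
                               ("orbito-frontal", "prefrontal", "precentral", "central",
                                "ant-parietal", "post-parietal", "angular")}
        assert zeros["4c"] == {f"R-{a}" for a in
                               ("precentral", "central", "ant-parietal",
                                "post-parietal", "angular")}
        assert zeros["4d"] == {f"R-{a}" for a in
                               ("precentral", "central", "ant-parietal", "post-parietal")}
        assert zeros["4e"] == {"R-ant-parietal", "R-post-parietal"}
        assert zeros["4f"] == {f"R-{a}" for a in
                               ("temporo-occipital", "post-temporal", "mid-temporal",
                                "ant-temporal", "temporopolar")}
        assert zeros["4g"] == {"R-temporo-occipital", "R-post-temporal", "R-mid-temporal"}
        assert zeros["4h"] == {"R-temporo-occipital", "R-post-temporal"}

    def test_ica_occlusion_spares_distal_territories(self, suites):
        """Carotid occlusion alone: collateral flow via the circle keeps the
        right MCA and ACA perfused."""
        col = suites["1"].table["1"]
        assert col["R-M1"] > 0
        assert all(col[a] > 0 for a in MCA_R_CORTICAL)

    def test_zero_flow_report_iff_unreachable(self, suites):
        """Reported zeros coincide with graph reachability for every named
        artery, across all scenario x condition combinations."""
        scenarios = cf.load_scenarios()
        for cond, suite in suites.items():
            net = suite.network
            by_name = {s.name: sid for sid, s in net.segments.items()}
            for sid_exp, scenario in scenarios.items():
                live = reachability_oracle(net, scenario.occluded_segments)
                sol = suite.solutions[sid_exp]
                for artery in REPORT_ARTERIES:
                    seg_id = by_name[artery]
                    q = sol.segment_flow[seg_id]
                    if seg_id in live and artery not in scenario.occluded_segments:
                        assert abs(q) > 1e-6, (cond, sid_exp, artery)
                    else:
                        assert abs(q) <= 1e-6, (cond, sid_exp, artery)

    def test_unreachable_segments_carry_no_flow(self, suites):
        """One-sided check over *all* segments (live ones may still carry a
        structural zero, e.g. perfectly balanced anastomoses)."""
        scenarios = cf.load_scenarios()
        for cond, suite in suites.items():
            net = suite.network
            for sid_exp, scenario in scenarios.items():
                live = reachability_oracle(net, scenario.occluded_segments)
                sol = suite.solutions[sid_exp]
                for seg_id, q in sol.segment_flow.items():
                    if seg_id not in live:
                        assert abs(q) <= 1e-6, (cond, sid_exp, seg_id)


class TestScaleInvariance:
    def test_classification_invariant_to_inflow_and_uniform_caliber(self):
        """Percent normalisation cancels the total inflow and any uniform
        diameter rescaling, so the ischemia classification is unchanged."""
        scenarios = {"4e": cf.load_scenarios()["4e"]}
        base = cf.run_experiment_suite(
            la_config=cf.CONDITIONS["2b"], scenarios=scenarios
        )

        geo = cf.default_geometry()
        frame = geo.frame.copy()
        frame["diameter_mm"] *= 1.3
        scaled_geo = cf.GeometryTable(frame)
        scaled_la = cf.LAConfiguration(
            intra_diameter=0.25 * 1.3, inter_diameter=1.0 * 1.3
        )
        scaled_bc = cf.BoundaryConditions(total_inflow=1500.0)
        scaled = cf.run_experiment_suite(
            geometry=scaled_geo, la_config=scaled_la,
            scenarios=scenarios, bc=scaled_bc,
        )
        assert np.allclose(
            base.table["4e"].to_numpy(), scaled.table["4e"].to_numpy(), atol=0.11
        )
        assert {a: base.reports["4e"].ischemia[a] for a in base.table.index} == {
            a: scaled.reports["4e"].ischemia[a] for a in base.table.index
        }


class TestSweep:
    def test_single_point_sweep_matches_suite(self):
        la = cf.CONDITIONS["2b"]
        sweep = cf.la_diameter_sweep(
            scenario="4a",
            inter_range=[la.inter_diameter],
            intra_range=[la.intra_diameter],
        )
        suite = cf.run_experiment_suite(la_config=la)
        col = suite.table["4a"]
        for row in sweep.percent.itertuples(index=False):
            assert row.percent == col[row.artery] or (
                math.isnan(row.percent) and math.isnan(col[row.artery])
            )

    def test_empty_range_rejected(self):
        with pytest.raises(ScenarioError):
            cf.la_diameter_sweep(scenario="4a", inter_range=[], intra_range=[0.25])

    def test_la_less_arteries_stay_at_zero_across_sweep(self):
        """Arteries lacking any anastomosis and any shared stem stay pinned
        at exactly 0.0 under occlusion of their feeding branch, no matter how
        wide the inter-territorial LA are grown."""
        sweep = cf.la_diameter_sweep(
            scenario="4g", inter_range=[0.0625, 0.5, 2.0], intra_range=[0.0]
        )
        sub = sweep.percent[
            sweep.percent["artery"].isin(
                ["R-temporo-occipital", "R-post-temporal", "R-mid-temporal"]
            )
        ]
        assert (sub["percent"] == 0.0).all()
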