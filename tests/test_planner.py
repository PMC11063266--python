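"""Shortest-path planning, classification, ranking and reports."""

import json

import numpy as np
import pytest

from cliviplan.anatomy import LandmarkSet
from cliviplan.planner import (
    PlanningError,
    classify_approach,
    compute_all_weights,
    dag_shortest_route,
    optimal_plan,
    plan_report,
    rank_plans,
    report_csv,
    validate_report,
    write_report,
)
from cliviplan.topology import enumerate_plans, load_topology
from cliviplan.weighting import WeightBreakdown

from test_topology import minimal_config


def fake_weights(topo, values):
    return {
        pid: WeightBreakdown(
            path_id=pid,
            tissue_volumes={c: 0.0 for c in range(8)},
            injury_risk=max(v, 0.0),
            surgical_freedom=max(-v, 0.0),
            weight=float(v),
        )
        for pid, v in values.items()
    }


def brute_force_min(topo, weights):
    """Independent oracle: exhaustive minimum over all enumerated plans."""
    best = None
    for plan in enumerate_plans(topo):
        total = sum(weights[pid].weight for pid in plan.paths)
        key = (total, plan.id)
        if best is None or key < best[0]:
            best = (key, plan)
    return best[0][0], best[1]


class TestDagShortestPath:
    def test_single_plan_topology(self):
        topo = load_topology(minimal_config())
        w = fake_weights(topo, {"pqrs": -3.5})
        res = optimal_plan(topo, w)
        assert res.plan_id == "only"
        assert res.total_weight == -3.5

    def test_matches_exhaustive_minimum_with_negative_weights(self, topo):
        rng = np.random.default_rng(99)
        for _ in range(1000):
            vals = {pid: float(v) for pid, v in
                    zip(sorted(topo.paths), rng.normal(0.0, 1000.0, size=12))}
            w = fake_weights(topo, vals)
            total, route = dag_shortest_route(topo, w)
            oracle_total, oracle_plan = brute_force_min(topo, w)
            assert total == pytest.approx(oracle_total, abs=1e-9)
            assert optimal_plan(topo, w).plan_id == oracle_plan.id

    def test_exact_tie_resolves_to_smaller_plan_id(self):
        cfg = minimal_config()
        # second parallel corridor: same entry/exit chain length, equal weight
        cfg["landmarks"].append("t")
        cfg["windows"] += [
            {"id": "pqs", "landmarks": ["p", "q", "s"]},
            {"id": "qst", "landmarks": ["q", "s", "t"]},
            {"id": "qrt", "landmarks": ["q", "r", "t"]},
        ]
        cfg["paths"] = [
            {"id": "pqrs", "landmarks": ["p", "q", "r", "s"],
             "entry_window": "pqr", "exit_window": "qrs"},
            {"id": "pqrt", "landmarks": ["p", "q", "r", "t"],
             "entry_window": "pqr", "exit_window": "qrt"},
            {"id": "qrst", "landmarks": ["q", "r", "s", "t"],
             "entry_window": "qrt", "exit_window": "qrs"},
        ]
        cfg["plans"] = [
            {"id": "zz-direct", "paths": ["pqrs"]},
            {"id": "aa-detour", "paths": ["pqrt", "qrst"]},
        ]
        topo = load_topology(cfg)
        w = fake_weights(topo, {"pqrs": 5.0, "pqrt": 2.0, "qrst": 3.0})
        assert optimal_plan(topo, w).plan_id == "aa-detour"  # exact tie at 5.0

    def test_disconnected_raises(self):
        cfg = minimal_config()
        cfg["landmarks"].append("t")
        cfg["windows"].append({"id": "rst", "landmarks": ["r", "s", "t"]})
        cfg["end_window"] = "rst"
        cfg["plans"] = []
        topo = load_topology(cfg)
        with pytest.raises(PlanningError, match="unreachable"):
            dag_shortest_route(topo, fake_weights(topo, {"pqrs": 1.0}))


class TestComputeAllWeights:
    def test_one_breakdown_per_path(self, coarse_phantom, topo, coeffs):
        lm, lms = coarse_phantom
        w = compute_all_weights(lm, lms, topo, coeffs)
        assert sorted(w) == sorted(topo.paths)
        assert len(w) == 12

    def test_pure_function_of_inputs(self, coarse_phantom, topo, coeffs):
        lm, lms = coarse_phantom
        w1 = compute_all_weights(lm, lms, topo, coeffs)
        w2 = compute_all_weights(lm, lms, topo, coeffs)
        assert w1 == w2

    def test_deleted_landmark_names_every_affected_path(self, coarse_phantom, topo, coeffs):
        lm, lms = coarse_phantom
        partial = LandmarkSet({k: lms[k] for k in lms if k != "f"})
        with pytest.raises(Exception) as err:
            compute_all_weights(lm, partial, topo, coeffs)
        for pid in ("abfi", "bfij", "cfij", "fijk"):
            assert pid in str(err.value)


class TestClassification:
    @staticmethod
    def _tiny_topo_landmarks(z_shift):
        cfg = minimal_config()
        topo = load_topology(cfg)
        lms = LandmarkSet({
            "p": (0.0, 0.0, 10.0 + z_shift),
            "q": (10.0, 0.0, 12.0 + z_shift),
            "r": (0.0, 10.0, 11.0 + z_shift),
            "s": (5.0, 5.0, 13.0 + z_shift),
        })
        return topo, lms

    def test_all_below_is_ita(self):
        topo, lms = self._tiny_topo_landmarks(0.0)
        high = LandmarkSet({**{k: lms[k] for k in lms if k != "q"}, "q": (10.0, 0.0, 40.0)})
        # tubercle (q) far above every centroid
        assert classify_approach(topo.plans["only"], topo, high) == "ITA"

    def test_all_above_is_sta(self):
        topo, lms = self._tiny_topo_landmarks(0.0)
        low = LandmarkSet({**{k: lms[k] for k in lms if k != "q"}, "q": (10.0, 0.0, -30.0)})
        assert classify_approach(topo.plans["only"], topo, low) == "STA"

    def test_straddling_is_tta(self):
        topo, lms = self._tiny_topo_landmarks(0.0)
        assert classify_approach(topo.plans["only"], topo, lms) == "TTA"

    def test_declared_labels_agree_with_geometry_on_default_phantom(
        self, default_phantom, topo
    ):
        _, lms = default_phantom
        for label in ("ITA", "TTA", "STA"):
            plan = topo.labelled_plan(label)
            assert classify_approach(plan, topo, lms) == label


class TestRankingAndReports:
    def test_seven_results_ordered(self, coarse_phantom, topo, coeffs):
        lm, lms = coarse_phantom
        w = compute_all_weights(lm, lms, topo, coeffs)
        results = rank_plans(topo, w, lms)
        assert len(results) == 7
        totals = [r.total_weight for r in results]
        assert totals == sorted(totals)
        assert [r.rank for r in results] == list(range(1, 8))
        assert results[0].plan_id == optimal_plan(topo, w, lms).plan_id

    def test_rank1_equals_optimal_for_random_weights(self, topo):
        rng = np.random.default_rng(5)
        for _ in range(100):
            vals = {pid: float(v) for pid, v in
                    zip(sorted(topo.paths), rng.normal(0, 500, size=12))}
            w = fake_weights(topo, vals)
            assert rank_plans(topo, w)[0].plan_id == optimal_plan(topo, w).plan_id

    def test_report_schema_and_csv(self, tmp_path, coarse_phantom, topo, coeffs):
        lm, lms = coarse_phantom
        w = compute_all_weights(lm, lms, topo, coeffs)
        results = rank_plans(topo, w, lms)
        report = plan_report(results, coeffs, {"seed": 0})
        validate_report(report)
        csv_path = tmp_path / "summary.csv"
        report_csv(results, csv_path)
        rows = csv_path.read_text().strip().splitlines()
        assert len(rows) == 1 + len(results)
        assert rows[0].startswith("plan_id,label,total_weight")

    def test_report_is_byte_reproducible(self, tmp_path, coarse_phantom, topo, coeffs):
        lm, lms = coarse_phantom
        paths = []
        for name in ("a.json", "b.json"):
            w = compute_all_weights(lm, lms, topo, coeffs)
            report = plan_report(rank_plans(topo, w, lms), coeffs, {"seed": 0})
            p = tmp_path / name
            write_report(report, p)
            paths.append(p)
        assert paths[0].read_bytes() == paths[1].read_bytes()
        json.loads(paths[0].read_text())  # well-formed JSON
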