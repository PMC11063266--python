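"""Plan scoring, shortest-path search, approach classification and reports.

The optimal plan minimises the sum of path weights over all face-adjacent
chains from the start to the end window.  Because weights are freedom-
corrected they are routinely *negative*, so classic Dijkstra does not apply;
the search is single-source relaxation over the window-node / path-edge
graph in topological order, which is exact on a DAG for arbitrary edge
signs.  The exhaustive plan enumeration is kept alongside as an oracle and
as the ranking backend.  Exact ties are broken lexicographically.

Approach classification is geometric: a plan whose corridor centroids all
lie below the jugular-tubercle landmark (minus a small band delta) is
infra-tubercle (ITA); all above is supra-tubercle (STA); anything straddling
the tubercle is trans-tubercle (TTA).  The superior axis is +z of the RAS
frame.
"""

from __future__ import annotations

import csv
import hashlib
import json
from dataclasses import dataclass
from importlib import resources
from pathlib import Path as FsPath
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import networkx as nx

from .anatomy import AnatomyError, LabelMap, LandmarkSet
from .geometry import Tetrahedron
from .topology import CorridorTopology, Plan, enumerate_plans
from .weighting import RiskCoefficients, WeightBreakdown, path_weight

__all__ = [
    "PlanResult",
    "PlanningError",
    "compute_all_weights",
    "dag_shortest_route",
    "optimal_plan",
    "classify_approach",
    "rank_plans",
    "plan_report",
    "write_report",
    "report_csv",
    "validate_report",
    "DEFAULT_TUBERCLE_BAND_MM",
]

#: Half-width (mm) of the trans-tubercle band around the tubercle landmark.
DEFAULT_TUBERCLE_BAND_MM = 2.0


class PlanningError(ValueError):
    """Planning failed (disconnected topology, missing weights, ...)."""


@dataclass(frozen=True)
class PlanResult:
    """A scored plan: total weight, per-path breakdowns, label and rank."""

    plan_id: str
    approach_label: str
    total_weight: float
    breakdowns: Tuple[WeightBreakdown, ...]
    rank: Optional[int] = None

    @property
    def injury_risk_sum(self) -> float:
        return sum(b.injury_risk for b in self.breakdowns)

    @property
    def surgical_freedom_sum(self) -> float:
        return sum(b.surgical_freedom for b in self.breakdowns)


def compute_all_weights(
    labelmap: LabelMap,
    landmarks: LandmarkSet,
    topology: CorridorTopology,
    coeffs: RiskCoefficients,
) -> Dict[str, WeightBreakdown]:
    """One :class:`WeightBreakdown` per topology path; pure in its inputs."""
    missing: Dict[str, list] = {}
    for p in topology.paths.values():
        absent = sorted(set(p.landmarks) - set(landmarks))
        if absent:
            missing[p.id] = absent
    if missing:
        details = "; ".join(f"path {pid!r} needs {ids}" for pid, ids in sorted(missing.items()))
        raise AnatomyError(f"unresolvable landmarks: {details}")
    return {
        pid: path_weight(labelmap, landmarks, topology.paths[pid], coeffs)
        for pid in sorted(topology.paths)
    }


def _plan_total(plan: Plan, weights: Mapping[str, WeightBreakdown]) -> float:
    # sequential accumulation in path order: bit-identical to the DAG
    # relaxation along the same route
    total = 0.0
    for pid in plan.paths:
        total += weights[pid].weight
    return total


def dag_shortest_route(
    topology: CorridorTopology, weights: Mapping[str, WeightBreakdown]
) -> Tuple[float, Tuple[str, ...]]:
    """Minimum-total-weight route by topological-order relaxation.

    Exact with negative edge weights; ties between routes resolve to the
    lexicographically smallest path-id sequence.  Raises
    :class:`PlanningError` if the end window is unreachable.
    """
    missing = sorted(set(topology.paths) - set(weights))
    if missing:
        raise PlanningError(f"weights missing for paths: {missing}")
    g = topology.graph
    best: Dict[str, Tuple[float, Tuple[str, ...]]] = {topology.start_window: (0.0, ())}
    for node in nx.topological_sort(g):
        if node not in best:
            continue
        dist, route = best[node]
        for _, nxt, pid in sorted(g.out_edges(node, data="path"), key=lambda e: e[2]):
            cand = (dist + weights[pid].weight, route + (pid,))
            cur = best.get(nxt)
            if cur is None or cand[0] < cur[0] or (cand[0] == cur[0] and cand[1] < cur[1]):
                best[nxt] = cand
    if topology.end_window not in best:
        raise PlanningError(
            f"no plan: end window {topology.end_window!r} is unreachable from "
            f"{topology.start_window!r}"
        )
    return best[topology.end_window]


def classify_approach(
    plan: Plan,
    topology: CorridorTopology,
    landmarks: LandmarkSet,
    delta_mm: float = DEFAULT_TUBERCLE_BAND_MM,
) -> str:
    """ITA / TTA / STA by corridor height relative to the jugular tubercle.

    Compares the superior (z) coordinate of every path-tetrahedron centroid
    with the tubercle landmark: all below ``tubercle - delta`` is ITA, all
    above ``tubercle + delta`` is STA, anything else (straddling or within
    the band) is TTA.
    """
    landmarks.require([topology.tubercle_landmark])
    z_tub = float(landmarks[topology.tubercle_landmark][2])
    zs = []
    for pid in plan.paths:
        path = topology.paths[pid]
        landmarks.require(path.landmarks)
        tetra = Tetrahedron.from_landmarks(landmarks, path.landmarks)
        zs.append(float(tetra.centroid[2]))
    if all(z < z_tub - delta_mm for z in zs):
        return "ITA"
    if all(z > z_tub + delta_mm for z in zs):
        return "STA"
    return "TTA"


def _as_result(
    plan: Plan,
    weights: Mapping[str, WeightBreakdown],
    topology: CorridorTopology,
    landmarks: Optional[LandmarkSet],
    rank: Optional[int] = None,
) -> PlanResult:
    if landmarks is not None:
        label = classify_approach(plan, topology, landmarks)
    else:
        label = plan.approach_label or "other"
    return PlanResult(
        plan_id=plan.id,
        approach_label=label,
        total_weight=_plan_total(plan, weights),
        breakdowns=tuple(weights[pid] for pid in plan.paths),
        rank=rank,
    )


def optimal_plan(
    topology: CorridorTopology,
    weights: Mapping[str, WeightBreakdown],
    landmarks: Optional[LandmarkSet] = None,
) -> PlanResult:
    """The minimum-total-weight plan, found by DAG shortest-path relaxation.

    The relaxation determines the minimum; when several declared plans tie
    exactly at that minimum the lexicographically smallest plan id wins.
    """
    total, route = dag_shortest_route(topology, weights)
    plan = topology.plan_by_sequence(route)
    tied = sorted(
        (p for p in topology.plans.values() if _plan_total(p, weights) == total),
        key=lambda p: p.id,
    )
    if tied:
        plan = tied[0]
    elif plan is None:
        plan = Plan(id="route:" + "-".join(route), paths=route)
    return _as_result(plan, weights, topology, landmarks, rank=1)


def rank_plans(
    topology: CorridorTopology,
    weights: Mapping[str, WeightBreakdown],
    landmarks: Optional[LandmarkSet] = None,
) -> List[PlanResult]:
    """All enumerated plans ranked ascending by total weight (ties by id)."""
    plans = enumerate_plans(topology)
    if not plans:
        raise PlanningError("topology has no start-to-end plan")
    scored = sorted(plans, key=lambda p: (_plan_total(p, weights), p.id))
    return [
        _as_result(plan, weights, topology, landmarks, rank=i + 1)
        for i, plan in enumerate(scored)
    ]


# ---------------------------------------------------------------------------
# Reports


def _round6(x: float) -> float:
    return float(f"{float(x):.6f}")


def plan_report(
    results: Sequence[PlanResult],
    coeffs: RiskCoefficients,
    provenance: Mapping[str, object],
) -> Dict[str, object]:
    """Machine-readable planning report (JSON-able, stable layout)."""
    from . import __version__

    winner = min(results, key=lambda r: (r.total_weight, r.plan_id))
    return {
        "tool": {"name": "cliviplan", "version": __version__},
        "provenance": {str(k): v for k, v in sorted(provenance.items())},
        "coefficients": {k: _round6(v) for k, v in coeffs.asdict().items()},
        "plans": [
            {
                "plan_id": r.plan_id,
                "approach_label": r.approach_label,
                "rank": r.rank,
                "total_weight": _round6(r.total_weight),
                "injury_risk_sum": _round6(r.injury_risk_sum),
                "surgical_freedom_sum": _round6(r.surgical_freedom_sum),
                "paths": [
                    {
                        "path_id": b.path_id,
                        "tissue_volumes_mm3": {k: _round6(v) for k, v in b.volumes_by_name().items()},
                        "injury_risk": _round6(b.injury_risk),
                        "surgical_freedom": _round6(b.surgical_freedom),
                        "weight": _round6(b.weight),
                    }
                    for b in r.breakdowns
                ],
            }
            for r in sorted(results, key=lambda r: (r.rank if r.rank is not None else 0, r.plan_id))
        ],
        "winner": {
            "plan_id": winner.plan_id,
            "approach_label": winner.approach_label,
            "total_weight": _round6(winner.total_weight),
        },
    }


def write_report(report: Mapping[str, object], path: str | FsPath) -> None:
    """Canonical JSON serialisation: sorted keys, fixed float format."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def report_csv(results: Sequence[PlanResult], path: str | FsPath) -> None:
    """One-row-per-plan CSV summary."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plan_id", "label", "total_weight", "injury_risk_sum", "freedom_sum", "rank"])
        for r in sorted(results, key=lambda r: (r.rank if r.rank is not None else 0, r.plan_id)):
            writer.writerow(
                [r.plan_id, r.approach_label, f"{r.total_weight:.6f}",
                 f"{r.injury_risk_sum:.6f}", f"{r.surgical_freedom_sum:.6f}", r.rank]
            )


def file_checksum(path: str | FsPath) -> str:
    return hashlib.sha256(FsPath(path).read_bytes()).hexdigest()


def _load_report_schema() -> Mapping[str, object]:
    ref = resources.files("cliviplan").joinpath("data/report_schema.json")
    return json.loads(ref.read_text())


def validate_report(report: Mapping[str, object]) -> None:
    """Check a report against the bundled schema (subset of JSON Schema:
    object/array/number/string/integer types, required properties, items)."""

    def check(instance, schema, where):
        typ = schema.get("type")
        if typ == "object":
            if not isinstance(instance, Mapping):
                raise ValueError(f"{where}: expected object")
            for key in schema.get("required", []):
                if key not in instance:
                    raise ValueError(f"{where}: missing required property {key!r}")
            for key, sub in schema.get("properties", {}).items():
                if key in instance:
                    check(instance[key], sub, f"{where}.{key}")
        elif typ == "array":
            if not isinstance(instance, (list, tuple)):
                raise ValueError(f"{where}: expected array")
            items = schema.get("items")
            if items:
                for i, element in enumerate(instance):
                    check(element, items, f"{where}[{i}]")
        elif typ == "number":
            if not isinstance(instance, (int, float)) or isinstance(instance, bool):
                raise ValueError(f"{where}: expected number, got {type(instance).__name__}")
        elif typ == "integer":
            if not isinstance(instance, int) or isinstance(instance, bool):
                raise ValueError(f"{where}: expected integer")
        elif typ == "string":
            if not isinstance(instance, str):
                raise ValueError(f"{where}: expected string")

    check(report, _load_report_schema(), "report")
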