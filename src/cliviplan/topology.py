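"""The corridor graph: windows, paths and plans.

A *window* is a triangular aperture spanned by three landmarks.  A *path* is
a tetrahedral corridor segment spanned by four landmarks, entered through one
of its triangular faces and exited through another.  A *plan* is a chain of
paths, face-adjacent (the exit window of each path is the entry window of the
next), leading from the topology's start window (the posterolateral surface
aperture) to its end window (the clival target).

The topology is declarative data, not code: it is loaded from a YAML/JSON
config (``schema: 1``) and fully validated.  The bundled default models the
retro-condylar corridor system of the inferior clivus with 11 landmarks
(``a``..``k``), 17 windows, 12 paths and 7 plans, three of which are
pre-labelled as the named approaches ITA, TTA and STA (running under,
through and above the jugular tubercle respectively).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path as FsPath
from typing import Dict, List, Mapping, Optional, Sequence

import networkx as nx
import yaml

__all__ = [
    "Window",
    "Path",
    "Plan",
    "CorridorTopology",
    "TopologyError",
    "load_topology",
    "default_topology",
    "enumerate_plans",
    "APPROACH_LABELS",
]

APPROACH_LABELS = ("ITA", "TTA", "STA")


class TopologyError(ValueError):
    """Malformed or inconsistent corridor topology."""


@dataclass(frozen=True)
class Window:
    """A triangular aperture: three distinct landmark ids (stored sorted)."""

    id: str
    landmarks: tuple[str, str, str]

    def __post_init__(self) -> None:
        if len(set(self.landmarks)) != 3:
            raise TopologyError(f"window {self.id!r}: landmarks must be 3 distinct ids, "
                                f"got {self.landmarks}")
        object.__setattr__(self, "landmarks", tuple(sorted(self.landmarks)))


@dataclass(frozen=True)
class Path:
    """A tetrahedral corridor segment with designated entry and exit faces."""

    id: str
    landmarks: tuple[str, str, str, str]
    entry_window: str
    exit_window: str

    def __post_init__(self) -> None:
        if len(set(self.landmarks)) != 4:
            raise TopologyError(f"path {self.id!r}: landmarks must be 4 distinct ids, "
                                f"got {self.landmarks}")
        object.__setattr__(self, "landmarks", tuple(sorted(self.landmarks)))
        if self.entry_window == self.exit_window:
            raise TopologyError(f"path {self.id!r}: entry and exit windows must differ")


@dataclass(frozen=True)
class Plan:
    """An ordered, face-adjacent sequence of path ids from start to end."""

    id: str
    paths: tuple[str, ...]
    approach_label: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.paths:
            raise TopologyError(f"plan {self.id!r}: empty path sequence")
        if self.approach_label is not None and self.approach_label not in APPROACH_LABELS:
            raise TopologyError(
                f"plan {self.id!r}: approach_label must be one of {APPROACH_LABELS}"
            )


@dataclass
class CorridorTopology:
    """Validated corridor graph with declared plans."""

    name: str
    landmark_ids: tuple[str, ...]
    windows: Dict[str, Window]
    paths: Dict[str, Path]
    plans: Dict[str, Plan]
    start_window: str
    end_window: str
    tubercle_landmark: str
    schema: int = 1
    _graph: nx.DiGraph = field(repr=False, default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.validate()

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        lm = set(self.landmark_ids)
        if len(self.landmark_ids) != len(lm):
            raise TopologyError("duplicate landmark ids in topology")
        for w in self.windows.values():
            missing = set(w.landmarks) - lm
            if missing:
                raise TopologyError(f"window {w.id!r} references unknown landmarks {sorted(missing)}")
        for p in self.paths.values():
            missing = set(p.landmarks) - lm
            if missing:
                raise TopologyError(f"path {p.id!r} references unknown landmarks {sorted(missing)}")
            for attr in ("entry_window", "exit_window"):
                wid = getattr(p, attr)
                if wid not in self.windows:
                    raise TopologyError(f"path {p.id!r}: {attr} {wid!r} is not a declared window")
                face = set(self.windows[wid].landmarks)
                if not face <= set(p.landmarks):
                    raise TopologyError(
                        f"path {p.id!r}: {attr} {wid!r} {sorted(face)} is not a face of "
                        f"its tetrahedron {list(p.landmarks)}"
                    )
        for wid in (self.start_window, self.end_window):
            if wid not in self.windows:
                raise TopologyError(f"start/end window {wid!r} is not a declared window")
        if self.tubercle_landmark not in lm:
            raise TopologyError(f"tubercle landmark {self.tubercle_landmark!r} is not a landmark")

        for plan in self.plans.values():
            prev_exit = self.start_window
            for pos, pid in enumerate(plan.paths):
                if pid not in self.paths:
                    raise TopologyError(f"plan {plan.id!r}: unknown path {pid!r} at position {pos}")
                p = self.paths[pid]
                if p.entry_window != prev_exit:
                    raise TopologyError(
                        f"plan {plan.id!r}: paths are not face-adjacent at position {pos} "
                        f"(path {pid!r} enters through {p.entry_window!r}, expected "
                        f"{prev_exit!r})"
                    )
                prev_exit = p.exit_window
            if prev_exit != self.end_window:
                raise TopologyError(
                    f"plan {plan.id!r}: last path exits through {prev_exit!r}, "
                    f"not the end window {self.end_window!r}"
                )

        g = nx.DiGraph()
        g.add_nodes_from(self.windows)
        for p in self.paths.values():
            if g.has_edge(p.entry_window, p.exit_window):
                raise TopologyError(
                    f"duplicate corridor between windows {p.entry_window!r} and "
                    f"{p.exit_window!r} (paths {g.edges[p.entry_window, p.exit_window]['path']!r} "
                    f"and {p.id!r})"
                )
            g.add_edge(p.entry_window, p.exit_window, path=p.id)
        if not nx.is_directed_acyclic_graph(g):
            cycle = nx.find_cycle(g)
            raise TopologyError(f"corridor graph contains a cycle: {cycle}")
        self._graph = g

    # -- accessors ----------------------------------------------------------

    @property
    def graph(self) -> nx.DiGraph:
        """Window-node / path-edge directed acyclic graph."""
        return self._graph

    def counts(self) -> tuple[int, int, int, int]:
        """(landmarks, windows, paths, plans)."""
        return (len(self.landmark_ids), len(self.windows), len(self.paths), len(self.plans))

    def plan_by_sequence(self, path_ids: Sequence[str]) -> Optional[Plan]:
        seq = tuple(path_ids)
        for plan in self.plans.values():
            if plan.paths == seq:
                return plan
        return None

    def labelled_plan(self, label: str) -> Optional[Plan]:
        for plan in self.plans.values():
            if plan.approach_label == label:
                return plan
        return None


def enumerate_plans(topology: CorridorTopology) -> List[Plan]:
    """All face-adjacent path sequences from the start to the end window.

    Deterministic: sequences are emitted in lexicographic order of their
    path-id tuples.  Sequences that match a declared plan inherit its id and
    label; any extra route gets a synthesised ``route:`` id.  Returns an
    empty list if start and end are disconnected.
    """
    g = topology.graph
    out: List[Plan] = []

    def dfs(window: str, acc: List[str]) -> None:
        if window == topology.end_window:
            declared = topology.plan_by_sequence(acc)
            if declared is not None:
                out.append(declared)
            else:
                out.append(Plan(id="route:" + "-".join(acc), paths=tuple(acc)))
            return
        edges = sorted(g.out_edges(window, data="path"), key=lambda e: e[2])
        for _, nxt, pid in edges:
            dfs(nxt, acc + [pid])

    dfs(topology.start_window, [])
    return out


# ---------------------------------------------------------------------------
# Loading


def _require(mapping: Mapping, key: str, where: str):
    if key not in mapping:
        raise TopologyError(f"{where}: missing required key {key!r}")
    return mapping[key]


def load_topology(config: str | FsPath | Mapping) -> CorridorTopology:
    """Load and validate a corridor topology from YAML/JSON (path or mapping)."""
    if isinstance(config, (str, FsPath)):
        text = FsPath(config).read_text()
        raw = yaml.safe_load(text) if str(config).endswith((".yaml", ".yml")) else json.loads(text)
    else:
        raw = dict(config)
    if not isinstance(raw, Mapping):
        raise TopologyError("topology config must be a mapping")
    schema = raw.get("schema")
    if schema != 1:
        raise TopologyError(f"unsupported topology schema {schema!r} (expected 1)")

    landmark_ids = tuple(str(x) for x in _require(raw, "landmarks", "topology"))
    windows: Dict[str, Window] = {}
    for entry in _require(raw, "windows", "topology"):
        w = Window(id=str(entry["id"]), landmarks=tuple(entry["landmarks"]))
        if w.id in windows:
            raise TopologyError(f"duplicate window id {w.id!r}")
        windows[w.id] = w
    paths: Dict[str, Path] = {}
    for entry in _require(raw, "paths", "topology"):
        p = Path(
            id=str(entry["id"]),
            landmarks=tuple(entry["landmarks"]),
            entry_window=str(entry["entry_window"]),
            exit_window=str(entry["exit_window"]),
        )
        if p.id in paths:
            raise TopologyError(f"duplicate path id {p.id!r}")
        paths[p.id] = p
    plans: Dict[str, Plan] = {}
    for entry in _require(raw, "plans", "topology"):
        plan = Plan(
            id=str(entry["id"]),
            paths=tuple(str(x) for x in entry["paths"]),
            approach_label=entry.get("approach"),
        )
        if plan.id in plans:
            raise TopologyError(f"duplicate plan id {plan.id!r}")
        plans[plan.id] = plan

    return CorridorTopology(
        name=str(raw.get("name", "unnamed")),
        landmark_ids=landmark_ids,
        windows=windows,
        paths=paths,
        plans=plans,
        start_window=str(_require(raw, "start_window", "topology")),
        end_window=str(_require(raw, "end_window", "topology")),
        tubercle_landmark=str(_require(raw, "tubercle_landmark", "topology")),
        schema=1,
    )


def default_topology() -> CorridorTopology:
    """The bundled default inferior-clivus topology (11 landmarks, 17 windows,
    12 paths, 7 plans; ITA/TTA/STA pre-labelled)."""
    ref = resources.files("cliviplan").joinpath("data/default_topology.yaml")
    with resources.as_file(ref) as path:
        return load_topology(path)
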