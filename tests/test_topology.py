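"""Corridor topology: validation, enumeration, default combinatorics."""

import random

import pytest

from cliviplan.topology import (
    CorridorTopology,
    Path,
    Plan,
    TopologyError,
    Window,
    default_topology,
    enumerate_plans,
    load_topology,
)


def minimal_config():
    """Smallest legal topology: one tetrahedron, two of its faces, one plan."""
    return {
        "schema": 1,
        "name": "minimal",
        "landmarks": ["p", "q", "r", "s"],
        "tubercle_landmark": "q",
        "start_window": "pqr",
        "end_window": "qrs",
        "windows": [
            {"id": "pqr", "landmarks": ["p", "q", "r"]},
            {"id": "qrs", "landmarks": ["q", "r", "s"]},
        ],
        "paths": [
            {"id": "pqrs", "landmarks": ["p", "q", "r", "s"],
             "entry_window": "pqr", "exit_window": "qrs"},
        ],
        "plans": [{"id": "only", "paths": ["pqrs"]}],
    }


class TestValidation:
    def test_minimal_topology_valid(self):
        topo = load_topology(minimal_config())
        assert topo.counts() == (4, 2, 1, 1)
        assert [p.id for p in enumerate_plans(topo)] == ["only"]

    def test_window_needs_distinct_landmarks(self):
        with pytest.raises(TopologyError, match="distinct"):
            Window(id="bad", landmarks=("a", "a", "b"))

    def test_path_entry_must_be_face(self):
        cfg = minimal_config()
        cfg["windows"].append({"id": "xyz", "landmarks": ["p", "q", "s"]})
        cfg["paths"][0]["entry_window"] = "xyz"
        cfg["plans"] = []
        load_topology(cfg)  # pqs IS a face of pqrs: fine
        cfg["windows"][-1]["landmarks"] = ["p", "q", "z"]
        cfg["landmarks"].append("z")
        with pytest.raises(TopologyError, match="face"):
            load_topology(cfg)

    def test_dangling_reference_located(self):
        cfg = minimal_config()
        cfg["plans"][0]["paths"] = ["pqrs", "nope"]
        with pytest.raises(TopologyError, match="nope"):
            load_topology(cfg)

    def test_non_adjacent_plan_names_plan_and_position(self):
        cfg = minimal_config()
        cfg["windows"].append({"id": "prs", "landmarks": ["p", "r", "s"]})
        cfg["landmarks"].append("t")
        cfg["windows"].append({"id": "rst", "landmarks": ["r", "s", "t"]})
        cfg["paths"].append({"id": "prst", "landmarks": ["p", "r", "s", "t"],
                             "entry_window": "prs", "exit_window": "rst"})
        cfg["end_window"] = "rst"
        cfg["plans"] = [{"id": "broken", "paths": ["pqrs", "prst"]}]
        with pytest.raises(TopologyError, match=r"broken.*position 1"):
            load_topology(cfg)

    def test_cycle_rejected(self):
        cfg = minimal_config()
        cfg["paths"].append({"id": "srqp", "landmarks": ["p", "q", "r", "s"],
                             "entry_window": "qrs", "exit_window": "pqr"})
        with pytest.raises(TopologyError):
            load_topology(cfg)

    def test_unsupported_schema(self):
        cfg = minimal_config()
        cfg["schema"] = 2
        with pytest.raises(TopologyError, match="schema"):
            load_topology(cfg)


class TestDefaultTopology:
    def test_printed_combinatorics(self, topo):
        assert topo.counts() == (11, 17, 12, 7)

    def test_enumeration_equals_declared_plans(self, topo):
        enumerated = enumerate_plans(topo)
        assert len(enumerated) == 7
        assert {p.id for p in enumerated} == set(topo.plans)
        assert {tuple(p.paths) for p in enumerated} == {
            tuple(p.paths) for p in topo.plans.values()
        }

    def test_enumeration_order_deterministic(self, topo):
        seqs = [tuple(p.paths) for p in enumerate_plans(topo)]
        assert seqs == sorted(seqs)

    def test_named_approaches_distinct(self, topo):
        labelled = {lab: topo.labelled_plan(lab) for lab in ("ITA", "TTA", "STA")}
        assert all(p is not None for p in labelled.values())
        seqs = [tuple(p.paths) for p in labelled.values()]
        assert len(set(seqs)) == 3

    def test_path_ids_are_sorted_landmark_concatenations(self, topo):
        for p in topo.paths.values():
            assert p.id == "".join(sorted(p.landmarks))
        assert "cfij" in topo.paths  # the trans-tubercle corridor segment

    def test_tta_traverses_cfij(self, topo):
        assert "cfij" in topo.labelled_plan("TTA").paths


class TestEnumerationOracle:
    @staticmethod
    def _random_layered_topology(rng):
        """Random layered DAG of face-adjacent tetrahedra via letter swaps."""
        letters = "abcdefghijklmn"
        layers = rng.randint(2, 5)
        windows = {}
        paths = {}
        frontier = [("a", "b", "c")]
        windows["abc"] = ("a", "b", "c")
        pool = list(letters[3:])
        for _ in range(layers):
            new_frontier = []
            for tri in frontier:
                for _ in range(rng.randint(1, 2)):
                    drop = rng.choice(tri)
                    add = rng.choice(pool)
                    if add in tri:
                        continue
                    new = tuple(sorted(set(tri) - {drop} | {add}))
                    quad = tuple(sorted(set(tri) | {add}))
                    pid = "".join(quad)
                    wid_in, wid_out = "".join(tri), "".join(new)
                    if pid in paths or wid_in == wid_out:
                        continue
                    windows.setdefault(wid_in, tri)
                    windows.setdefault(wid_out, new)
                    paths[pid] = (quad, wid_in, wid_out)
                    new_frontier.append(new)
            if not new_frontier:
                break
            frontier = new_frontier
        end = "".join(frontier[0])
        return windows, paths, end

    def test_count_matches_dfs_oracle(self):
        rng = random.Random(20240901)
        tested = 0
        for _ in range(60):
            windows, paths, end = self._random_layered_topology(rng)
            cfg = {
                "schema": 1,
                "name": "random",
                "landmarks": sorted({c for w in windows.values() for c in w}),
                "tubercle_landmark": "a",
                "start_window": "abc",
                "end_window": end,
                "windows": [{"id": wid, "landmarks": list(tri)} for wid, tri in windows.items()],
                "paths": [
                    {"id": pid, "landmarks": list(quad), "entry_window": wi, "exit_window": wo}
                    for pid, (quad, wi, wo) in paths.items()
                ],
                "plans": [],
            }
            try:
                topo = load_topology(cfg)
            except TopologyError:
                continue  # rejected configs (cycles etc.) are out of scope here
            tested += 1
            # independent brute-force DFS over (entry -> exit) edges
            adj = {}
            for pid, (_, wi, wo) in paths.items():
                adj.setdefault(wi, []).append((pid, wo))

            def count(w):
                if w == end:
                    return 1
                return sum(count(nxt) for _, nxt in adj.get(w, []))

            assert len(enumerate_plans(topo)) == count("abc")
        assert tested >= 30
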