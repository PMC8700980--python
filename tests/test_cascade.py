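import numpy as np
import pandas as pd
import pytest

from regcascade.cascade import (Cascade, build_all_cascades, cascade_size,
                                compare_cascades, grow_cascade)
from regcascade.config import PipelineConfig


def act_rows(edges, cell_type="NPC", condition="normal"):
    """edges: (regulator, target, edge_type, r, active)"""
    return pd.DataFrame(
        [{"regulator": a, "target": b, "edge_type": t, "cell_type": cell_type,
          "condition": condition, "r": r, "active": active}
         for a, b, t, r, active in edges])


def net_rows(pairs, edge_type="tf_gene"):
    return pd.DataFrame([{"regulator": a, "target": b, "edge_type": edge_type,
                          "evidence": "x"} for a, b in pairs])


def brute_force_layers(root, edges, gate, max_layers):
    """Independent layered-reachability oracle with the same
    first-encounter rule: lexicographic parents, one parent per node."""
    layer = {root: 0}
    frontier = [root]
    kept = []
    for depth in range(1, max_layers + 1):
        new = []
        for parent in sorted(frontier):
            for a, b in sorted(edges):
                if a != parent or b in layer:
                    continue
                if gate.get((a, b), False):
                    layer[b] = depth
                    kept.append((a, b))
                    new.append(b)
        frontier = new
    return layer, set(kept)


class TestGrowCascade:
    def test_no_passing_edges_gives_root_only(self):
        net = net_rows([("TF1", "A")])
        acts = act_rows([("TF1", "A", "tf_gene", 0.5, False)])
        c = grow_cascade("TF1", net, acts, PipelineConfig(), "NPC", "normal")
        assert c.node_set() == {"TF1"}
        assert cascade_size(c) == 1

    def test_gate_is_strict_greater_than(self):
        net = net_rows([("TF1", "A"), ("TF1", "B")])
        acts = act_rows([("TF1", "A", "tf_gene", 0.8, True),
                         ("TF1", "B", "tf_gene", 0.8000001, True)])
        c = grow_cascade("TF1", net, acts, PipelineConfig(), "NPC", "normal")
        assert c.node_set() == {"TF1", "B"}  # r = 0.8 exactly does not pass

    def test_negative_correlation_passes_by_magnitude(self):
        net = net_rows([("TF1", "A")])
        acts = act_rows([("TF1", "A", "tf_gene", -0.95, True)])
        c = grow_cascade("TF1", net, acts, PipelineConfig(), "NPC", "normal")
        assert c.node_set() == {"TF1", "A"}

    def test_depth_capped_at_max_layers(self):
        chain = [(f"N{i}", f"N{i+1}") for i in range(6)]
        net = net_rows(chain)
        acts = act_rows([(a, b, "tf_gene", 0.99, True) for a, b in chain])
        c = grow_cascade("N0", net, acts, PipelineConfig(max_layers=3),
                         "NPC", "normal")
        assert c.node_set() == {"N0", "N1", "N2", "N3"}
        assert c.depth == 3

    def test_lncrna_gene_edges_exempt_from_gate(self):
        net = pd.concat([net_rows([("TF1", "LNC")], "tf_lncrna"),
                         net_rows([("LNC", "G")], "lncrna_gene")],
                        ignore_index=True)
        acts = act_rows([("TF1", "LNC", "tf_lncrna", 0.9, True),
                         ("LNC", "G", "lncrna_gene", 0.1, True)])
        c = grow_cascade("TF1", net, acts, PipelineConfig(), "NPC", "normal")
        assert c.node_set() == {"TF1", "LNC", "G"}

    def test_first_encounter_wins_lexicographic(self):
        # B and C both regulate D; B sorts first, so D hangs under B
        net = net_rows([("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")])
        acts = act_rows([(a, b, "tf_gene", 0.95, True)
                         for a, b in [("A", "B"), ("A", "C"), ("B", "D"),
                                      ("C", "D")]])
        c = grow_cascade("A", net, acts, PipelineConfig(), "NPC", "normal")
        assert ("B", "D") in c.edge_set()
        assert ("C", "D") not in c.edge_set()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_reachability_oracle(self, seed):
        """Random networks <= 30 nodes: growth equals an independently
        coded layered reachability with the same gate."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        nodes = [f"n{i:02d}" for i in range(n)]
        pairs = set()
        for _ in range(int(rng.integers(n, 3 * n))):
            a, b = rng.choice(n, size=2, replace=False)
            pairs.add((nodes[a], nodes[b]))
        pairs = sorted(pairs)
        rs = rng.uniform(-1, 1, size=len(pairs))
        cfg = PipelineConfig()
        acts = act_rows([(a, b, "tf_gene", r, abs(r) >= 0.75)
                         for (a, b), r in zip(pairs, rs)])
        gate = {(a, b): abs(r) > cfg.cascade_corr_cutoff
                for (a, b), r in zip(pairs, rs)}
        net = net_rows(pairs)
        root = nodes[0]
        c = grow_cascade(root, net, acts, cfg, "NPC", "normal")
        layers, kept = brute_force_layers(root, pairs, gate, cfg.max_layers)
        assert dict(c.nodes) == layers
        assert c.edge_set() == kept

    def test_deleting_edges_never_grows_cascades(self):
        rng = np.random.default_rng(99)
        pairs = sorted({(f"n{a}", f"n{b}") for a, b in
                        rng.integers(0, 12, size=(30, 2)) if a != b})
        rs = rng.uniform(-1, 1, size=len(pairs))
        cfg = PipelineConfig()
        acts = act_rows([(a, b, "tf_gene", r, True)
                         for (a, b), r in zip(pairs, rs)])
        net = net_rows(pairs)
        full = grow_cascade("n0", net, acts, cfg, "NPC", "normal")
        smaller = grow_cascade("n0", net.iloc[: len(net) // 2], acts, cfg,
                               "NPC", "normal")
        assert smaller.size <= full.size

    def test_raising_cutoff_never_grows_cascades(self):
        rng = np.random.default_rng(98)
        pairs = sorted({(f"n{a}", f"n{b}") for a, b in
                        rng.integers(0, 12, size=(30, 2)) if a != b})
        rs = rng.uniform(-1, 1, size=len(pairs))
        acts = act_rows([(a, b, "tf_gene", r, True)
                         for (a, b), r in zip(pairs, rs)])
        net = net_rows(pairs)
        low = grow_cascade("n0", net, acts, PipelineConfig(cascade_corr_cutoff=0.5),
                           "NPC", "normal")
        high = grow_cascade("n0", net, acts, PipelineConfig(cascade_corr_cutoff=0.9),
                            "NPC", "normal")
        assert high.size <= low.size
        assert high.node_set() <= low.node_set()


class TestBuildAndCompare:
    def test_childless_roots_not_counted(self):
        net = net_rows([("TF1", "A"), ("TF2", "B")])
        acts = act_rows([("TF1", "A", "tf_gene", 0.9, True),
                         ("TF2", "B", "tf_gene", 0.1, False)])
        out = build_all_cascades(["TF1", "TF2"], net, acts, PipelineConfig(),
                                 [("NPC", "normal")])
        assert [c.root for c in out[("NPC", "normal")]] == ["TF1"]

    def test_identical_lists_all_stable(self):
        c = Cascade("TF1", "NPC", "normal",
                    nodes=[("TF1", 0), ("A", 1)],
                    edges=[("TF1", "A", "tf_gene", 0.9)])
        report = compare_cascades([c], [c])
        assert list(report["status"]) == ["stable"]
        assert not report["lost_over_threshold"].any()

    def test_lost_cascade_over_threshold_flagged(self):
        nodes = [("TF1", 0)] + [(f"g{i}", 1) for i in range(24)]
        edges = [("TF1", f"g{i}", "tf_gene", 0.9) for i in range(24)]
        big = Cascade("TF1", "NPC", "normal", nodes=nodes, edges=edges)
        report = compare_cascades([big], [], size_threshold=20)
        row = report.iloc[0]
        assert row["status"] == "lost"
        assert bool(row["lost_over_threshold"]) is True
        assert row["n_lost_edges"] == 24

    def test_shrunk_cascade_reports_lost_edges(self):
        full = Cascade("TF1", "NPC", "normal",
                       nodes=[("TF1", 0), ("A", 1), ("B", 1)],
                       edges=[("TF1", "A", "tf_gene", 0.9),
                              ("TF1", "B", "tf_gene", 0.85)])
        small = Cascade("TF1", "NPC", "ASD",
                        nodes=[("TF1", 0), ("A", 1)],
                        edges=[("TF1", "A", "tf_gene", 0.9)])
        report = compare_cascades([full], [small])
        row = report.iloc[0]
        assert row["status"] == "shrunk"
        assert row["lost_edges"] == "TF1->B"


class TestSyntheticRecovery:
    def test_planted_cascades_recovered_exactly_and_differentially(
            self, study, config, pipeline_dir):
        """Normal-group cascades equal the planted node sets; broken-edge
        subtrees are absent in the disease group; counts and total sizes
        shrink in disease."""
        from regcascade import io as rio
        broken = set(map(tuple, study.truth.broken_edges))
        for ct in ("iPSC", "NPC", "neuron"):
            normal = {c.root: c for c in rio.read_cascade_json(
                pipeline_dir / f"cascades_{ct}_normal.json", config)}
            asd = {c.root: c for c in rio.read_cascade_json(
                pipeline_dir / f"cascades_{ct}_ASD.json", config)}
            for tf in study.topology.tfs:
                expected_n = study.topology.planted_cascade_nodes(tf)
                assert normal[tf].node_set() == expected_n
                expected_a = study.topology.planted_cascade_nodes(tf, broken)
                got_a = asd[tf].node_set() if tf in asd else {tf}
                assert got_a == expected_a
            assert len(normal) >= len(asd)
        # paper-style headline comparison in the progenitor stage
        normal_npc = rio.read_cascade_json(
            pipeline_dir / "cascades_NPC_normal.json", config)
        asd_npc = rio.read_cascade_json(
            pipeline_dir / "cascades_NPC_ASD.json", config)
        assert sum(c.size for c in normal_npc) > sum(c.size for c in asd_npc)

    def test_roots_with_all_layer1_edges_broken_are_lost(self, study, config,
                                                         pipeline_dir):
        from regcascade import io as rio
        broken = set(map(tuple, study.truth.broken_edges))
        layer1 = {}
        for p, c, layer in study.topology.cascade_edges:
            if layer == 1:
                layer1.setdefault(p, []).append((p, c))
        for tf, lncs in study.topology.lncrna_of_tf.items():
            layer1.setdefault(tf, []).extend((tf, l) for l in lncs)
        fully_broken = [tf for tf, edges in layer1.items()
                        if all(e in broken for e in edges)]
        asd = {c.root for c in rio.read_cascade_json(
            pipeline_dir / "cascades_NPC_ASD.json", config)}
        for tf in fully_broken:
            assert tf not in asd
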