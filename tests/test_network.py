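import numpy as np
import pandas as pd
import pytest

from ncnet import network
from ncnet.io import InteractionTable
from ncnet.synth import (SynthConfig, contrast_set_from_directions,
                         simulate_interactions)
from tests.conftest import make_interactions


def dirset(contrast, genes, biotype):
    return contrast_set_from_directions(
        contrast, {g: "up" for g in genes}, biotype)


CONTRAST = "ObCRC_vs_Nw"


@pytest.fixture(scope="module")
def planted():
    cfg = SynthConfig(seed=5)
    evidence, truth = simulate_interactions(cfg)
    sets = {"lncRNA": contrast_set_from_directions(
                CONTRAST, truth.del_directions, "lncRNA_known"),
            "miRNA": contrast_set_from_directions(
                CONTRAST, truth.dem_directions, "miRNA"),
            "mRNA": contrast_set_from_directions(
                CONTRAST, truth.det_directions, "mRNA")}
    layers = [
        network.build_dem_det_layer(sets["miRNA"], sets["mRNA"], evidence),
        network.build_del_dem_layer(sets["lncRNA"], sets["miRNA"], evidence,
                                    cfg.score_cutoff),
        network.build_del_det_layer(sets["lncRNA"], sets["mRNA"], evidence),
    ]
    net = network.integrate(layers, sets)
    return cfg, evidence, truth, sets, layers, net


class TestLayers:
    def test_det_filter_excludes_non_differential_targets(self):
        ev = make_interactions(
            [("miR-1", "miRNA", "G9", "mRNA", "validated", np.nan)])
        dem = dirset(CONTRAST, ["miR-1"], "miRNA")
        det = dirset(CONTRAST, ["G1"], "mRNA")  # G9 not differential
        assert len(network.build_dem_det_layer(dem, det, ev)) == 0

    def test_planted_five_by_four_gives_twenty_edges(self):
        mirnas = [f"m{i}" for i in range(5)]
        genes = [f"G{i}" for i in range(4)]
        rows = [(m, "miRNA", g, "mRNA", "validated", np.nan)
                for m in mirnas for g in genes]
        ev = make_interactions(rows)
        layer = network.build_dem_det_layer(dirset(CONTRAST, mirnas, "miRNA"),
                                            dirset(CONTRAST, genes, "mRNA"),
                                            ev)
        assert len(layer) == 20  # brute-force count of the planted list

    def test_predicted_mirna_target_rows_ignored(self):
        ev = make_interactions(
            [("miR-1", "miRNA", "G1", "mRNA", "predicted", 0.99)])
        dem = dirset(CONTRAST, ["miR-1"], "miRNA")
        det = dirset(CONTRAST, ["G1"], "mRNA")
        assert len(network.build_dem_det_layer(dem, det, ev)) == 0

    def test_score_cutoff_boundary_inclusive(self, evidence_small):
        del_set = dirset(CONTRAST, ["L1", "L2"], "lncRNA_known")
        dem = dirset(CONTRAST, ["miR-1", "miR-2"], "miRNA")
        layer = network.build_del_dem_layer(del_set, dem, evidence_small, 0.6)
        pairs = set(zip(layer["source"], layer["target"]))
        assert ("L2", "miR-2") in pairs      # score 0.60 kept
        assert ("L2", "miR-1") not in pairs  # score 0.59 dropped

    def test_validated_takes_precedence_over_predicted(self):
        ev = make_interactions([
            ("L1", "lncRNA", "miR-1", "miRNA", "predicted", 0.9),
            ("L1", "lncRNA", "miR-1", "miRNA", "validated", np.nan)])
        layer = network.build_del_dem_layer(
            dirset(CONTRAST, ["L1"], "lncRNA_known"),
            dirset(CONTRAST, ["miR-1"], "miRNA"), ev, 0.6)
        assert len(layer) == 1
        assert layer["evidence"].iloc[0] == "validated"

    def test_raising_cutoff_never_adds_edges(self, evidence_small):
        del_set = dirset(CONTRAST, ["L1", "L2"], "lncRNA_known")
        dem = dirset(CONTRAST, ["miR-1", "miR-2"], "miRNA")
        prev = None
        for cutoff in (0.2, 0.4, 0.6, 0.8, 0.95):
            layer = network.build_del_dem_layer(del_set, dem, evidence_small,
                                                cutoff)
            pairs = set(zip(layer["source"], layer["target"]))
            if prev is not None:
                assert pairs <= prev
            prev = pairs

    def test_predicted_lncrna_mrna_rows_never_edges(self, evidence_small):
        del_set = dirset(CONTRAST, ["L1", "L2"], "lncRNA_known")
        det = dirset(CONTRAST, ["G1", "G2"], "mRNA")
        layer = network.build_del_det_layer(del_set, det, evidence_small)
        assert ("L2", "G2") not in set(zip(layer["source"], layer["target"]))
        assert ("L1", "G1") in set(zip(layer["source"], layer["target"]))

    def test_empty_inputs_give_empty_layers(self, evidence_small):
        empty = dirset(CONTRAST, [], "miRNA")
        det = dirset(CONTRAST, ["G1"], "mRNA")
        assert len(network.build_dem_det_layer(empty, det,
                                               evidence_small)) == 0
        assert len(network.build_del_dem_layer(
            dirset(CONTRAST, [], "lncRNA_known"), empty, evidence_small)) == 0


class TestIntegrateAndHubs:
    def test_planted_layer_edge_counts_match_truth(self, planted):
        _, _, truth, _, layers, _ = planted
        for layer_df, name in zip(layers, ("dem_det", "del_dem", "del_det")):
            got = set(zip(layer_df["source"], layer_df["target"]))
            assert got == set(truth.layer_edges[name]), name

    def test_integrated_counts_and_handshake(self, planted):
        _, _, truth, _, _, net = planted
        n_true_edges = sum(len(v) for v in truth.layer_edges.values())
        assert net.n_edges == n_true_edges
        assert sum(dict(net.graph.degree()).values()) == 2 * net.n_edges

    def test_degree_equals_incident_edge_recount(self, planted):
        _, _, _, _, _, net = planted
        recount: dict = {}
        for row in net.edge_table().itertuples(index=False):
            recount[row.source] = recount.get(row.source, 0) + 1
            recount[row.target] = recount.get(row.target, 0) + 1
        assert recount == dict(net.graph.degree())

    def test_hub_sets_match_planted_truth_exactly(self, planted):
        _, _, truth, _, _, net = planted
        hubs = network.identify_hubs(net, 6)
        for cls in ("lncRNA", "miRNA", "mRNA"):
            assert hubs.ids(cls) == frozenset(truth.hubs.get(cls, {})), cls

    def test_three_planted_lncrna_hubs(self, planted):
        _, _, _, _, _, net = planted
        hubs = network.identify_hubs(net, 6)
        assert len(hubs.ids("lncRNA")) == 3

    def test_xist_like_lncrna_has_264_mrna_targets(self, planted):
        cfg, _, truth, _, layers, _ = planted
        del_det = layers[2]
        xist_edges = (del_det["source"] == "LNC001").sum()
        assert xist_edges == cfg.xist_like_targets == 264
        assert truth.hubs["lncRNA"]["LNC001"] >= 264

    def test_missing_endpoint_direction_errors(self):
        edges = pd.DataFrame([("miR-1", "G1", "dem_det", "validated",
                               np.nan)],
                             columns=["source", "target", "layer",
                                      "evidence", "score"])
        with pytest.raises(ValueError, match="missing"):
            network.integrate([edges],
                              {"miRNA": dirset(CONTRAST, ["miR-1"], "miRNA")})

    def test_empty_layers_give_empty_network(self, planted):
        _, _, _, sets, _, _ = planted
        net = network.integrate([], sets)
        assert net.n_nodes == net.n_edges == 0

    def test_star_graph_hub_identification(self):
        rows = [("miR-c", "miRNA", f"G{i}", "mRNA", "validated", np.nan)
                for i in range(7)]
        ev = make_interactions(rows)
        dem = dirset(CONTRAST, ["miR-c"], "miRNA")
        det = dirset(CONTRAST, [f"G{i}" for i in range(7)], "mRNA")
        net = network.integrate(
            [network.build_dem_det_layer(dem, det, ev)],
            {"miRNA": dem, "mRNA": det})
        hubs = network.identify_hubs(net, 6)
        assert hubs.all_ids() == {"miR-c"}
        all_nodes = network.identify_hubs(net, 1)
        assert all_nodes.all_ids() == set(net.graph.nodes)


class TestDisplayAndExport:
    def test_display_zero_threshold_is_identity(self, planted):
        _, _, _, _, _, net = planted
        out = network.display_subgraph(net, 0)
        assert out.n_nodes == net.n_nodes and out.n_edges == net.n_edges

    def test_display_path_keeps_center_but_no_edges(self):
        ev = make_interactions([
            ("L1", "lncRNA", "miR-b", "miRNA", "validated", np.nan),
            ("miR-b", "miRNA", "G1", "mRNA", "validated", np.nan)])
        del_set = dirset(CONTRAST, ["L1"], "lncRNA_known")
        dem = dirset(CONTRAST, ["miR-b"], "miRNA")
        det = dirset(CONTRAST, ["G1"], "mRNA")
        net = network.integrate(
            [network.build_dem_det_layer(dem, det, ev),
             network.build_del_dem_layer(del_set, dem, ev)],
            {"lncRNA": del_set, "miRNA": dem, "mRNA": det})
        out = network.display_subgraph(net, 2)
        assert set(out.graph.nodes) == {"miR-b"}
        assert out.n_edges == 0

    def test_display_uses_full_network_degrees_idempotently(self, planted):
        _, _, _, _, _, net = planted
        once = network.display_subgraph(net, 6)
        # same thresholds applied to full-network degrees: recomputing the
        # kept-node set from the original network changes nothing
        keep = {n for n, d in net.graph.degree() if d >= 6}
        assert set(once.graph.nodes) == keep

    def test_sif_line_format(self, planted, tmp_path):
        ev = make_interactions(
            [("miR-1", "miRNA", "GENE1", "mRNA", "validated", np.nan)])
        dem = dirset(CONTRAST, ["miR-1"], "miRNA")
        det = dirset(CONTRAST, ["GENE1"], "mRNA")
        net = network.integrate([network.build_dem_det_layer(dem, det, ev)],
                                {"miRNA": dem, "mRNA": det})
        path = tmp_path / "net.sif"
        network.export_graph(net, path, "SIF")
        assert path.read_text().strip() == "GENE1\tdem_det\tmiR-1"

    def test_graphml_round_trip(self, planted, tmp_path):
        _, _, _, _, _, net = planted
        path = tmp_path / "net.graphml"
        network.export_graph(net, path, "GraphML")
        back = network.read_graphml(path)
        assert dict(back.graph.nodes(data=True)) == \
            dict(net.graph.nodes(data=True))
        assert {frozenset(e): d for *e, d in
                back.graph.edges(data=True)} == \
            {frozenset(e): d for *e, d in net.graph.edges(data=True)}

    def test_empty_network_exports(self, tmp_path):
        import networkx as nx
        net = network.TripartiteNetwork(nx.Graph())
        for fmt, name in (("SIF", "e.sif"), ("GraphML", "e.graphml")):
            network.export_graph(net, tmp_path / name, fmt)
            assert (tmp_path / name).exists()
        assert network.read_graphml(tmp_path / "e.graphml").n_nodes == 0

    def test_unknown_format_rejected(self, planted, tmp_path):
        _, _, _, _, _, net = planted
        with pytest.raises(ValueError, match="format"):
            network.export_graph(net, tmp_path / "x", "DOT")


class TestClassPairProperty:
    def test_random_evidence_tables_never_break_class_pairs(self):
        rng = np.random.default_rng(0)
        classes = {"miRNA": [f"m{i}" for i in range(6)],
                   "lncRNA": [f"l{i}" for i in range(4)],
                   "mRNA": [f"g{i}" for i in range(10)]}
        pairs = [("miRNA", "mRNA"), ("lncRNA", "miRNA"), ("lncRNA", "mRNA")]
        for _ in range(200):
            rows = []
            for _ in range(rng.integers(1, 15)):
                sc, tc = pairs[rng.integers(0, 3)]
                ev = "validated" if rng.random() < 0.5 else "predicted"
                rows.append((rng.choice(classes[sc]), sc,
                             rng.choice(classes[tc]), tc, ev,
                             round(float(rng.uniform(0, 1)), 3)
                             if ev == "predicted" else np.nan))
            df = pd.DataFrame(rows, columns=["source_id", "source_class",
                                             "target_id", "target_class",
                                             "evidence", "score"])
            df = df.drop_duplicates(["source_id", "target_id", "evidence"])
            table = InteractionTable(df.reset_index(drop=True))
            sets = {cls: dirset(CONTRAST, names,
                                {"miRNA": "miRNA", "mRNA": "mRNA",
                                 "lncRNA": "lncRNA_known"}[cls])
                    for cls, names in classes.items()}
            layers = [
                network.build_dem_det_layer(sets["miRNA"], sets["mRNA"],
                                            table),
                network.build_del_dem_layer(sets["lncRNA"], sets["miRNA"],
                                            table,
                                            float(rng.uniform(0.2, 0.9))),
                network.build_del_det_layer(sets["lncRNA"], sets["mRNA"],
                                            table),
            ]
            net = network.integrate(layers, sets)  # validates class pairs
            filtered = network.display_subgraph(net, int(rng.integers(0, 4)))
            assert filtered.n_edges <= net.n_edges
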