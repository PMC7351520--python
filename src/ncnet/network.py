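"""Tripartite lncRNA-miRNA-mRNA network construction and hub analysis.

Three evidence layers are built per contrast, each restricted to features
differential in that contrast (the "DET filter"):

* ``dem_det`` — validated miRNA->mRNA target interactions;
* ``del_dem`` — lncRNA-miRNA interactions, either experimentally verified or
  predicted with score >= a cutoff (default 0.6, boundary inclusive); when a
  pair has both kinds of support the stored evidence is ``validated``;
* ``del_det`` — experimentally verified lncRNA-mRNA interactions only.

Layers are integrated into one undirected graph whose nodes carry molecule
class and regulation direction. "Degree" is the plain incident-edge count
across all layers; hubs are nodes with degree >= a threshold (default 6,
i.e. "exceeding 5"). Display filtering keeps nodes by their full-network
degree, then drops edges with a removed endpoint. Export formats are SIF
(one line per edge) and GraphML (round-trippable with all attributes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from ncnet.io import InteractionTable
from ncnet.setops import ContrastSet

__all__ = ["TripartiteNetwork", "HubReport", "build_dem_det_layer",
           "build_del_dem_layer", "build_del_det_layer", "integrate",
           "identify_hubs", "display_subgraph", "export_graph", "read_graphml"]

LAYERS = ("dem_det", "del_dem", "del_det")
_LAYER_CLASSES = {"dem_det": ("miRNA", "mRNA"),
                  "del_dem": ("lncRNA", "miRNA"),
                  "del_det": ("lncRNA", "mRNA")}
_EDGE_COLS = ["source", "target", "layer", "evidence", "score"]


@dataclass(frozen=True)
class TripartiteNetwork:
    """Undirected integrated network; nodes carry node_class and direction,
    edges carry layer, evidence and (for predicted edges) score."""

    graph: nx.Graph = field(repr=False)

    def __post_init__(self) -> None:
        for u, v, attrs in self.graph.edges(data=True):
            if u == v:
                raise ValueError(f"self-edge at {u}")
            layer = attrs.get("layer")
            if layer not in _LAYER_CLASSES:
                raise ValueError(f"edge ({u}, {v}) has bad layer {layer!r}")
            want = set(_LAYER_CLASSES[layer])
            got = {self.graph.nodes[u]["node_class"],
                   self.graph.nodes[v]["node_class"]}
            if got != want:
                raise ValueError(
                    f"edge ({u}, {v}) in layer {layer} joins classes {got}")

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def nodes_of_class(self, node_class: str) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True)
                if d["node_class"] == node_class]

    def edge_table(self) -> pd.DataFrame:
        rows = [(min(u, v), max(u, v), d["layer"], d["evidence"],
                 d.get("score")) for u, v, d in self.graph.edges(data=True)]
        return pd.DataFrame(sorted(rows), columns=_EDGE_COLS)


@dataclass(frozen=True)
class HubReport:
    """Hub nodes by molecule class, each with its integrated-network degree,
    sorted by degree descending then id ascending."""

    min_degree: int
    hubs: Mapping[str, tuple]  # class -> ((node, degree), ...)

    def ids(self, node_class: str) -> frozenset:
        return frozenset(n for n, _ in self.hubs.get(node_class, ()))

    def all_ids(self) -> frozenset:
        return frozenset(n for hubs in self.hubs.values() for n, _ in hubs)


def _empty_edges() -> pd.DataFrame:
    return pd.DataFrame(columns=_EDGE_COLS)


def build_dem_det_layer(dem: ContrastSet, det: ContrastSet,
                        evidence: InteractionTable) -> pd.DataFrame:
    """Validated miRNA->mRNA edges filtered to differential features.

    Predicted miRNA-target rows are ignored: only experimentally validated
    target interactions enter this layer.
    """
    rows = evidence.subset("miRNA", "mRNA")
    keep = (rows["evidence"] == "validated") & \
        rows["source_id"].isin(dem.genes) & rows["target_id"].isin(det.genes)
    sel = rows.loc[keep]
    out = pd.DataFrame({"source": sel["source_id"], "target": sel["target_id"],
                        "layer": "dem_det", "evidence": "validated",
                        "score": float("nan")})
    return out.drop_duplicates(["source", "target"]).reset_index(drop=True) \
        if len(out) else _empty_edges()


def build_del_dem_layer(del_set: ContrastSet, dem: ContrastSet,
                        evidence: InteractionTable,
                        score_cutoff: float = 0.6) -> pd.DataFrame:
    """lncRNA-miRNA edges: verified, or predicted with score >= cutoff.

    The verified and predicted sources are unioned; a pair supported by both
    is stored once with evidence ``validated``.
    """
    rows = evidence.subset("lncRNA", "miRNA")
    de = rows["source_id"].isin(del_set.genes) & \
        rows["target_id"].isin(dem.genes)
    ok = de & ((rows["evidence"] == "validated") |
               ((rows["evidence"] == "predicted") &
                (rows["score"] >= score_cutoff)))
    sel = rows.loc[ok].copy()
    if not len(sel):
        return _empty_edges()
    # validated takes precedence on duplicate pairs
    sel["rank"] = (sel["evidence"] != "validated").astype(int)
    sel = sel.sort_values(["source_id", "target_id", "rank"])
    sel = sel.drop_duplicates(["source_id", "target_id"], keep="first")
    sel.loc[sel["evidence"] == "validated", "score"] = float("nan")
    return pd.DataFrame({"source": sel["source_id"],
                         "target": sel["target_id"], "layer": "del_dem",
                         "evidence": sel["evidence"], "score": sel["score"]}
                        ).reset_index(drop=True)


def build_del_det_layer(del_set: ContrastSet, det: ContrastSet,
                        evidence: InteractionTable) -> pd.DataFrame:
    """Experimentally verified lncRNA-mRNA edges filtered to differential
    features; predicted rows are never admitted."""
    rows = evidence.subset("lncRNA", "mRNA")
    keep = (rows["evidence"] == "validated") & \
        rows["source_id"].isin(del_set.genes) & \
        rows["target_id"].isin(det.genes)
    sel = rows.loc[keep]
    if not len(sel):
        return _empty_edges()
    out = pd.DataFrame({"source": sel["source_id"], "target": sel["target_id"],
                        "layer": "del_det", "evidence": "validated",
                        "score": float("nan")})
    return out.drop_duplicates(["source", "target"]).reset_index(drop=True)


def integrate(layers: Iterable[pd.DataFrame],
              class_sets: Mapping[str, ContrastSet]) -> TripartiteNetwork:
    """Union the per-layer edge sets into one typed undirected graph.

    ``class_sets`` maps node_class (miRNA/lncRNA/mRNA) to the ContrastSet
    providing regulation directions; every edge endpoint must be found there.
    Isolated features never enter the network.
    """
    directions: dict[str, tuple[str, str]] = {}
    for node_class, cset in class_sets.items():
        for gene, direction in cset.directions().items():
            directions[gene] = (node_class, direction)

    g = nx.Graph()
    for layer_df in layers:
        for row in layer_df.itertuples(index=False):
            src_cls, tgt_cls = _LAYER_CLASSES[row.layer]
            for node in (row.source, row.target):
                if node not in directions:
                    raise ValueError(
                        f"edge endpoint {node!r} missing from every "
                        "contrast set")
            g.add_node(row.source, node_class=directions[row.source][0],
                       direction=directions[row.source][1])
            g.add_node(row.target, node_class=directions[row.target][0],
                       direction=directions[row.target][1])
            attrs = {"layer": row.layer, "evidence": row.evidence}
            if row.evidence == "predicted" and pd.notna(row.score):
                attrs["score"] = float(row.score)
            g.add_edge(row.source, row.target, **attrs)
    return TripartiteNetwork(g)


def identify_hubs(net: TripartiteNetwork, min_degree: int = 6) -> HubReport:
    """Nodes whose integrated degree reaches min_degree, by molecule class."""
    if min_degree < 1:
        raise ValueError("min_degree must be >= 1")
    by_class: dict[str, list[tuple[str, int]]] = {}
    for node, deg in net.graph.degree():
        if deg >= min_degree:
            cls = net.graph.nodes[node]["node_class"]
            by_class.setdefault(cls, []).append((node, deg))
    hubs = {cls: tuple(sorted(items, key=lambda nd: (-nd[1], nd[0])))
            for cls, items in by_class.items()}
    return HubReport(min_degree, hubs)


def display_subgraph(net: TripartiteNetwork, min_degree: int
                     ) -> TripartiteNetwork:
    """Display filter: keep nodes with FULL-network degree >= min_degree and
    the edges whose both endpoints are kept (degrees are not recomputed)."""
    if min_degree < 0:
        raise ValueError("min_degree must be >= 0")
    keep = {n for n, d in net.graph.degree() if d >= min_degree}
    return TripartiteNetwork(net.graph.subgraph(keep).copy())


def export_graph(net: TripartiteNetwork, path, format: str = "GraphML"
                 ) -> None:
    """Write the network as SIF ("source layer target" lines) or GraphML."""
    fmt = format.lower()
    if fmt == "sif":
        with open(path, "w", encoding="utf-8") as fh:
            for row in net.edge_table().itertuples(index=False):
                fh.write(f"{row.source}\t{row.layer}\t{row.target}\n")
    elif fmt == "graphml":
        nx.write_graphml(net.graph, path)
    else:
        raise ValueError(f"unknown format {format!r} (SIF or GraphML)")


def read_graphml(path) -> TripartiteNetwork:
    """Re-import a GraphML export, reproducing the network exactly."""
    return TripartiteNetwork(nx.read_graphml(path))
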