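"""End-to-end pipeline orchestration with a machine-readable summary.

Stages run in dependency order on whatever inputs the config provides:
contrast-set collapse and Venn overlap always (DEL/DEM tables are mandatory,
defaulting to the shipped fixtures); optional count-based DE re-calling,
per-contrast network construction + hub reports, over-representation
analysis and qPCR validation when their inputs are configured. The summary
is deterministic for fixed inputs and seed (sorted keys, no timestamps), so
re-running a pipeline yields byte-identical summary.json.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from ncnet import de, enrich, io, network, qpcr, setops

log = logging.getLogger("ncnet")

__all__ = ["PipelineConfig", "run_pipeline", "overlap_summary"]

_THRESHOLD_BOUNDS = {
    "fdr_lncrna": (0.0, 1.0), "fdr_mirna": (0.0, 1.0),
    "score_cutoff": (0.0, 1.0), "enrich_alpha": (0.0, 1.0),
}


@dataclass
class PipelineConfig:
    """Inputs and thresholds of one full run.

    ``del_tables`` / ``dem_tables`` map contrast_id -> TSV path and default
    to the shipped fixtures when left empty. Optional inputs switch their
    stages on: ``det_tables`` + ``evidence`` enable networks and (with
    ``gmt``) enrichment; ``counts`` + ``groups`` enable DE re-calling;
    ``plate`` enables the qPCR stage.
    """

    out_dir: str = "ncnet_run"
    del_tables: dict = field(default_factory=dict)
    dem_tables: dict = field(default_factory=dict)
    det_tables: dict = field(default_factory=dict)
    evidence: str | None = None
    gmt: str | None = None
    counts: str | None = None
    groups: str | None = None
    plate: str | None = None
    qpcr_control: str = "Nw"
    contrasts: tuple = io.CONTRASTS
    seed: int = 0
    fdr_lncrna: float = 0.05
    fdr_mirna: float = 0.06
    min_reads: int = 10
    score_cutoff: float = 0.6
    hub_min_degree: int = 6
    display_min_degree: int = 6
    enrich_alpha: float = 0.05
    kappa_min: float = 0.4

    def __post_init__(self) -> None:
        for name, (lo, hi) in _THRESHOLD_BOUNDS.items():
            v = getattr(self, name)
            if not lo < v < hi:
                raise ValueError(f"{name}={v} outside ({lo}, {hi})")
        if self.min_reads < 0 or self.hub_min_degree < 1:
            raise ValueError("bad min_reads / hub_min_degree")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def input_paths(self) -> dict[str, str]:
        paths: dict[str, str] = {}
        for prefix, tables in (("del", self.del_tables),
                               ("dem", self.dem_tables),
                               ("det", self.det_tables)):
            for cid, p in tables.items():
                paths[f"{prefix}:{cid}"] = str(p)
        for name in ("evidence", "gmt", "counts", "groups", "plate"):
            p = getattr(self, name)
            if p is not None:
                paths[name] = str(p)
        return paths


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def overlap_summary(del_sets: Mapping[str, setops.ContrastSet],
                    dem_sets: Mapping[str, setops.ContrastSet]) -> dict:
    """All multi-contrast overlap statistics for the three-contrast design."""
    order = list(del_sets)
    del_venn = setops.venn_partition(*(del_sets[c] for c in order))
    dem_venn = setops.venn_partition(*(dem_sets[c] for c in order))
    shared = setops.shared_obesity_cancer(del_venn, dem_venn)

    def venn_block(venn, sets):
        pairs = {}
        for i, a in enumerate(order):
            for b in order[i + 1:]:
                pairs[f"{a}&{b}"] = sorted(venn.members(a, b))
        return {
            "per_contrast": {c: {"n_genes": len(sets[c]),
                                 **setops.direction_tally(sets[c])}
                             for c in order},
            "total_genes": venn.union_size(),
            "triple": sorted(venn.triple),
            "pairwise_exact": pairs,
        }

    return {
        "del": venn_block(del_venn, del_sets),
        "dem": venn_block(dem_venn, dem_sets),
        "shared_obesity_cancer": sorted(shared),
        "n_shared_obesity_cancer": len(shared),
    }


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all configured stages; write per-stage outputs and
    summary.json under ``cfg.out_dir``; return the summary dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # fail fast: every referenced input must exist before any computation
    del_tables = dict(cfg.del_tables) or \
        {c: str(io.fixture_path("del", c)) for c in cfg.contrasts}
    dem_tables = dict(cfg.dem_tables) or \
        {c: str(io.fixture_path("dem", c)) for c in cfg.contrasts}
    paths = dict(cfg.input_paths())
    for prefix, tables in (("del", del_tables), ("dem", dem_tables)):
        for cid, p in tables.items():
            paths[f"{prefix}:{cid}"] = str(p)
    missing = [p for p in paths.values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"missing input file(s): {missing}")

    manifest = {
        "inputs": {k: {"path": v, "sha256_16": _digest(v)}
                   for k, v in sorted(paths.items())},
        "parameters": {k: getattr(cfg, k) for k in (
            "seed", "fdr_lncrna", "fdr_mirna", "min_reads", "score_cutoff",
            "hub_min_degree", "display_min_degree", "enrich_alpha",
            "kappa_min")},
    }
    summary: dict = {"parameters": manifest["parameters"]}

    # --- stage: contrast sets + overlaps -----------------------------------
    log.info("stage setops: %d contrasts", len(cfg.contrasts))
    del_sets = {c: setops.build_contrast_set(io.read_contrast_table(
        del_tables[c], c)) for c in cfg.contrasts}
    dem_sets = {c: setops.build_contrast_set(io.read_contrast_table(
        dem_tables[c], c)) for c in cfg.contrasts}
    if len(cfg.contrasts) == 3:
        summary["overlaps"] = overlap_summary(del_sets, dem_sets)
    else:  # Venn algebra is defined for the three-contrast design only
        summary["overlaps"] = {
            "per_contrast": {
                kind: {c: {"n_genes": len(s),
                           **setops.direction_tally(s)}
                       for c, s in sets.items()}
                for kind, sets in (("del", del_sets), ("dem", dem_sets))}}

    # --- stage: count-based DE re-calling ----------------------------------
    if cfg.counts and cfg.groups:
        log.info("stage de: %s", cfg.counts)
        matrix = io.read_count_matrix(cfg.counts, cfg.groups)
        de_block = {}
        for c in cfg.contrasts:
            test_group = c.split("_vs_")[0]
            control = c.split("_vs_")[1]
            result = de.run_de(matrix, control, test_group,
                               fdr_threshold=cfg.fdr_mirna,
                               min_reads=cfg.min_reads)
            result.table.to_csv(out / f"de_{c}.tsv", sep="\t",
                                index_label="feature_id")
            calls = result.table["call"].value_counts()
            de_block[c] = {"dispersion": result.dispersion,
                           "n_tested": len(result.table),
                           "n_up": int(calls.get("up", 0)),
                           "n_down": int(calls.get("down", 0))}
        summary["de"] = de_block

    # --- stage: networks + hubs --------------------------------------------
    if cfg.evidence and cfg.det_tables:
        evidence = io.read_interaction_table(cfg.evidence)
        net_block = {}
        for c in cfg.contrasts:
            if c not in cfg.det_tables:
                continue
            log.info("stage network: %s", c)
            det = setops.build_contrast_set(
                io.read_contrast_table(cfg.det_tables[c], c))
            layers = [
                network.build_dem_det_layer(dem_sets[c], det, evidence),
                network.build_del_dem_layer(del_sets[c], dem_sets[c],
                                            evidence, cfg.score_cutoff),
                network.build_del_det_layer(del_sets[c], det, evidence),
            ]
            net = network.integrate(layers, {"miRNA": dem_sets[c],
                                             "lncRNA": del_sets[c],
                                             "mRNA": det})
            network.export_graph(net, out / f"network_{c}.graphml", "GraphML")
            network.export_graph(net, out / f"network_{c}.sif", "SIF")
            hubs = network.identify_hubs(net, cfg.hub_min_degree)
            net_block[c] = {
                "n_nodes": net.n_nodes, "n_edges": net.n_edges,
                "layer_edges": {ly: int((net.edge_table()["layer"] == ly)
                                        .sum()) for ly in network.LAYERS},
                "hubs": {cls: [[n, d] for n, d in hubs.hubs.get(cls, ())]
                         for cls in ("lncRNA", "miRNA", "mRNA")},
            }

            # enrichment on this contrast's network mRNA targets
            if cfg.gmt:
                log.info("stage enrich: %s", c)
                terms = io.read_gmt(cfg.gmt)
                in_net = set(net.nodes_of_class("mRNA"))
                query = {g: det.direction(g) for g in sorted(in_net)}
                universe = det.genes
                res = enrich.enrich_collection(query, universe, terms,
                                               cfg.enrich_alpha)
                membership = dict(zip(res["term_id"],
                                      (set(t) for t in res["overlap_genes"])))
                groups_map = enrich.kappa_group_terms(res, membership,
                                                      frozenset(query),
                                                      cfg.kappa_min)
                res_out = res.drop(columns=["overlap_genes"]).copy()
                res_out["group_id"] = res_out["term_id"].map(groups_map)
                res_out.to_csv(out / f"enrichment_{c}.tsv", sep="\t",
                               index=False)
                sig = res[res["significant"]]
                net_block[c]["enrichment"] = {
                    "n_tested": len(res), "n_significant": len(sig),
                    "significant_terms": sorted(sig["term_id"]),
                    "n_groups": int(groups_map.nunique()),
                }
        summary["networks"] = net_block

    # --- stage: qPCR validation --------------------------------------------
    if cfg.plate:
        log.info("stage qpcr: %s", cfg.plate)
        plate = io.read_qpcr_plate(cfg.plate)
        qpcr_block = {}
        for assay in sorted(plate.data["assay_id"].unique()):
            rel = qpcr.ddct_fold(plate, cfg.qpcr_control, assay)
            res = qpcr.anova_lsd(rel.ddct_by_group(), cfg.qpcr_control)
            qpcr_block[assay] = {
                "group_mean_fold": {g: float(v) for g, v in
                                    rel.groups["mean_fold"].items()},
                "anova_p": res.p_omnibus,
                "lsd": {r.group: {"p": r.p, "stars": r.stars}
                        for r in res.pairwise.itertuples(index=False)},
            }
        summary["qpcr"] = qpcr_block

    with open(out / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    with open(out / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1, sort_keys=True)
    log.info("wrote %s", out / "summary.json")
    return summary
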