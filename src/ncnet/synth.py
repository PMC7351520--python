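"""Seeded generators for every input the pipeline consumes, with ground truth.

The generators emulate the study design the pipeline targets: four subject
groups (Nw, Ob, NwCRC, ObCRC) with six replicates each, negative-binomial
small-RNA counts with planted differential expression (miRNA fold changes
within the span observed in adipocyte small-RNA profiling, |log2FC| in
[0.48, 1.56]; lncRNAs in a separate regime including on/off features whose
rate is zero in one condition, producing extreme fold changes), planted
tripartite interaction evidence with prescribed hub degrees including one
very-high-degree lncRNA (the XIST-like pattern, 264 validated mRNA targets),
pathway gene sets with one planted enriched term, and Ct plates whose target
Ct is monotone decreasing in expression.

Everything is a pure function of :class:`SynthConfig`; per-stage RNG streams
are derived as ``default_rng(seed + stage_index)`` with stage indices 0
(counts), 1 (interactions), 2 (qPCR), 3 (gene sets).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ncnet.de import CountMatrix
from ncnet.io import (GeneSetCollection, InteractionTable, QpcrPlate,
                      write_contrast_table, write_count_matrix, write_gmt,
                      write_interaction_table, write_qpcr_plate)
from ncnet.io import ContrastTable
from ncnet.setops import ContrastSet

__all__ = ["SynthConfig", "GroundTruth", "simulate_counts",
           "simulate_interactions", "simulate_gene_sets", "simulate_qpcr",
           "contrast_set_from_directions", "contrast_table_from_directions",
           "simulate_bundle"]

GROUPS = ("Nw", "Ob", "NwCRC", "ObCRC")
_STAGE_COUNTS, _STAGE_INTERACTIONS, _STAGE_QPCR, _STAGE_GENESETS = range(4)


@dataclass(frozen=True)
class SynthConfig:
    """Generation parameters; defaults mirror the emulated study conditions."""

    seed: int = 0
    groups: tuple = GROUPS
    n_per_group: int = 6

    # count matrix (small-RNA features)
    n_mirna: int = 500
    n_lncrna: int = 60
    de_fraction_mirna: float = 0.10
    de_fraction_lncrna: float = 0.20
    onoff_fraction_lncrna: float = 0.3   # of DE lncRNAs: presence/absence
    log2fc_range_mirna: tuple = (0.48, 1.56)
    log2fc_range_lncrna: tuple = (2.0, 8.0)
    dispersion: float = 0.15
    library_size: int = 200_000

    # planted interaction structure (one contrast's network)
    n_del: int = 12
    n_dem: int = 20
    n_det: int = 1000   # differential transcripts, the enrichment universe
    mirna_hub_degrees: tuple = (12, 9, 8)    # dem_det targets of hub miRNAs
    lncrna_hub_degrees: tuple = (8, 7, 6)    # del_dem links of hub lncRNAs
    xist_like_targets: int = 264             # del_det degree of hub lncRNA 1
    score_range: tuple = (0.3, 1.0)          # predicted lncRNA-miRNA scores
    score_cutoff: float = 0.6                # survival rule baked into truth
    n_decoys: int = 15

    # pathway gene sets
    n_terms: int = 50
    planted_term_size: int = 10
    term_size_range: tuple = (10, 40)

    # qPCR plates
    qpcr_sigma: float = 0.2
    qpcr_target_baseline: float = 26.0
    qpcr_reference_baseline: float = 20.0

    def rng(self, stage: int) -> np.random.Generator:
        return np.random.default_rng(self.seed + stage)


@dataclass
class GroundTruth:
    """What was planted, recorded alongside the emitted data."""

    de_log2fc: dict = field(default_factory=dict)    # contrast -> {feat: lfc}
    feature_class: dict = field(default_factory=dict)
    del_directions: dict = field(default_factory=dict)
    dem_directions: dict = field(default_factory=dict)
    det_directions: dict = field(default_factory=dict)
    layer_edges: dict = field(default_factory=dict)  # layer -> [(s, t), ...]
    hubs: dict = field(default_factory=dict)         # class -> {node: degree}
    enriched_terms: list = field(default_factory=list)
    qpcr_folds: dict = field(default_factory=dict)   # assay -> {group: fold}

    def to_json(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["layer_edges"] = {k: [list(e) for e in v]
                                  for k, v in self.layer_edges.items()}
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path, encoding="utf-8") as fh:
            payload = json.load(fh)
        payload["layer_edges"] = {k: [tuple(e) for e in v]
                                  for k, v in payload["layer_edges"].items()}
        return cls(**payload)

    def recount_hubs(self, min_degree: int = 6) -> dict:
        """Brute-force degree recount over the planted edge lists."""
        deg: dict[str, int] = {}
        for edges in self.layer_edges.values():
            for s, t in edges:
                deg[s] = deg.get(s, 0) + 1
                deg[t] = deg.get(t, 0) + 1
        cls_of = {}
        for d, c in ((self.del_directions, "lncRNA"),
                     (self.dem_directions, "miRNA"),
                     (self.det_directions, "mRNA")):
            for g in d:
                cls_of[g] = c
        out: dict[str, dict[str, int]] = {}
        for node, d in deg.items():
            if d >= min_degree:
                out.setdefault(cls_of[node], {})[node] = d
        return out


# ---------------------------------------------------------------------------
# counts


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, phi: float
             ) -> np.ndarray:
    """NB(mean, dispersion phi) draws; Poisson when phi = 0."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if phi == 0:
        out[pos] = rng.poisson(mean[pos])
    else:
        r = 1.0 / phi
        p = r / (r + mean[pos])
        out[pos] = rng.negative_binomial(r, p)
    return out


def simulate_counts(cfg: SynthConfig) -> tuple[CountMatrix, GroundTruth]:
    """NB count matrix over miRNA + lncRNA features with planted DE.

    Per disease group, a fraction of each feature class is differential with
    a group-specific rate multiplier ``2**log2fc``; a fraction of the DE
    lncRNAs is on/off (rate forced to zero on one side), yielding extreme
    log2 fold changes downstream.
    """
    rng = cfg.rng(_STAGE_COUNTS)
    n_feat = cfg.n_mirna + cfg.n_lncrna
    features = [f"miR-syn-{i + 1:04d}" for i in range(cfg.n_mirna)] + \
               [f"LNC-syn-{i + 1:04d}" for i in range(cfg.n_lncrna)]
    classes = ["miRNA"] * cfg.n_mirna + ["lncRNA"] * cfg.n_lncrna

    # baseline relative abundances: heavy-tailed, as in small-RNA libraries
    base = rng.lognormal(mean=0.0, sigma=1.5, size=n_feat)
    base /= base.sum()

    truth = GroundTruth(feature_class=dict(zip(features, classes)))
    disease = [g for g in cfg.groups if g != "Nw"]

    # pass 1: finite planted fold changes per disease group
    selections: dict[str, dict[int, float]] = {}
    for g in disease:
        planted: dict[int, float] = {}
        for cls, n_cls, offset, frac, lo_hi in (
                ("miRNA", cfg.n_mirna, 0, cfg.de_fraction_mirna,
                 cfg.log2fc_range_mirna),
                ("lncRNA", cfg.n_lncrna, cfg.n_mirna, cfg.de_fraction_lncrna,
                 cfg.log2fc_range_lncrna)):
            n_de = int(round(frac * n_cls))
            idx = rng.choice(n_cls, size=n_de, replace=False) + offset
            lfc = rng.uniform(*lo_hi, size=n_de) * \
                rng.choice([-1.0, 1.0], size=n_de)
            planted.update(zip((int(i) for i in idx), (float(v) for v in lfc)))
        selections[g] = planted

    # pass 2: promote part of each group's *exclusive* DE lncRNAs to on/off
    # (positive sign -> present only in the disease group; negative sign ->
    # silenced there); exclusivity keeps other contrasts' truth clean
    on_group = np.full(n_feat, "", dtype=object)
    for g in disease:
        lnc_idx = [i for i in selections[g] if i >= cfg.n_mirna]
        exclusive = [i for i in lnc_idx
                     if not any(i in selections[h] for h in disease if h != g)]
        n_onoff = min(int(round(cfg.onoff_fraction_lncrna * len(lnc_idx))),
                      len(exclusive))
        if n_onoff:
            chosen = rng.choice(len(exclusive), size=n_onoff, replace=False)
            for j in chosen:
                i = exclusive[int(j)]
                sign = np.sign(selections[g][i])
                selections[g][i] = float(sign * np.inf)
                if sign > 0:
                    base[i] = 0.0          # absent everywhere except...
                    on_group[i] = g        # ...the group it switches on in

    rate_mult = {g: np.ones(n_feat) for g in cfg.groups}
    typical = np.median(base[base > 0])
    for g in disease:
        contrast = f"{g}_vs_Nw"
        truth.de_log2fc[contrast] = {features[i]: v
                                     for i, v in selections[g].items()}
        for i, v in selections[g].items():
            if v == -np.inf:
                rate_mult[g][i] = 0.0
            elif np.isfinite(v):
                rate_mult[g][i] = 2.0 ** v

    groups_map, columns = {}, {}
    for g in cfg.groups:
        for rep in range(1, cfg.n_per_group + 1):
            s = f"{g}_{rep}"
            groups_map[s] = g
            rates = base * rate_mult[g]
            rates[on_group == g] = typical
            mean = rates / max(rates.sum(), 1e-300) * cfg.library_size
            columns[s] = _nb_draw(rng, mean, cfg.dispersion)
    counts = pd.DataFrame(columns, index=features)
    return CountMatrix(counts, groups_map), truth


# ---------------------------------------------------------------------------
# interactions


def _directions(rng: np.random.Generator, names: Sequence[str]) -> dict:
    return {n: ("up" if rng.random() < 0.5 else "down") for n in names}


def simulate_interactions(cfg: SynthConfig
                          ) -> tuple[InteractionTable, GroundTruth]:
    """Evidence table with a planted tripartite network for one contrast.

    Hub lncRNA 1 emulates the XIST pattern: ``xist_like_targets`` validated
    mRNA interactions. Designated hub degrees are guaranteed; every other
    ncRNA is capped below the hub threshold (miRNAs: <= 3 targets + <= 2
    lncRNA links; lncRNAs: <= 2 miRNA links + <= 3 mRNA links), so the
    planted hub sets are exact. Decoy rows whose endpoints fall outside the
    differential sets, or whose prediction score misses the cutoff, are mixed
    in and must be excluded downstream.
    """
    if cfg.xist_like_targets > cfg.n_det:
        raise ValueError("xist_like_targets cannot exceed n_det")
    rng = cfg.rng(_STAGE_INTERACTIONS)
    dels = [f"LNC{i + 1:03d}" for i in range(cfg.n_del)]
    dems = [f"miR-syn-{i + 1:03d}" for i in range(cfg.n_dem)]
    dets = [f"GENE{i + 1:04d}" for i in range(cfg.n_det)]
    truth = GroundTruth(del_directions=_directions(rng, dels),
                        dem_directions=_directions(rng, dems),
                        det_directions=_directions(rng, dets))

    n_mhub = len(cfg.mirna_hub_degrees)
    n_lhub = len(cfg.lncrna_hub_degrees)
    if n_mhub > cfg.n_dem or n_lhub > cfg.n_del:
        raise ValueError("more hubs than nodes")

    rows: list[tuple] = []          # evidence-table rows
    edges = {"dem_det": [], "del_dem": [], "del_det": []}

    def add(src, s_cls, tgt, t_cls, evidence, score, layer=None,
            survives=True):
        rows.append((src, s_cls, tgt, t_cls, evidence,
                     score if score is not None else np.nan))
        if layer and survives:
            edges[layer].append((src, tgt))

    # dem_det: validated miRNA -> mRNA targets
    for i, m in enumerate(dems):
        k = cfg.mirna_hub_degrees[i] if i < n_mhub else int(rng.integers(1, 4))
        for g in rng.choice(dets, size=k, replace=False):
            add(m, "miRNA", g, "mRNA", "validated", None, "dem_det")

    # del_dem: hub lncRNAs validated; others sparse, partly predicted
    mirna_link_quota = {m: (np.inf if i < n_mhub else 2)
                        for i, m in enumerate(dems)}

    def take_partners(k):
        pool = [m for m in dems if mirna_link_quota[m] > 0]
        chosen = list(rng.choice(pool, size=min(k, len(pool)), replace=False))
        for m in chosen:
            mirna_link_quota[m] -= 1
        return chosen

    for j, l in enumerate(dels):
        if j < n_lhub:
            for m in take_partners(cfg.lncrna_hub_degrees[j]):
                add(l, "lncRNA", m, "miRNA", "validated", None, "del_dem")
        else:
            for m in take_partners(int(rng.integers(0, 3))):
                if rng.random() < 0.5:
                    add(l, "lncRNA", m, "miRNA", "validated", None, "del_dem")
                else:
                    score = float(rng.uniform(*cfg.score_range))
                    add(l, "lncRNA", m, "miRNA", "predicted", round(score, 4),
                        "del_dem", survives=score >= cfg.score_cutoff)

    # del_det: the XIST-like hub plus sparse verified links elsewhere
    xist = dels[0]
    for g in rng.choice(dets, size=cfg.xist_like_targets, replace=False):
        add(xist, "lncRNA", g, "mRNA", "validated", None, "del_det")
    for l in dels[n_lhub:]:
        for g in rng.choice(dets, size=int(rng.integers(0, 4)), replace=False):
            add(l, "lncRNA", g, "mRNA", "validated", None, "del_det")

    # decoys: endpoints outside the differential sets (never edges)
    for i in range(cfg.n_decoys):
        kind = i % 3
        if kind == 0:
            add(f"miR-decoy-{i}", "miRNA", rng.choice(dets), "mRNA",
                "validated", None)
        elif kind == 1:
            # non-differential target; drawn from non-hub sources so hub
            # row counts stay exactly as planted
            add(rng.choice(dels[n_lhub:]), "lncRNA", f"GENE-decoy-{i}",
                "mRNA", "validated", None)
        else:
            add(f"LNC-decoy-{i}", "lncRNA", rng.choice(dems), "miRNA",
                "predicted", round(float(rng.uniform(*cfg.score_range)), 4))

    df = pd.DataFrame(rows, columns=["source_id", "source_class", "target_id",
                                     "target_class", "evidence", "score"])
    df = df.drop_duplicates(["source_id", "target_id", "evidence"])
    for layer in edges:
        seen = set()
        edges[layer] = [e for e in edges[layer]
                        if not (e in seen or seen.add(e))]
    truth.layer_edges = edges
    truth.hubs = truth.recount_hubs(min_degree=6)
    return InteractionTable(df.reset_index(drop=True)), truth


# ---------------------------------------------------------------------------
# gene sets and qPCR


def simulate_gene_sets(cfg: SynthConfig, universe: Sequence[str],
                       query: Sequence[str]
                       ) -> tuple[GeneSetCollection, GroundTruth]:
    """Random pathway terms plus one planted term fully inside the query."""
    rng = cfg.rng(_STAGE_GENESETS)
    query = list(query)
    universe = list(universe)
    if cfg.planted_term_size > len(query):
        raise ValueError("planted term larger than the query")
    sets: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    planted = rng.choice(query, size=cfg.planted_term_size, replace=False)
    sets["T_planted"] = frozenset(planted)
    names["T_planted"] = "planted enriched pathway"
    for i in range(cfg.n_terms):
        size = int(rng.integers(cfg.term_size_range[0],
                                cfg.term_size_range[1] + 1))
        members = rng.choice(universe, size=min(size, len(universe)),
                             replace=False)
        tid = f"T{i + 1:03d}"
        sets[tid] = frozenset(members)
        names[tid] = f"random pathway {i + 1}"
    truth = GroundTruth(enriched_terms=["T_planted"])
    return GeneSetCollection(sets, names), truth


def simulate_qpcr(cfg: SynthConfig,
                  folds: Mapping[str, Mapping[str, float]],
                  reference_assays: Mapping[str, str] | None = None
                  ) -> tuple[QpcrPlate, GroundTruth]:
    """Ct plate realizing planted per-group fold changes for each assay.

    ``folds`` maps assay -> group -> true fold relative to the Nw control
    (control fold must be 1). Target Ct is the assay baseline minus
    ``log2(fold)`` plus Normal(0, sigma) noise; the reference assay has a
    stable baseline plus the same noise level.
    """
    rng = cfg.rng(_STAGE_QPCR)
    reference_assays = reference_assays or {}
    rows = []
    for assay, group_folds in folds.items():
        if not np.isclose(group_folds.get("Nw", 1.0), 1.0):
            raise ValueError(f"control-group fold must be 1 for {assay}")
        ref = reference_assays.get(
            assay, "let-7a-5p" if assay.lower().startswith("mir") else "GUSB")
        for g in cfg.groups:
            fold = float(group_folds.get(g, 1.0))
            for rep in range(1, cfg.n_per_group + 1):
                ct_t = cfg.qpcr_target_baseline - np.log2(fold) + \
                    rng.normal(0.0, cfg.qpcr_sigma)
                ct_r = cfg.qpcr_reference_baseline + \
                    rng.normal(0.0, cfg.qpcr_sigma)
                rows.append((f"{g}_{rep}", g, assay, ct_t, ct_r, ref))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "assay_id",
                                     "ct_target", "ct_reference",
                                     "reference_assay"])
    truth = GroundTruth(qpcr_folds={a: dict(f) for a, f in folds.items()})
    return QpcrPlate(df), truth


# ---------------------------------------------------------------------------
# helpers and the full bundle


def contrast_set_from_directions(contrast_id: str,
                                 directions: Mapping[str, str],
                                 biotype: str) -> ContrastSet:
    """Wrap a gene -> direction map as a single-transcript ContrastSet."""
    entries = pd.DataFrame(
        {"direction": pd.Series(directions, dtype=object),
         "n_transcripts": 1, "biotype": biotype})
    entries.index.name = "gene_name"
    return ContrastSet(contrast_id, entries.sort_index())


def contrast_table_from_directions(contrast_id: str,
                                   directions: Mapping[str, str],
                                   biotype: str, magnitude: float = 1.0,
                                   fdr: float = 0.01) -> ContrastTable:
    rows = [(g, g, biotype, magnitude if d == "up" else -magnitude, fdr)
            for g, d in sorted(directions.items())]
    df = pd.DataFrame(rows, columns=["feature_id", "gene_name", "biotype",
                                     "log2fc", "fdr"])
    return ContrastTable(contrast_id, df)


def default_qpcr_folds(cfg: SynthConfig) -> dict[str, dict[str, float]]:
    """Planted validation folds for four synthetic assays."""
    rng = cfg.rng(_STAGE_QPCR + 10)
    folds = {}
    for assay in ("LNC001", "LNC002", "miR-syn-001", "miR-syn-002"):
        folds[assay] = {"Nw": 1.0}
        for g in cfg.groups:
            if g != "Nw":
                folds[assay][g] = float(
                    2.0 ** (rng.uniform(0.6, 1.6) * rng.choice([-1, 1])))
    return folds


def simulate_bundle(cfg: SynthConfig, out_dir) -> GroundTruth:
    """Emit every pipeline input to ``out_dir`` and return merged truth.

    Files: counts.tsv, groups.tsv, del.tsv / dem.tsv / det.tsv (one planted
    contrast), evidence.tsv, pathways.gmt, plate.tsv, truth.json.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, t_counts = simulate_counts(cfg)
    write_count_matrix(matrix, out / "counts.tsv", out / "groups.tsv")

    evidence, t_net = simulate_interactions(cfg)
    write_interaction_table(evidence, out / "evidence.tsv")
    contrast = "ObCRC_vs_Nw"
    for name, directions, biotype in (
            ("del", t_net.del_directions, "lncRNA_known"),
            ("dem", t_net.dem_directions, "miRNA"),
            ("det", t_net.det_directions, "mRNA")):
        write_contrast_table(
            contrast_table_from_directions(contrast, directions, biotype),
            out / f"{name}.tsv")

    network_mrna = sorted({g for s, t in t_net.layer_edges["dem_det"]
                           for g in [t]} |
                          {t for s, t in t_net.layer_edges["del_det"]})
    gmt, t_terms = simulate_gene_sets(cfg, sorted(t_net.det_directions),
                                      network_mrna)
    write_gmt(gmt, out / "pathways.gmt")

    folds = default_qpcr_folds(cfg)
    plate, t_qpcr = simulate_qpcr(cfg, folds)
    write_qpcr_plate(plate, out / "plate.tsv")

    truth = GroundTruth(
        de_log2fc=t_counts.de_log2fc,
        feature_class=t_counts.feature_class,
        del_directions=t_net.del_directions,
        dem_directions=t_net.dem_directions,
        det_directions=t_net.det_directions,
        layer_edges=t_net.layer_edges,
        hubs=t_net.hubs,
        enriched_terms=t_terms.enriched_terms,
        qpcr_folds=t_qpcr.qpcr_folds)
    truth.to_json(out / "truth.json")
    return truth
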