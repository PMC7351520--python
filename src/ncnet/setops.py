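"""Gene-level contrast sets and multi-contrast overlap (Venn) algebra.

A contrast table lists differential *transcripts*; overlap statements are
made at the *gene* level, so tables are first collapsed to one entry per
gene symbol. A gene whose transcripts disagree in fold-change sign within a
contrast is "mixed" (inversely modulated) but still counts once, like any
other gene, in overlap regions and totals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from ncnet.io import ContrastTable, ValidationError

__all__ = ["ContrastSet", "VennPartition", "build_contrast_set",
           "venn_partition", "shared_obesity_cancer", "direction_tally",
           "plot_venn3"]


@dataclass(frozen=True)
class ContrastSet:
    """Direction-annotated gene set of one contrast.

    ``entries`` is indexed by gene_name with columns direction
    (up/down/mixed), n_transcripts and biotype.
    """

    contrast_id: str
    entries: pd.DataFrame = field(repr=False)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def genes(self) -> frozenset:
        return frozenset(self.entries.index)

    def direction(self, gene: str) -> str:
        return str(self.entries.loc[gene, "direction"])

    def directions(self) -> dict[str, str]:
        return dict(self.entries["direction"])


@dataclass(frozen=True)
class VennPartition:
    """Exact 7-region partition of three gene sets by membership.

    Regions are keyed by the frozenset of contrast_ids a gene belongs to.
    """

    contrast_ids: tuple[str, str, str]
    region_members: Mapping[frozenset, frozenset] = field(repr=False)

    @property
    def region_counts(self) -> dict[frozenset, int]:
        return {k: len(v) for k, v in self.region_members.items()}

    def members(self, *contrasts: str, exact: bool = True) -> frozenset:
        """Genes in exactly (default) the region of the given contrasts, or
        the full intersection of those contrasts with ``exact=False``."""
        key = frozenset(contrasts)
        if not key <= set(self.contrast_ids):
            raise ValueError(f"unknown contrast(s) in {sorted(key)}")
        if exact:
            return self.region_members.get(key, frozenset())
        out: set = set()
        for region, genes in self.region_members.items():
            if key <= region:
                out |= genes
        return frozenset(out)

    @property
    def triple(self) -> frozenset:
        return self.region_members.get(frozenset(self.contrast_ids),
                                       frozenset())

    def union_size(self) -> int:
        return sum(self.region_counts.values())


def build_contrast_set(t: ContrastTable) -> ContrastSet:
    """Collapse a contrast table to one direction-annotated entry per gene."""
    if (t.data["log2fc"] == 0).any():
        bad = t.data.loc[t.data["log2fc"] == 0, "feature_id"].tolist()
        raise ValidationError(
            f"differential rows must have a signed log2fc; zero at {bad}")
    rows = []
    for gene, grp in t.data.groupby("gene_name", sort=True):
        signs = set(np.sign(grp["log2fc"]))
        direction = "mixed" if len(signs) > 1 else (
            "up" if signs == {1.0} else "down")
        rows.append((gene, direction, len(grp), grp["biotype"].iloc[0]))
    entries = pd.DataFrame(rows, columns=["gene_name", "direction",
                                          "n_transcripts", "biotype"]
                           ).set_index("gene_name")
    return ContrastSet(t.contrast_id, entries)


def venn_partition(a: ContrastSet, b: ContrastSet, c: ContrastSet
                   ) -> VennPartition:
    """Partition the union of three gene sets into the 7 membership regions."""
    ids = (a.contrast_id, b.contrast_id, c.contrast_id)
    if len(set(ids)) != 3:
        raise ValueError(f"contrast_ids must be distinct, got {ids}")
    sets = {s.contrast_id: s.genes for s in (a, b, c)}
    regions: dict[frozenset, set] = {}
    for gene in frozenset().union(*sets.values()):
        key = frozenset(cid for cid, genes in sets.items() if gene in genes)
        regions.setdefault(key, set()).add(gene)
    return VennPartition(ids, {k: frozenset(v) for k, v in regions.items()})


def shared_obesity_cancer(del_venn: VennPartition,
                          dem_venn: VennPartition) -> frozenset:
    """ncRNAs dysregulated in every disease contrast: union of the lncRNA
    and miRNA triple-intersection regions."""
    if set(del_venn.contrast_ids) != set(dem_venn.contrast_ids):
        raise ValueError("partitions built over different contrasts")
    del_part, dem_part = del_venn.triple, dem_venn.triple
    if del_part & dem_part:
        raise ValueError("lncRNA and miRNA namespaces collide: "
                         f"{sorted(del_part & dem_part)}")
    return del_part | dem_part


def direction_tally(s: ContrastSet) -> dict[str, int]:
    counts = s.entries["direction"].value_counts()
    return {"n_up": int(counts.get("up", 0)),
            "n_down": int(counts.get("down", 0)),
            "n_mixed": int(counts.get("mixed", 0))}


def plot_venn3(partition: VennPartition, path, title: str | None = None
               ) -> None:
    """Render a simple three-circle Venn diagram with region counts.

    Minimal matplotlib renderer (circle patches + count labels); layout is
    schematic, not area-proportional.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    a, b, c = partition.contrast_ids
    centers = {a: (-0.45, 0.3), b: (0.45, 0.3), c: (0.0, -0.5)}
    colors = ["#1b9e77", "#d95f02", "#7570b3"]
    fig, ax = plt.subplots(figsize=(5, 5))
    for (cid, xy), col in zip(centers.items(), colors):
        ax.add_patch(Circle(xy, 0.85, alpha=0.3, color=col))
        ax.annotate(cid, xy, xytext=(xy[0] * 2.2, xy[1] * 2.2 + 0.1),
                    ha="center", fontsize=9)
    label_pos = {
        frozenset([a]): (-0.85, 0.55), frozenset([b]): (0.85, 0.55),
        frozenset([c]): (0.0, -1.0), frozenset([a, b]): (0.0, 0.55),
        frozenset([a, c]): (-0.55, -0.25), frozenset([b, c]): (0.55, -0.25),
        frozenset([a, b, c]): (0.0, 0.0),
    }
    for key, xy in label_pos.items():
        ax.annotate(str(len(partition.region_members.get(key, ()))), xy,
                    ha="center", va="center", fontsize=11)
    ax.set_xlim(-1.8, 1.8)
    ax.set_ylim(-1.8, 1.8)
    ax.set_aspect("equal")
    ax.axis("off")
    if title:
        ax.set_title(title)
    fig.savefig(path, bbox_inches="tight")
    plt.close(fig)
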