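"""Tabular I/O: contrast tables, interaction-evidence tables, GMT gene sets,
count matrices, group maps and qPCR Ct plates.

All files are UTF-8, tab-separated, "." decimal mark, Unix newlines. A feature
that is not differential in a contrast is simply absent from that contrast's
table (no sentinel values). Gene symbols are opaque, case-sensitive strings;
no alias resolution is attempted.

The package ships per-contrast fixtures of the published DEL (lncRNA) and DEM
(miRNA) tables, one TSV per comparison against the healthy-lean (Nw) control;
load them with :func:`load_fixture_contrast`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONTRASTS = ("NwCRC_vs_Nw", "Ob_vs_Nw", "ObCRC_vs_Nw")
BIOTYPES = ("mRNA", "lncRNA_known", "lncRNA_novel", "miRNA")
#: legal (source_class, target_class) pairs for evidence edges
CLASS_PAIRS = (("miRNA", "mRNA"), ("lncRNA", "miRNA"), ("lncRNA", "mRNA"))

_CONTRAST_COLS = ["feature_id", "gene_name", "biotype", "log2fc", "fdr"]
_INTERACTION_COLS = ["source_id", "source_class", "target_id", "target_class",
                     "evidence", "score"]
_PLATE_COLS = ["sample_id", "group", "assay_id", "ct_target", "ct_reference",
               "reference_assay"]


class ParseError(ValueError):
    """A file did not conform to the expected dialect."""


class ValidationError(ValueError):
    """A parsed table violated a domain invariant."""


@dataclass(frozen=True)
class ContrastTable:
    """Differential features of one contrast (disease group vs Nw control).

    ``data`` columns: feature_id, gene_name, biotype, log2fc, fdr. One row per
    differential transcript/miRNA; multi-transcript genes contribute several
    rows sharing a gene_name.
    """

    contrast_id: str
    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != _CONTRAST_COLS:
            raise ValidationError(f"bad columns: {list(df.columns)}")
        if df["feature_id"].duplicated().any():
            dups = df.loc[df["feature_id"].duplicated(), "feature_id"].tolist()
            raise ValidationError(f"duplicate feature_id: {dups}")
        bad = set(df["biotype"]) - set(BIOTYPES)
        if bad:
            raise ValidationError(f"unknown biotype(s): {sorted(bad)}")
        if not np.isfinite(df["log2fc"].to_numpy(float)).all():
            raise ValidationError("log2fc must be finite")
        fdr = df["fdr"].to_numpy(float)
        if ((fdr < 0) | (fdr > 1)).any():
            raise ValidationError("fdr outside [0, 1]")

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class InteractionTable:
    """Typed regulatory-evidence edges emulating TarBase / miRTarBase /
    DIANA-LncBase / ENCORI exports.

    ``evidence`` is ``validated`` (experimental support, no score) or
    ``predicted`` (carries a score in [0, 1], e.g. a LncBase prediction score).
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != _INTERACTION_COLS:
            raise ValidationError(f"bad columns: {list(df.columns)}")
        pairs = set(zip(df["source_class"], df["target_class"]))
        bad = pairs - set(CLASS_PAIRS)
        if bad:
            raise ValidationError(f"illegal class pair(s): {sorted(bad)}")
        if set(df["evidence"]) - {"validated", "predicted"}:
            raise ValidationError("evidence must be validated|predicted")
        score = df["score"].to_numpy(float)
        pred = (df["evidence"] == "predicted").to_numpy()
        if np.isnan(score[pred]).any():
            raise ValidationError("predicted rows must carry a score")
        if not np.isnan(score[~pred]).all():
            raise ValidationError("validated rows must not carry a score")
        ok = np.isnan(score) | ((score >= 0) & (score <= 1))
        if not ok.all():
            raise ValidationError("score outside [0, 1]")
        if df.duplicated(["source_id", "target_id", "evidence"]).any():
            raise ValidationError("duplicate (source, target, evidence) rows")

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, source_class: str, target_class: str) -> pd.DataFrame:
        m = (self.data["source_class"] == source_class) & \
            (self.data["target_class"] == target_class)
        return self.data.loc[m]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (pathway terms), as read from a GMT file."""

    sets: Mapping[str, frozenset]
    names: Mapping[str, str]

    def __post_init__(self) -> None:
        for tid, members in self.sets.items():
            if not members:
                raise ValidationError(f"empty gene set: {tid}")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


@dataclass(frozen=True)
class QpcrPlate:
    """Per-sample Ct values for target and endogenous-reference assays."""

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data
        if list(df.columns) != _PLATE_COLS:
            raise ValidationError(f"bad columns: {list(df.columns)}")
        for col in ("ct_target", "ct_reference"):
            vals = df[col].to_numpy(float)
            if not np.isfinite(vals).all():
                bad = df.loc[~np.isfinite(vals), "sample_id"].tolist()
                raise ValidationError(f"non-finite {col} for sample(s) {bad}")

    def __len__(self) -> int:
        return len(self.data)


# ---------------------------------------------------------------------------
# readers / writers


def _read_tsv(path, columns, numeric):
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty file (missing header)") from None
    if list(df.columns) != columns:
        raise ParseError(f"{path}: expected header {columns}, "
                         f"got {list(df.columns)}")
    for col in numeric:
        raw = df[col]
        converted = pd.to_numeric(raw.mask(raw == "", np.nan),
                                  errors="coerce")
        bad = converted.isna() & (raw != "")
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based, after header
            raise ParseError(
                f"{path}:{line}: malformed numeric field {col!r}: "
                f"{raw[bad.idxmax()]!r}")
        df[col] = converted
    return df


def read_contrast_table(path, contrast_id: str) -> ContrastTable:
    """Read one contrast's differential-feature table.

    Rows with empty log2fc cells are rejected: a feature that is not
    differential in this contrast must not appear as a row at all.
    """
    df = _read_tsv(path, _CONTRAST_COLS, ["log2fc", "fdr"])
    if df["log2fc"].isna().any() or df["fdr"].isna().any():
        line = int((df["log2fc"].isna() | df["fdr"].isna()).idxmax()) + 2
        raise ParseError(f"{path}:{line}: empty numeric cell "
                         "(non-differential features must be absent rows)")
    return ContrastTable(contrast_id, df.reset_index(drop=True))


def write_contrast_table(table: ContrastTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_interaction_table(path) -> InteractionTable:
    df = _read_tsv(path, _INTERACTION_COLS, ["score"])
    return InteractionTable(df.reset_index(drop=True))


def write_interaction_table(table: InteractionTable, path) -> None:
    table.data.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT gene-set file: term_id TAB description TAB gene1 TAB ...

    Duplicate member symbols within a line are deduplicated; a duplicate
    term_id across lines is an error.
    """
    sets: dict[str, frozenset] = {}
    names: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line needs >= 3 "
                                 f"fields, got {len(fields)}")
            tid, desc, *genes = fields
            if tid in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate term_id "
                                      f"{tid!r}")
            members = frozenset(g for g in genes if g)
            if not members:
                raise ParseError(f"{path}:{lineno}: term {tid!r} has no genes")
            sets[tid] = members
            names[tid] = desc
    return GeneSetCollection(sets, names)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for tid in collection.sets:
            genes = "\t".join(sorted(collection.sets[tid]))
            fh.write(f"{tid}\t{collection.names.get(tid, tid)}\t{genes}\n")


def read_count_matrix(counts_path, groups_path):
    """Read a raw count matrix (features x samples TSV, first column
    feature_id) plus a two-column sample->group TSV, returning a
    :class:`ncnet.de.CountMatrix`."""
    from ncnet.de import CountMatrix

    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    groups_df = pd.read_csv(groups_path, sep="\t", dtype=str)
    if groups_df.shape[1] != 2:
        raise ParseError(f"{groups_path}: expected two columns "
                         "(sample, group)")
    groups = dict(zip(groups_df.iloc[:, 0], groups_df.iloc[:, 1]))
    return CountMatrix(counts, groups)


def write_count_matrix(matrix, counts_path, groups_path) -> None:
    matrix.counts.to_csv(counts_path, sep="\t", index_label="feature_id")
    pd.DataFrame({"sample": list(matrix.sample_groups),
                  "group": list(matrix.sample_groups.values())}
                 ).to_csv(groups_path, sep="\t", index=False)


def read_qpcr_plate(path) -> QpcrPlate:
    df = _read_tsv(path, _PLATE_COLS, ["ct_target", "ct_reference"])
    return QpcrPlate(df.reset_index(drop=True))


def write_qpcr_plate(plate: QpcrPlate, path) -> None:
    plate.data.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# shipped fixtures


def fixture_path(kind: str, contrast_id: str) -> Path:
    """Path of a shipped DE table fixture; kind is 'del' or 'dem'."""
    if kind not in ("del", "dem"):
        raise ValueError(f"kind must be 'del' or 'dem', got {kind!r}")
    if contrast_id not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast_id!r}")
    root = importlib.resources.files("ncnet") / "data"
    return Path(str(root / f"{kind}_{contrast_id}.tsv"))


def load_fixture_contrast(kind: str, contrast_id: str) -> ContrastTable:
    """Load one of the six shipped per-contrast DE tables (DEL or DEM)."""
    return read_contrast_table(fixture_path(kind, contrast_id), contrast_id)


def load_all_fixtures(kind: str) -> dict[str, ContrastTable]:
    """All three contrasts of the shipped DEL or DEM tables."""
    return {c: load_fixture_contrast(kind, c) for c in CONTRASTS}
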