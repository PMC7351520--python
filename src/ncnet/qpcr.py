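"""qPCR relative quantification (2^-ddCt) and validation statistics.

dCt = Ct(target) - Ct(reference assay); ddCt centers dCt on the arithmetic
mean of the control group's dCt (group-mean calibration, not a designated
calibrator sample), and fold = 2^-ddCt. By construction the control group's
folds have geometric mean exactly 1.

Group comparisons use one-way ANOVA followed by Fisher's LSD post hoc:
pairwise t statistics against the control group with the pooled within-group
mean square and its residual degrees of freedom, unadjusted two-sided p, with
significance stars at p <= 0.05 (*) and p <= 0.005 (**). The ANOVA scale is
ddCt (log2 of fold) by default; ``scale="fold"`` analyses the linear folds.

Cross-platform concordance uses Spearman's rank correlation: Pearson on
mid-ranks; the p-value comes from the t approximation on n - 2 degrees of
freedom, replaced by an exact full-permutation enumeration when n <= 8.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ncnet.io import QpcrPlate

__all__ = ["RelativeExpression", "AnovaLsdResult", "ddct_fold", "anova_lsd",
           "spearman_concordance", "stars"]


@dataclass(frozen=True)
class RelativeExpression:
    """Per-sample dCt/ddCt/fold for one assay plus per-group summaries."""

    assay_id: str
    control_group: str
    samples: pd.DataFrame = field(repr=False)   # group, dct, ddct, fold
    groups: pd.DataFrame = field(repr=False)    # mean_fold, sd_fold, n

    def fold_by_group(self) -> dict[str, np.ndarray]:
        return {g: grp["fold"].to_numpy()
                for g, grp in self.samples.groupby("group", sort=False)}

    def ddct_by_group(self) -> dict[str, np.ndarray]:
        return {g: grp["ddct"].to_numpy()
                for g, grp in self.samples.groupby("group", sort=False)}


@dataclass(frozen=True)
class AnovaLsdResult:
    f_statistic: float
    p_omnibus: float
    df_between: int
    df_within: int
    pairwise: pd.DataFrame = field(repr=False)  # group, diff, t, p, stars


def stars(p: float) -> str:
    """Significance marks: ** for p <= 0.005, * for p <= 0.05, else ''."""
    if p <= 0.005:
        return "**"
    if p <= 0.05:
        return "*"
    return ""


def ddct_fold(plate: QpcrPlate, control_group: str = "Nw",
              assay_id: str | None = None) -> RelativeExpression:
    """Relative expression by the 2^-ddCt method for one assay of a plate.

    If the plate holds several assays, ``assay_id`` selects one (mandatory in
    that case). Raises if the control group is absent.
    """
    df = plate.data
    if assay_id is None:
        assays = df["assay_id"].unique()
        if len(assays) != 1:
            raise ValueError(f"plate holds assays {list(assays)}; "
                             "pass assay_id")
        assay_id = assays[0]
    df = df[df["assay_id"] == assay_id].copy()
    if not (df["group"] == control_group).any():
        raise ValueError(f"control group {control_group!r} absent")
    df["dct"] = df["ct_target"] - df["ct_reference"]
    control_mean = df.loc[df["group"] == control_group, "dct"].mean()
    df["ddct"] = df["dct"] - control_mean
    df["fold"] = np.exp2(-df["ddct"])
    samples = df[["sample_id", "group", "dct", "ddct", "fold"]] \
        .set_index("sample_id")
    groups = samples.groupby("group", sort=False)["fold"] \
        .agg(mean_fold="mean", sd_fold="std", n="size")
    return RelativeExpression(assay_id, control_group, samples, groups)


def anova_lsd(values_by_group: Mapping[str, Sequence[float]],
              control_group: str, alpha: float = 0.05) -> AnovaLsdResult:
    """One-way ANOVA with Fisher's LSD post hoc tests against the control.

    Degenerate inputs: identical values everywhere give F = 0, p = 1; zero
    within-group variance with real group differences gives F = inf, p = 0.
    """
    groups = {g: np.asarray(v, dtype=float)
              for g, v in values_by_group.items()}
    if control_group not in groups:
        raise ValueError(f"control group {control_group!r} absent")
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    small = [g for g, v in groups.items() if len(v) < 2]
    if small:
        raise ValueError(f"group(s) with < 2 samples: {small}")

    all_vals = np.concatenate(list(groups.values()))
    grand = all_vals.mean()
    n_total, n_groups = len(all_vals), len(groups)
    ss_between = sum(len(v) * (v.mean() - grand) ** 2
                     for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = n_groups - 1, n_total - n_groups
    if ss_between == 0:
        f_stat, p_omni = 0.0, 1.0
    elif ss_within == 0:
        f_stat, p_omni = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_b) / (ss_within / df_w)
        p_omni = float(stats.f.sf(f_stat, df_b, df_w))

    mse = ss_within / df_w
    ctrl = groups[control_group]
    rows = []
    for g, v in groups.items():
        if g == control_group:
            continue
        diff = v.mean() - ctrl.mean()
        se = math.sqrt(mse * (1 / len(v) + 1 / len(ctrl)))
        if se == 0:
            t = 0.0 if diff == 0 else math.copysign(float("inf"), diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / se
            p = float(2 * stats.t.sf(abs(t), df_w))
        rows.append((g, diff, t, p, stars(p)))
    pairwise = pd.DataFrame(rows, columns=["group", "diff", "t", "p", "stars"])
    return AnovaLsdResult(f_stat, p_omni, df_b, df_w, pairwise)


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rho(x: np.ndarray, y: np.ndarray) -> float:
    rx, ry = _midranks(x), _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt((rx ** 2).sum() * (ry ** 2).sum())
    return float((rx * ry).sum() / denom)


def spearman_concordance(x: Sequence[float], y: Sequence[float],
                         exact_max_n: int = 8) -> tuple[float, float]:
    """Spearman rho and two-sided p between paired measurements.

    rho is the Pearson correlation of mid-ranks (average ranks on ties). For
    n <= exact_max_n the p-value enumerates all n! rank permutations
    (P[|rho_perm| >= |rho_obs|]); otherwise it uses the t approximation with
    n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D sequences")
    n = len(x)
    if n < 3:
        raise ValueError("need >= 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input: rho undefined")
    rho = _rho(x, y)
    if n <= exact_max_n:
        ry = _midranks(y)
        hits = total = 0
        obs = abs(rho) * (1 - 1e-12)
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_rho(_midranks(x), np.asarray(perm))) >= obs:
                hits += 1
        p = hits / total
    else:
        t = rho * math.sqrt((n - 2) / max(1e-300, 1 - rho ** 2))
        p = float(2 * stats.t.sf(abs(t), n - 2))
    return rho, min(1.0, p)
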