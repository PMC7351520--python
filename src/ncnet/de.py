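"""Differential expression on small-RNA count matrices.

The model is the classic conditional negative-binomial (NB) exact test with a
single common dispersion shared across features, applied after low-count
filtering and upper-quartile normalization:

* counts ``Y_fj ~ NB(mean = mu_fg * N_j, dispersion phi)`` for feature f in
  sample j of group g, with ``Var = mu + phi * mu^2``;
* per-sample effective library sizes are equalized by scaling counts to the
  geometric-mean effective size (rounding half-to-even), after which the
  group sums of a feature are themselves NB and the null conditional
  distribution of the group-A sum given the feature total is free of the
  mean — the exact-test analogue of Fisher's test for overdispersed counts;
* two-sided p-values sum the probabilities of all splits no more likely than
  the observed one; at ``phi = 0`` the conditional law is binomial and the
  test reduces to an exact binomial test;
* Benjamini-Hochberg step-up controls FDR across features, and calls are
  thresholded boundary-inclusively (``fdr <= threshold``).

Fold changes are ``log2`` ratios of normalized group mean rates with a small
proportional prior count (default 0.125 per sample) added to numerator and
denominator, so presence/absence features yield large but finite values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.special import gammaln, logsumexp
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CountMatrix", "DeResult", "filter_low_counts", "upper_quartile_factors",
    "equalize_library_sizes", "estimate_common_dispersion", "exact_nb_test",
    "bh_adjust", "call_differential", "run_de",
]

#: proportional prior count per sample used in log2 fold changes
PRIOR_COUNT = 0.125

_REL_TIE_TOL = 1e-12  # relative tolerance when comparing outcome probabilities


@dataclass(frozen=True)
class CountMatrix:
    """Raw integer counts, features x samples, with a sample->group map."""

    counts: pd.DataFrame = field(repr=False)
    sample_groups: Mapping[str, str]

    def __post_init__(self) -> None:
        if self.counts.shape[1] < 2:
            raise ValueError("need >= 2 samples")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.floor(arr)):
                raise ValueError("counts must be integers")
            object.__setattr__(self, "counts", self.counts.astype(np.int64))
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_groups)
        if missing:
            raise ValueError(f"samples without a group: {sorted(missing)}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    @property
    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def group_samples(self, group: str) -> list[str]:
        return [s for s in self.samples if self.sample_groups[s] == group]

    def subset_groups(self, groups: Sequence[str]) -> "CountMatrix":
        keep = [s for s in self.samples if self.sample_groups[s] in groups]
        return CountMatrix(self.counts[keep],
                           {s: self.sample_groups[s] for s in keep})


@dataclass(frozen=True)
class DeResult:
    """Per-feature test results plus the shared nuisance estimates."""

    table: pd.DataFrame = field(repr=False)  # log2fc, p_raw, fdr, call
    dispersion: float
    norm_factors: pd.Series = field(repr=False)

    def called(self) -> pd.DataFrame:
        return self.table[self.table["call"] != "ns"]


def filter_low_counts(m: CountMatrix, min_reads: int = 10) -> CountMatrix:
    """Keep features whose maximum count across samples reaches min_reads."""
    if min_reads < 0:
        raise ValueError("min_reads must be >= 0")
    keep = m.counts.max(axis=1) >= min_reads
    return CountMatrix(m.counts.loc[keep], dict(m.sample_groups))


def upper_quartile_factors(m: CountMatrix, quantile: float = 0.75,
                           library_sizes: pd.Series | None = None) -> pd.Series:
    """Per-sample normalization factors from upper-quartile count rates.

    For each sample j, ``q_j`` is the `quantile`-quantile of its counts over
    the features that are nonzero in at least one sample, divided by the
    library size (column sums unless supplied); the factor is
    ``q_j / geometric_mean(q)``, so the factors have geometric mean 1 and
    dividing each sample's rate by its factor equalizes upper quartiles.
    """
    if library_sizes is None:
        library_sizes = m.library_sizes
    lib = library_sizes.reindex(m.samples).to_numpy(float)
    zero = lib == 0
    if zero.any():
        bad = [s for s, z in zip(m.samples, zero) if z]
        raise ValueError(f"all-zero sample(s): {bad}")
    expressed = m.counts.loc[m.counts.sum(axis=1) > 0]
    q = np.quantile(expressed.to_numpy(float), quantile, axis=0) / lib
    if (q <= 0).any():
        bad = [s for s, v in zip(m.samples, q) if v <= 0]
        raise ValueError(f"zero upper-quartile in sample(s): {bad}; "
                         "raise the quantile or filter features")
    factors = q / np.exp(np.mean(np.log(q)))
    return pd.Series(factors, index=m.samples, name="norm_factor")


def equalize_library_sizes(m: CountMatrix,
                           factors: pd.Series | None = None) -> CountMatrix:
    """Scale counts so every sample has the same effective library size.

    Effective size is ``library_size * factor``; counts are rescaled to the
    geometric mean of effective sizes and rounded half-to-even. The exact
    test's conditioning argument requires this equalization.
    """
    if factors is None:
        factors = upper_quartile_factors(m)
    eff = m.library_sizes.to_numpy(float) * factors.reindex(m.samples).to_numpy(float)
    common = np.exp(np.mean(np.log(eff)))
    scaled = m.counts.to_numpy(float) * (common / eff)[None, :]
    pseudo = np.rint(scaled).astype(np.int64)  # rint = round half-to-even
    return CountMatrix(pd.DataFrame(pseudo, index=m.counts.index,
                                    columns=m.counts.columns),
                       dict(m.sample_groups))


def _group_blocks(m: CountMatrix) -> dict[str, np.ndarray]:
    blocks: dict[str, list[str]] = {}
    for s in m.samples:
        blocks.setdefault(m.sample_groups[s], []).append(s)
    return {g: m.counts[cols].to_numpy(np.int64) for g, cols in blocks.items()}


def _conditional_loglik(phi: float, blocks: Mapping[str, np.ndarray]) -> float:
    """Sum over features/groups of the NB log-likelihood conditional on the
    per-group totals (equal library sizes assumed). phi-free terms dropped."""
    if phi <= 0:
        raise ValueError("phi must be > 0 here")
    r = 1.0 / phi
    total = 0.0
    for y in blocks.values():
        n = y.shape[1]
        z = y.sum(axis=1)
        total += float(
            gammaln(y + r).sum()
            - y.shape[0] * n * gammaln(r)
            + (gammaln(n * r) - gammaln(z + n * r)).sum()
        )
    return total


def estimate_common_dispersion(m: CountMatrix,
                               phi_max: float = 5.0) -> float:
    """Common NB dispersion maximizing the conditional log-likelihood.

    Counts must already have equalized effective library sizes. Returns 0.0
    when the likelihood is maximized at the Poisson boundary (e.g. all
    features constant across samples).
    """
    blocks = _group_blocks(m)
    if len(blocks) < 2:
        raise ValueError("need >= 2 groups")
    small = [g for g, y in blocks.items() if y.shape[1] < 2]
    if len(blocks) - len(small) == 0 or small == list(blocks):
        raise ValueError(
            f"groups with a single replicate only ({small}): dispersion is "
            "not estimable; supply a fixed phi to exact_nb_test")

    lo = 1e-6
    res = minimize_scalar(lambda t: -_conditional_loglik(np.exp(t), blocks),
                          bounds=(np.log(lo), np.log(phi_max)),
                          method="bounded",
                          options={"xatol": 1e-8})
    phi = float(np.exp(res.x))
    # boundary check: treat a maximum at the lower bound as phi = 0
    if phi <= lo * 2.5 and \
            _conditional_loglik(lo, blocks) >= _conditional_loglik(phi, blocks) - 1e-9:
        return 0.0
    return phi


def _exact_p_one(za: int, z: int, na: int, nb: int, phi: float) -> float:
    """Two-sided conditional exact p for one feature.

    Under the null the group-A sum given the total z follows, for phi > 0,
    the NB-conditional law P(x) prop. C(x + na*r - 1, x) C(z - x + nb*r - 1,
    z - x); for phi = 0 it is Binomial(z, na/(na+nb)). The p-value sums the
    probabilities of all splits with probability <= that of the observed one.
    """
    x = np.arange(z + 1)
    if phi == 0:
        logp = (gammaln(z + 1) - gammaln(x + 1) - gammaln(z - x + 1)
                + x * np.log(na / (na + nb)) + (z - x) * np.log(nb / (na + nb)))
    else:
        r = 1.0 / phi
        ra, rb = na * r, nb * r
        logp = (gammaln(x + ra) - gammaln(x + 1)
                + gammaln(z - x + rb) - gammaln(z - x + 1))
        logp -= logsumexp(logp)
    prob = np.exp(logp - logsumexp(logp))
    cutoff = prob[za] * (1.0 + _REL_TIE_TOL)
    return float(min(1.0, prob[prob <= cutoff].sum()))


def exact_nb_test(m: CountMatrix, group_a: str, group_b: str,
                  phi: float, prior_count: float = PRIOR_COUNT) -> pd.DataFrame:
    """Per-feature conditional exact test of group_b vs group_a.

    ``m`` must have equalized effective library sizes (see
    :func:`equalize_library_sizes`). Returns a DataFrame with ``log2fc``
    (positive = higher in group_b) and ``p_raw``.
    """
    if phi < 0:
        raise ValueError("phi must be >= 0")
    groups = set(m.sample_groups.values())
    for g in (group_a, group_b):
        if g not in groups:
            raise ValueError(f"unknown group label {g!r}")
    cols_a = m.group_samples(group_a)
    cols_b = m.group_samples(group_b)
    ya = m.counts[cols_a].to_numpy(np.int64)
    yb = m.counts[cols_b].to_numpy(np.int64)
    na, nb = len(cols_a), len(cols_b)
    za, zb = ya.sum(axis=1), yb.sum(axis=1)

    lfc = np.log2((zb / nb + prior_count) / (za / na + prior_count))
    p = np.ones(len(za))
    for i, (a, b) in enumerate(zip(za, zb)):
        z = int(a + b)
        if z > 0:
            p[i] = _exact_p_one(int(a), z, na, nb, phi)
    return pd.DataFrame({"log2fc": lfc, "p_raw": p}, index=m.counts.index)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(results: pd.DataFrame, threshold: float) -> pd.Series:
    """up/down/ns calls from log2fc sign and fdr <= threshold (inclusive)."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    sig = results["fdr"] <= threshold
    call = np.where(sig & (results["log2fc"] > 0), "up",
                    np.where(sig & (results["log2fc"] < 0), "down", "ns"))
    return pd.Series(call, index=results.index, name="call")


def run_de(m: CountMatrix, group_a: str, group_b: str, *,
           fdr_threshold: float = 0.06, min_reads: int = 10,
           phi: float | None = None) -> DeResult:
    """Full DE pipeline for one contrast: filter, normalize, equalize,
    estimate dispersion (unless given), exact test, BH, calls."""
    sub = m.subset_groups([group_a, group_b])
    sub = filter_low_counts(sub, min_reads)
    if len(sub.features) == 0:
        empty = pd.DataFrame(columns=["log2fc", "p_raw", "fdr", "call"])
        return DeResult(empty, phi or 0.0,
                        pd.Series(1.0, index=sub.samples))
    factors = upper_quartile_factors(sub)
    eq = equalize_library_sizes(sub, factors)
    if phi is None:
        phi = estimate_common_dispersion(eq)
    table = exact_nb_test(eq, group_a, group_b, phi)
    table["fdr"] = bh_adjust(table["p_raw"].to_numpy())
    table["call"] = call_differential(table, fdr_threshold)
    return DeResult(table, phi, factors)
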