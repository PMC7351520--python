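"""Two-sided hypergeometric over-representation analysis with BH correction,
direction fractions and Cohen's-kappa term grouping.

For a query of n genes drawn from an N-gene universe and a term covering K
universe genes, the overlap k is tested two-sidedly by doubling the smaller
hypergeometric tail (capped at 1): enrichment and depletion are both
detectable, matching a "two-sided enrichment" setting. Significance is
declared on the BH-adjusted p at strict ``p_adj < alpha``.

Significant terms are then clustered by pairwise Cohen's kappa of their
binary overlap-membership vectors over the query, joining pairs with
kappa >= a cutoff (default 0.4) and taking connected components as groups —
a flat re-implementation of the kappa-score grouping popularized by
ClueGO-style enrichment tools (without GO-tree leveling or term fusion).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ncnet.de import bh_adjust
from ncnet.io import GeneSetCollection

__all__ = ["hypergeom_two_sided", "enrich_collection", "kappa_group_terms",
           "cohens_kappa"]


def hypergeom_two_sided(k: int, K: int, n: int, N: int) -> float:
    """Two-sided hypergeometric p: 2 * min(P[X >= k], P[X <= k]), capped at 1.

    X ~ Hypergeometric(N, K, n): overlap of a size-n draw with a size-K
    category in an N-element universe.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"need 0 <= K,n <= N; got K={K}, n={n}, N={N}")
    if not (max(0, K + n - N) <= k <= min(K, n)):
        raise ValueError(f"k={k} outside support [{max(0, K + n - N)}, "
                         f"{min(K, n)}] for K={K}, n={n}, N={N}")
    dist = hypergeom(N, K, n)
    upper = float(dist.sf(k - 1))   # P[X >= k]
    lower = float(dist.cdf(k))      # P[X <= k]
    return min(1.0, 2.0 * min(upper, lower))


def enrich_collection(query: Mapping[str, str], universe: frozenset | set,
                      terms: GeneSetCollection, alpha: float = 0.05
                      ) -> pd.DataFrame:
    """Test every term of a collection against a direction-annotated query.

    ``query`` maps gene -> direction (up/down/mixed) and must be a subset of
    ``universe``. Term members are intersected with the universe before
    testing; terms empty after intersection are skipped. Returns one row per
    tested term: term_id, term_name, k, K, n, N, p, p_adj,
    direction_fraction_up (NaN when k = 0), significant (p_adj < alpha,
    strict) and overlap_genes, sorted by p_adj then term_id.
    """
    qset = set(query)
    stray = qset - set(universe)
    if stray:
        raise ValueError(f"query genes outside universe: {sorted(stray)[:5]}")
    N, n = len(universe), len(qset)
    rows = []
    for tid, members in terms.sets.items():
        in_universe = members & set(universe)
        K = len(in_universe)
        if K == 0:
            continue
        overlap = sorted(in_universe & qset)
        k = len(overlap)
        p = hypergeom_two_sided(k, K, n, N)
        n_up = sum(query[g] == "up" for g in overlap)
        frac_up = n_up / k if k else float("nan")
        rows.append((tid, terms.names.get(tid, tid), k, K, n, N, p, frac_up,
                     tuple(overlap)))
    if not rows:
        return pd.DataFrame(columns=["term_id", "term_name", "k", "K", "n",
                                     "N", "p", "p_adj",
                                     "direction_fraction_up", "significant",
                                     "overlap_genes"])
    df = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n",
                                     "N", "p", "direction_fraction_up",
                                     "overlap_genes"])
    df["p_adj"] = bh_adjust(df["p"].to_numpy())
    df["significant"] = df["p_adj"] < alpha
    df = df[["term_id", "term_name", "k", "K", "n", "N", "p", "p_adj",
             "direction_fraction_up", "significant", "overlap_genes"]]
    return df.sort_values(["p_adj", "term_id"]).reset_index(drop=True)


def cohens_kappa(members_a: frozenset | set, members_b: frozenset | set,
                 query: frozenset | set) -> float:
    """Cohen's kappa between two binary membership vectors over the query."""
    m = len(query)
    if m == 0:
        raise ValueError("empty query")
    both = sum((g in members_a) and (g in members_b) for g in query)
    only_a = sum((g in members_a) and (g not in members_b) for g in query)
    only_b = sum((g not in members_a) and (g in members_b) for g in query)
    neither = m - both - only_a - only_b
    po = (both + neither) / m
    pa, pb = (both + only_a) / m, (both + only_b) / m
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        return 1.0  # identical constant vectors agree perfectly
    return (po - pe) / (1 - pe)


def kappa_group_terms(results: pd.DataFrame,
                      membership: Mapping[str, frozenset | set],
                      query: frozenset | set,
                      kappa_min: float = 0.4) -> pd.Series:
    """Group significant terms by connected components of the kappa graph.

    ``membership`` maps term_id -> overlap gene set. Pairs of significant
    terms with kappa >= kappa_min are joined; each group is named after its
    representative, the member with the smallest p_adj (ties: smallest
    term_id). Returns term_id -> group_id for the significant terms.
    """
    if not 0 <= kappa_min <= 1:
        raise ValueError("kappa_min must be in [0, 1]")
    sig = results.loc[results["significant"], ["term_id", "p_adj"]]
    tids = list(sig["term_id"])
    g = nx.Graph()
    g.add_nodes_from(tids)
    for i, ta in enumerate(tids):
        for tb in tids[i + 1:]:
            if cohens_kappa(membership[ta], membership[tb], query) >= kappa_min:
                g.add_edge(ta, tb)
    p_of = dict(zip(sig["term_id"], sig["p_adj"]))
    assignment: dict[str, str] = {}
    for comp in nx.connected_components(g):
        rep = min(comp, key=lambda t: (p_of[t], t))
        for t in comp:
            assignment[t] = rep
    return pd.Series(assignment, name="group_id")
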