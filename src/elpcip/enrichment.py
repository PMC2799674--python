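"""Category over-representation of a query gene set against an annotated background.

The statistic is the one-sided hypergeometric upper tail (Fisher's exact
test for enrichment) with Benjamini-Hochberg FDR across the categories of
one aspect.  Annotations are taken as provided: no ontology-graph
propagation is performed, so the universe is exactly the annotated items
of the requested aspect.
"""

from __future__ import annotations

from typing import Iterable

import pandas as pd
from scipy import stats

from .anova import bh_fdr
from .io import FormatError

__all__ = ["hypergeometric_tail", "enrich"]


def hypergeometric_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes, n draws)."""
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"impossible counts: k={k}, n={n}, K={K}, N={N}")
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"impossible counts: k={k}, n={n}, K={K}, N={N}")
    if k == 0:
        return 1.0
    # survival function at k-1; scipy computes the mass in log space
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    annotations: pd.DataFrame,
    aspect: str,
    min_category_size: int = 1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` items per category.

    The background universe N is the set of items annotated in ``aspect``;
    the effective query size n is the query's overlap with that universe.
    Returns a DataFrame sorted by ascending p with columns category_id,
    aspect, query_count, query_total, background_count, background_total,
    p_value, q_value.
    """
    ann = annotations.loc[annotations["aspect"] == aspect]
    universe = set(ann["item_id"])
    if not universe:
        raise FormatError(f"no items annotated for aspect {aspect!r}")
    query_set = set(query) & universe
    N = len(universe)
    n = len(query_set)
    rows = []
    for category_id, members_df in ann.groupby("category_id"):
        members = set(members_df["item_id"])
        K = len(members)
        if K < min_category_size:
            continue
        k = len(query_set & members)
        rows.append(
            {
                "category_id": category_id,
                "aspect": aspect,
                "query_count": k,
                "query_total": n,
                "background_count": K,
                "background_total": N,
                "p_value": hypergeometric_tail(k, n, K, N),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "category_id",
            "aspect",
            "query_count",
            "query_total",
            "background_count",
            "background_total",
            "p_value",
        ],
    )
    if len(out):
        out["q_value"] = bh_fdr(out["p_value"].to_numpy())
        out = out.sort_values(
            ["p_value", "category_id"], kind="stable", ignore_index=True
        )
    else:
        out["q_value"] = []
    return out
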