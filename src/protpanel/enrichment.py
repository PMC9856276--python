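"""Hypergeometric over-representation analysis (ORA).

Tests whether a query protein list overlaps a named protein set more than
chance would predict given a finite universe: with ``M`` universe
proteins, ``K`` of them in the set, a query of size ``n`` and overlap
``k``, the p-value is the upper tail ``P(X >= k)`` of the hypergeometric
distribution.  Benjamini-Hochberg adjustment is applied across the tested
sets.  The recommended universe is the set of assays that passed QC on
the relevant panel, not the whole proteome.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneSetCollection
from .diffexpr import bh_adjust


class EnrichmentError(ValueError):
    pass


def hypergeom_tail(M: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail ``P(X >= k)`` for X ~ Hypergeometric(M, K, n)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, M, K, n))


def ora(
    query: Iterable[str],
    universe: Iterable[str],
    collection: GeneSetCollection,
    min_overlap: int = 1,
    min_set_size: int = 3,
) -> pd.DataFrame:
    """Over-representation of a query list in each gene set.

    Query proteins outside the universe are dropped (and counted in the
    ``n_query_dropped`` attribute of the result).  Sets are intersected
    with the universe before testing; sets smaller than ``min_set_size``
    or overlapping the query by less than ``min_overlap`` are not tested.
    Columns: set_name, k (overlap), K (set size), n (query size),
    M (universe size), p, p_adj.
    """
    uni = {str(u) for u in universe}
    if not uni:
        raise EnrichmentError("empty universe")
    query_all = [str(q) for q in query]
    query_set = {q for q in query_all if q in uni}
    n_dropped = len(set(query_all)) - len(query_set)
    M, n = len(uni), len(query_set)

    rows = []
    for name in collection.names():
        members = set(collection[name]) & uni
        K = len(members)
        if K == 0 or K < min_set_size:
            continue
        k = len(members & query_set)
        if k < min_overlap:
            continue
        rows.append({
            "set_name": name, "k": k, "K": K, "n": n, "M": M,
            "p": hypergeom_tail(M, K, n, k),
        })
    result = pd.DataFrame(rows, columns=["set_name", "k", "K", "n", "M", "p"])
    if len(result):
        result["p_adj"] = bh_adjust(result["p"].to_numpy())
        result = result.sort_values(
            ["p_adj", "p", "set_name"]
        ).reset_index(drop=True)
    else:
        result["p_adj"] = []
    result.attrs["n_query_dropped"] = n_dropped
    return result
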