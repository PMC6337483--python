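"""Hypergeometric over-representation of gene sets and immune-term annotation.

For a universe of N genes, a set with K members in the universe, and a
differential list of n genes overlapping the set in k genes, the
enrichment p-value is the upper tail

    P(X >= k),   X ~ Hypergeometric(N, K, n)

computed by exact summation of log-space binomial coefficients. One
Benjamini-Hochberg family covers all tested sets of a collection;
significance is adjusted p < 0.05 by default.

Immune annotation is deliberately database-free: a case-insensitive
pattern (default ``immune``) is matched against set names of a
user-supplied GMT collection, and every differential gene belonging to a
matching set is returned with its matched term names.
"""

from __future__ import annotations

import logging
import re
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from ddipipe.deg import adjust_bh
from ddipipe.io import GeneSetCollection

logger = logging.getLogger(__name__)


def _log_binom(n: float, k: np.ndarray) -> np.ndarray:
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    ``N``: universe size, ``K``: set size within the universe, ``n``: number
    of draws (differential genes), ``k``: observed overlap.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1, dtype=float)
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, np.array(float(n)))
    return float(min(1.0, np.exp(logsumexp(log_terms))))


def enrich(
    degs: Iterable[str],
    collection: GeneSetCollection,
    universe: Iterable[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Over-representation table: one row per gene set with K > 0 in the universe.

    Differential genes outside the universe are dropped and logged. Columns:
    ``set``, ``K``, ``n``, ``k``, ``N``, ``p``, ``p_adj``, ``significant``,
    ``overlap_genes``; rows sorted by (p_adj, p, set name). An empty
    differential list yields an empty table with a warning.
    """
    universe_set = set(universe)
    if not universe_set:
        raise ValueError("universe must be non-empty")
    deg_set = set(degs)
    outside = deg_set - universe_set
    if outside:
        logger.warning(
            "dropping %d differential gene(s) outside the universe", len(outside)
        )
        deg_set -= outside
    if not deg_set:
        logger.warning("empty differential gene list; returning empty table")
        return _empty_table()
    N, n = len(universe_set), len(deg_set)
    rows = []
    for name in collection:
        members = collection.members(name) & universe_set
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(members & deg_set)
        k = len(overlap)
        rows.append(
            {
                "set": name,
                "K": K,
                "n": n,
                "k": k,
                "N": N,
                "p": hypergeom_upper(k, K, n, N),
                "overlap_genes": ",".join(overlap),
            }
        )
    if not rows:
        return _empty_table()
    table = pd.DataFrame(rows)
    table["p_adj"] = adjust_bh(table["p"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    table = table.sort_values(by=["p_adj", "p", "set"], kind="mergesort").reset_index(drop=True)
    return table[["set", "K", "n", "k", "N", "p", "p_adj", "significant", "overlap_genes"]]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["set", "K", "n", "k", "N", "p", "p_adj", "significant", "overlap_genes"]
    )


def annotate_immune(
    degs: Iterable[str], collection: GeneSetCollection, pattern: str = "immune"
) -> dict[str, list[str]]:
    """Map each differential gene to the immune-named sets that contain it.

    ``pattern`` is a case-insensitive regular expression searched in set
    names. Genes in no matching set are omitted; an empty result (or no
    matching set names at all) is returned with a warning.
    """
    rx = re.compile(pattern, re.IGNORECASE)
    matching = [name for name in collection if rx.search(name)]
    if not matching:
        logger.warning("no set name matches pattern %r", pattern)
        return {}
    out: dict[str, list[str]] = {}
    deg_list = sorted(set(degs))
    for gene in deg_list:
        terms = [name for name in matching if gene in collection.members(name)]
        if terms:
            out[gene] = terms
    if not out:
        logger.warning("no differential gene belongs to a set matching %r", pattern)
    return out
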