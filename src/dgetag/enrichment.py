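"""Hypergeometric over-representation tests with BH and Storey corrections.

For a query gene set of size n drawn from a universe of N genes of which K
carry a term, the enrichment p-value is the upper tail P(X >= k) of the
hypergeometric(N, K, n) distribution. Multiple terms are corrected two ways:
Benjamini-Hochberg FDR values and Storey q-values with the fixed-lambda
plug-in estimate of pi0 (the proportion of true nulls).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .de import bh_adjust

DEFAULT_LAMBDA = 0.5


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ hypergeometric(N population, K marked, n drawn)."""
    if not (0 <= k <= n <= N and 0 <= K <= N):
        raise ValueError(f"invalid hypergeometric bounds k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def storey_qvalues(
    p_values, lambda_: float = DEFAULT_LAMBDA
) -> tuple[np.ndarray, float]:
    """Storey q-values with the fixed-lambda plug-in pi0 estimate.

    pi0 = min(1, #{p > lambda} / (m * (1 - lambda))); q-values follow the BH
    step-up scaled by pi0. When every p-value is <= lambda, pi0 is undefined
    and falls back to 1 with a warning (q-values then equal BH FDR values).
    """
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 <= lambda_ < 1:
        raise ValueError("lambda_ must lie in [0, 1)")
    m = p.size
    if m == 0:
        return p, 1.0
    n_above = int((p > lambda_).sum())
    if n_above == 0:
        warnings.warn(
            "no p-values above lambda; pi0 undefined, falling back to pi0=1",
            stacklevel=2,
        )
        pi0 = 1.0
    else:
        pi0 = min(1.0, n_above / (m * (1.0 - lambda_)))
    order = np.argsort(p, kind="stable")
    ranked = p[order] * pi0 * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q, pi0


def read_annotation(path) -> dict[str, set[str]]:
    """Two-column TSV (gene_id, term_id) -> gene -> set of terms."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "term_id"], comment="#")
    out: dict[str, set[str]] = {}
    for gid, term in zip(df["gene_id"], df["term_id"]):
        out.setdefault(str(gid), set()).add(str(term))
    return out


def enrich(
    query_genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe_genes: Iterable[str],
    method: str = "BH",
    lambda_: float = DEFAULT_LAMBDA,
    term_names: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Term over-representation of a query gene set against a universe.

    ``annotation`` maps gene -> terms. Query genes outside the universe are
    dropped with a warning; duplicated ids count once. One row per term with
    at least one query gene; both BH FDR and Storey q-values are computed,
    and the ``significance_value`` column follows ``method`` ("BH" or
    "storey"). Sorted by p-value.
    """
    universe = set(universe_genes)
    if not universe:
        raise ValueError("empty universe")
    if method not in ("BH", "storey"):
        raise ValueError("method must be 'BH' or 'storey'")
    query = set(query_genes)
    outside = query - universe
    if outside:
        warnings.warn(
            f"{len(outside)} query genes outside the universe were dropped",
            stacklevel=2,
        )
        query &= universe

    by_term: dict[str, set[str]] = {}
    for gene in universe:
        for term in annotation.get(gene, ()):
            by_term.setdefault(term, set()).add(gene)

    n = len(query)
    N = len(universe)
    rows = []
    for term, members in sorted(by_term.items()):
        K = len(members)
        k = len(members & query)
        if K == 0 or k == 0:
            continue
        rows.append(
            {
                "term_id": term,
                "term_name": (term_names or {}).get(term, ""),
                "K": K,
                "n": n,
                "k": k,
                "N": N,
                "p_value": hypergeom_upper_tail(k, K, n, N),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "term_name", "K", "n", "k", "N", "p_value"]
    )
    if len(result):
        result["fdr"] = bh_adjust(result["p_value"].to_numpy())
        q, pi0 = storey_qvalues(result["p_value"].to_numpy(), lambda_)
        result["q_value"] = q
        result["pi0"] = pi0
        result["significance_value"] = (
            result["fdr"] if method == "BH" else result["q_value"]
        )
        result = result.sort_values("p_value", kind="stable").reset_index(drop=True)
    return result
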