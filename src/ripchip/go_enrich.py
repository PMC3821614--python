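"""GO Biological Process over-representation by hypergeometric test.

For each term, k of the n annotated target genes fall in the term against
K of the N universe genes; the upper-tail hypergeometric probability
P[X >= k] scores the over-representation, reported alongside the "k/K"
enrichment ratio.  No multiple-testing correction is applied beyond the
fixed p cutoff; annotations are taken as given per GMT line (no DAG
propagation).
"""
from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd
import scipy.stats

from .io import Thresholds, write_records

logger = logging.getLogger(__name__)

__all__ = ["hypergeom_upper_tail", "enrich_terms", "write_go_table"]

MIN_TERM_SIZE = 2  # singleton terms give unstable p and are dropped


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] for X ~ Hypergeometric(N, K, n).

    k = term hits in the gene list, K = term size in the universe,
    n = list size, N = universe size.
    """
    if not (0 <= k <= min(K, n) and K <= N and n <= N):
        raise ValueError(
            f"invalid hypergeometric arguments k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(scipy.stats.hypergeom.sf(k - 1, N, K, n))


def enrich_terms(
    target_genes: set[str],
    gene_sets: Mapping[str, tuple[str, frozenset[str]]],
    universe: set[str],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Score every gene set against a target list within a universe.

    Gene sets are intersected with the universe before counting; terms
    with fewer than two universe members are dropped.  Results are sorted
    by ascending p (ties by term id) and flagged significant at
    p < go_alpha.
    """
    if not universe:
        raise ValueError("empty universe")
    targets = set(target_genes) & set(universe)
    if targets != set(target_genes):
        stray = set(target_genes) - set(universe)
        raise ValueError(
            f"target genes outside the universe: {sorted(stray)[:5]}"
        )
    N = len(universe)
    n = len(targets)
    rows = []
    for term_id in sorted(gene_sets):
        name, members = gene_sets[term_id]
        in_universe = members & universe
        K = len(in_universe)
        if K == 0:
            continue
        if K < MIN_TERM_SIZE:
            logger.info("term %s has %d universe member(s); dropped", term_id, K)
            continue
        k = len(in_universe & targets)
        p = hypergeom_upper_tail(k, K, n, N)
        rows.append(
            {
                "term_id": term_id,
                "term_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
                "ratio_label": f"{k}/{K}",
                "significant": p < thresholds.go_alpha,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "term_id", "term_name", "k", "K", "n", "N",
            "p_value", "ratio_label", "significant",
        ],
    )
    return table.sort_values(
        ["p_value", "term_id"], kind="mergesort"
    ).reset_index(drop=True)


def write_go_table(table: pd.DataFrame, path) -> None:
    """Write the over-representation table (GO annotation, p-value,
    enrichment k/K), most significant first."""
    out = table[["term_id", "term_name", "p_value", "ratio_label", "significant"]]
    write_records(out, path, sort_by=["p_value", "term_id"])
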