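"""Cross-genotype comparison of RNP target sets.

Three views of how the loss of one RNA-binding protein reshapes the other
protein's RNP cargo: a Venn partition of the two genotypes' target sets,
a per-gene KO/WT ratio-of-enrichments classification (an "unchanged" band
around 1 separating increased from reduced association), and a
hierarchical clustering of log2 enrichments for heat-map ordering.

Ratios are computed for every gene in the union of the target sets using
each genotype's enrichment even when it is sub-threshold there; only genes
failing detection in a genotype get a one-sided class (wt_only / ko_only)
and an undefined ratio.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch

from .io import Thresholds, write_records

__all__ = [
    "VennPartition",
    "partition_venn",
    "ratio_of_enrichments",
    "ClusterResult",
    "hierarchical_cluster",
    "write_association_table",
]


@dataclass(frozen=True)
class VennPartition:
    common: frozenset[str]
    wt_exclusive: frozenset[str]
    ko_exclusive: frozenset[str]
    wt_exclusive_pct: int  # |wt_exclusive| / |WT| * 100, nearest integer
    ko_exclusive_pct: int
    union_size: int


def _pct(numerator: int, denominator: int) -> int:
    if denominator == 0:
        return 0
    return int(np.floor(100.0 * numerator / denominator + 0.5))


def partition_venn(targets_wt: set[str], targets_ko: set[str]) -> VennPartition:
    """Exact set partition of two target lists with exclusive-percentage
    bookkeeping (share of each genotype's own set, rounded to integer)."""
    wt, ko = set(targets_wt), set(targets_ko)
    common = wt & ko
    wt_ex = wt - ko
    ko_ex = ko - wt
    return VennPartition(
        common=frozenset(common),
        wt_exclusive=frozenset(wt_ex),
        ko_exclusive=frozenset(ko_ex),
        wt_exclusive_pct=_pct(len(wt_ex), len(wt)),
        ko_exclusive_pct=_pct(len(ko_ex), len(ko)),
        union_size=len(wt | ko),
    )


def classify_ratio(ratio: float, band: tuple[float, float]) -> str:
    """Band classification of a KO/WT enrichment ratio; the band is closed,
    so a ratio exactly on a boundary counts as unchanged."""
    lo, hi = band
    if np.isnan(ratio):
        return "undefined"
    if ratio > hi:
        return "increased"
    if ratio < lo:
        return "reduced"
    return "unchanged"


def ratio_of_enrichments(
    records: pd.DataFrame,
    targets_wt: set[str],
    targets_ko: set[str],
    thresholds: Thresholds = Thresholds(),
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-gene association records over the union of the target sets.

    ``records`` is the combined enrichment table (both genotypes, columns
    gene_symbol / genotype / enrichment / detected).  Returns the record
    table and the band census {unchanged, increased, reduced, wt_only,
    ko_only}.
    """
    union = sorted(set(targets_wt) | set(targets_ko))
    venn = partition_venn(targets_wt, targets_ko)
    wide = records.pivot_table(
        index="gene_symbol", columns="genotype", values="enrichment", aggfunc="first"
    )
    det = (
        records.pivot_table(
            index="gene_symbol", columns="genotype", values="detected", aggfunc="first"
        )
        if "detected" in records.columns
        else pd.DataFrame(True, index=wide.index, columns=wide.columns)
    )
    rows = []
    for gene in union:
        enr_wt = float(wide.at[gene, "WT"]) if "WT" in wide.columns and gene in wide.index else np.nan
        enr_ko = float(wide.at[gene, "KO"]) if "KO" in wide.columns and gene in wide.index else np.nan
        det_wt = bool(det.at[gene, "WT"]) if gene in det.index and "WT" in det.columns else False
        det_ko = bool(det.at[gene, "KO"]) if gene in det.index and "KO" in det.columns else False
        measurable_wt = det_wt and np.isfinite(enr_wt) and enr_wt > 0
        measurable_ko = det_ko and np.isfinite(enr_ko) and enr_ko > 0
        if measurable_wt and measurable_ko:
            ratio = enr_ko / enr_wt
            assoc = classify_ratio(ratio, thresholds.association_band)
        elif measurable_wt:
            ratio, assoc = np.nan, "wt_only"
        elif measurable_ko:
            ratio, assoc = np.nan, "ko_only"
        else:
            ratio, assoc = np.nan, "undefined"
        if gene in venn.common:
            venn_class = "common"
        elif gene in venn.wt_exclusive:
            venn_class = "wt_exclusive"
        else:
            venn_class = "ko_exclusive"
        rows.append(
            {
                "gene_symbol": gene,
                "enr_wt": enr_wt if measurable_wt else np.nan,
                "enr_ko": enr_ko if measurable_ko else np.nan,
                "ratio": ratio,
                "assoc_class": assoc,
                "venn": venn_class,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=["gene_symbol", "enr_wt", "enr_ko", "ratio", "assoc_class", "venn"],
    )
    census = {
        cls: int((table["assoc_class"] == cls).sum())
        for cls in ("unchanged", "increased", "reduced", "wt_only", "ko_only")
    }
    return table, census


@dataclass
class ClusterResult:
    order: list[str]  # leaf order, for heat-map rows
    linkage: np.ndarray  # scipy linkage matrix (empty for < 2 rows)
    ordered_values: pd.DataFrame


def hierarchical_cluster(values: pd.DataFrame) -> ClusterResult:
    """Agglomerative clustering of genes (rows) for heat-map ordering.

    Euclidean distance, average linkage; rows are pre-sorted by symbol so
    the leaf order is deterministic under ties.  Undefined entries must be
    imputed by the caller (the pipeline uses 0 = ratio-neutral log2
    enrichment).
    """
    frame = values.sort_index(kind="mergesort")
    if frame.shape[0] < 2:
        return ClusterResult(list(frame.index), np.empty((0, 4)), frame.copy())
    linkage = sch.linkage(frame.to_numpy(dtype=float), method="average", metric="euclidean")
    leaves = sch.leaves_list(linkage)
    order = [frame.index[i] for i in leaves]
    return ClusterResult(order, linkage, frame.iloc[leaves].copy())


def write_association_table(
    table: pd.DataFrame, path, definitions: pd.Series | None = None
) -> None:
    """Write the ratio-of-enrichments table, largest ratio first,
    one-sided classes last."""
    out = table.copy()
    out["definition"] = (
        definitions.reindex(out["gene_symbol"]).fillna("").to_numpy()
        if definitions is not None
        else ""
    )
    out = out[["gene_symbol", "definition", "enr_wt", "enr_ko", "ratio", "assoc_class", "venn"]]
    out["_ratio_sort"] = out["ratio"].fillna(-np.inf)
    out = out.sort_values(
        ["_ratio_sort", "gene_symbol"], ascending=[False, True], kind="mergesort"
    ).drop(columns="_ratio_sort")
    write_records(out, path)
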