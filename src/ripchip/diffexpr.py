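"""Differential expression of total nuclear RNA between genotypes.

Per gene the KO total-fraction replicates are tested against the WT total
replicates (pooled t), q-values are assigned across all tested genes, and
the linear fold change of the means decides direction.  A gene is called
only when raw p, q and fold all clear their thresholds; "up" means
KO above WT.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Fraction, Genotype, StudyDesign, Thresholds, write_records
from .preprocess import GeneMatrix
from .stats import bh_fdr, t_test_rows

__all__ = ["DiffExprSummary", "call_differential_expression", "write_diffexpr_table"]


@dataclass(frozen=True)
class DiffExprSummary:
    n_total: int
    n_up: int
    n_down: int

    def __post_init__(self) -> None:
        assert self.n_total == self.n_up + self.n_down


def call_differential_expression(
    g: GeneMatrix, design: StudyDesign, thresholds: Thresholds = Thresholds()
) -> tuple[pd.DataFrame, DiffExprSummary]:
    """Call KO-vs-WT differential expression on the TOTAL fraction.

    Returns a per-gene record table (gene_symbol, fold, direction, p_value,
    q_value, status) plus summary counts; n_total = n_up + n_down by
    construction.
    """
    ko_ids = design.select(Genotype.KO, Fraction.TOTAL)
    wt_ids = design.select(Genotype.WT, Fraction.TOTAL)
    for name, ids in (("KO", ko_ids), ("WT", wt_ids)):
        if len(ids) < 2:
            raise ValueError(
                f"{name} TOTAL fraction has {len(ids)} replicate(s); need >= 2"
            )
    ko = g.log2_values[ko_ids].to_numpy()
    wt = g.log2_values[wt_ids].to_numpy()
    stat, p = t_test_rows(ko, wt)
    q = bh_fdr(p)
    diff = ko.mean(axis=1) - wt.mean(axis=1)
    linear = 2.0 ** np.abs(diff)
    direction = np.where(diff >= 0, "up", "down")
    significant = (
        (p < thresholds.test_alpha)
        & (q < thresholds.fdr_alpha)
        & (linear > thresholds.fold_change_min)
    )
    status = np.where(
        ~significant,
        "not_significant",
        np.where(direction == "up", "up_regulated", "down_regulated"),
    )
    records = pd.DataFrame(
        {
            "gene_symbol": g.gene_symbols,
            "fold": linear,
            "direction": direction,
            "p_value": p,
            "q_value": q,
            "status": status,
        }
    ).reset_index(drop=True)
    n_up = int((records["status"] == "up_regulated").sum())
    n_down = int((records["status"] == "down_regulated").sum())
    return records, DiffExprSummary(n_total=n_up + n_down, n_up=n_up, n_down=n_down)


def write_diffexpr_table(
    records: pd.DataFrame, path, definitions: pd.Series | None = None
) -> None:
    """Write the priority-list table (gene, definition, p-value, fold
    increase/decrease), most changed first."""
    out = records[records["status"] != "not_significant"].copy()
    out["definition"] = (
        definitions.reindex(out["gene_symbol"]).fillna("").to_numpy()
        if definitions is not None
        else ""
    )
    out = out[["gene_symbol", "definition", "p_value", "fold", "direction", "status"]]
    write_records(out, path, sort_by=["fold", "gene_symbol"], ascending=[False, True])
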