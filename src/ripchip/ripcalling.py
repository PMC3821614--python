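"""IP-vs-total enrichment and RNP target calling.

The core statistic of a RIP-Chip experiment: per gene and genotype, the
enrichment is the relative abundance of the transcript in the
immunoprecipitate compared with its level in total nuclear RNA, realized
on the preprocessed scale as 2^(mean log2 IP - mean log2 TOTAL).  A gene
is a target of the RNP complex in a genotype when it is detected there,
its IP-vs-total t-test clears the raw-p and FDR thresholds, and its
enrichment strictly exceeds the fold cutoff.  The two genotypes' IP
analyses are independent experiments, so q-values are assigned within
genotype.

A housekeeping negative control (Gapdh) is expected to ride along only as
a low contaminant: its enrichment must stay below the fold cutoff in every
genotype.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Fraction, Genotype, StudyDesign, Thresholds, write_records
from .preprocess import GeneMatrix, gene_detection_by_genotype
from .stats import bh_fdr, t_test_rows

__all__ = [
    "TargetSummary",
    "compute_enrichment",
    "call_targets",
    "call_rip_targets",
    "negative_control_check",
    "write_enrichment_table",
]


@dataclass(frozen=True)
class TargetSummary:
    genotype: str
    n_targets: int
    n_high: int  # targets above the high-enrichment cutoff
    platform_fraction_pct: float | None  # % of platform transcripts, 1 decimal


def compute_enrichment(
    g: GeneMatrix, design: StudyDesign, genotype: Genotype | str
) -> pd.DataFrame:
    """Per-gene IP-vs-total enrichment and test statistics for one genotype.

    Returns columns gene_symbol, genotype, enrichment (linear),
    log2_enrichment, statistic, p_value.
    """
    geno = Genotype(genotype)
    ip_ids = design.select(geno, Fraction.IP)
    total_ids = design.select(geno, Fraction.TOTAL)
    for frac, ids in ((Fraction.IP, ip_ids), (Fraction.TOTAL, total_ids)):
        if len(ids) < 2:
            raise ValueError(
                f"genotype {geno.value} fraction {frac.value} has "
                f"{len(ids)} replicate(s); need >= 2"
            )
    ip = g.log2_values[ip_ids].to_numpy()
    total = g.log2_values[total_ids].to_numpy()
    stat, p = t_test_rows(ip, total)
    log2_enr = ip.mean(axis=1) - total.mean(axis=1)
    return pd.DataFrame(
        {
            "gene_symbol": g.gene_symbols,
            "genotype": geno.value,
            "enrichment": 2.0**log2_enr,
            "log2_enrichment": log2_enr,
            "statistic": stat,
            "p_value": p,
        }
    ).reset_index(drop=True)


def call_targets(
    records: pd.DataFrame,
    thresholds: Thresholds = Thresholds(),
    detected: pd.Series | None = None,
    platform_size: int | None = None,
    high_fold: float = 4.0,
) -> tuple[pd.DataFrame, TargetSummary]:
    """Flag targets among one genotype's enrichment records.

    Assigns q-values (BH across the genotype's genes), applies the target
    rule (detected AND p < test_alpha AND q < fdr_alpha AND enrichment
    strictly > fold_change_min) and summarizes: target count, count above
    ``high_fold`` enrichment, and — when the platform transcript count is
    given — the targets' share of the platform as a one-decimal percent.
    """
    genotypes = records["genotype"].unique()
    if len(genotypes) != 1:
        raise ValueError("call_targets expects records of a single genotype")
    out = records.copy()
    out["q_value"] = bh_fdr(out["p_value"].to_numpy())
    if detected is None:
        det = np.ones(len(out), dtype=bool)
    else:
        det = detected.reindex(out["gene_symbol"]).fillna(False).to_numpy(dtype=bool)
    out["detected"] = det
    out["is_target"] = (
        det
        & (out["p_value"] < thresholds.test_alpha)
        & (out["q_value"] < thresholds.fdr_alpha)
        & (out["enrichment"] > thresholds.fold_change_min)
    )
    n_targets = int(out["is_target"].sum())
    n_high = int((out["is_target"] & (out["enrichment"] > high_fold)).sum())
    pct = (
        round(100.0 * n_targets / platform_size, 1)
        if platform_size is not None
        else None
    )
    summary = TargetSummary(
        genotype=str(genotypes[0]),
        n_targets=n_targets,
        n_high=n_high,
        platform_fraction_pct=pct,
    )
    return out, summary


def call_rip_targets(
    g: GeneMatrix,
    design: StudyDesign,
    thresholds: Thresholds = Thresholds(),
    platform_size: int | None = None,
    high_fold: float = 4.0,
) -> tuple[pd.DataFrame, dict[str, TargetSummary]]:
    """Run enrichment + target calling for every genotype in the design.

    A gene failing the detection rule restricted to one genotype's two
    fractions is never a target there but stays eligible in the other
    genotype (the absent-in-one-genotype case).
    """
    detection = gene_detection_by_genotype(g, design, thresholds.detection_alpha)
    frames = []
    summaries: dict[str, TargetSummary] = {}
    for geno in design.genotypes():
        records = compute_enrichment(g, design, geno)
        called, summary = call_targets(
            records,
            thresholds,
            detected=detection[geno.value],
            platform_size=platform_size,
            high_fold=high_fold,
        )
        frames.append(called)
        summaries[geno.value] = summary
    return pd.concat(frames, ignore_index=True), summaries


def negative_control_check(
    records: pd.DataFrame,
    control_genes: set[str],
    thresholds: Thresholds = Thresholds(),
) -> pd.DataFrame:
    """Check that each control gene's enrichment stays below the fold
    cutoff in every genotype.

    Returns one row per control: gene_symbol, status in
    {pass, fail, not_evaluable}, max_enrichment.
    """
    rows = []
    for gene in sorted(control_genes):
        sub = records[records["gene_symbol"] == gene]
        if sub.empty:
            rows.append(
                {"gene_symbol": gene, "status": "not_evaluable", "max_enrichment": np.nan}
            )
            continue
        max_enr = float(sub["enrichment"].max())
        status = "pass" if max_enr < thresholds.fold_change_min else "fail"
        rows.append({"gene_symbol": gene, "status": status, "max_enrichment": max_enr})
    return pd.DataFrame(rows)


def write_enrichment_table(
    records: pd.DataFrame, path, definitions: pd.Series | None = None
) -> None:
    """Write a per-genotype target table (gene, definition, p-value,
    enrichment), sorted by descending enrichment."""
    out = records[records["is_target"]].copy()
    out["definition"] = (
        definitions.reindex(out["gene_symbol"]).fillna("").to_numpy()
        if definitions is not None
        else ""
    )
    out = out[["gene_symbol", "definition", "p_value", "enrichment"]]
    write_records(out, path, sort_by=["enrichment", "gene_symbol"], ascending=[False, True])
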