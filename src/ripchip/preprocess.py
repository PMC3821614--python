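"""Normalization and filtering of probe intensities, and the probe->gene
collapse.

The preprocessing chain mirrors standard bead-array practice: quantile
normalization of the background-corrected linear intensities across all
arrays, log2 transform with a floor, removal of probes undetected in every
design condition, removal of probes without a RefSeq annotation, and a
collapse to one probe per gene symbol (the probe with the highest mean
log2 intensity, so that genotype-specific absent/present calls survive
averaging).

Detection is decided per (genotype, fraction) condition: a probe counts as
detected in a condition when its detection p-value is <= alpha in at least
half (rounded up) of that condition's replicates.  A probe detected in no
condition is discarded.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ProbeAnnotation, ProbeMatrix, Scale, StudyDesign, Thresholds

logger = logging.getLogger(__name__)

__all__ = [
    "GeneMatrix",
    "quantile_normalize",
    "log2_transform",
    "detection_by_condition",
    "filter_detection",
    "filter_refseq",
    "collapse_to_genes",
    "gene_detection_by_genotype",
    "preprocess",
]


@dataclass
class GeneMatrix:
    """Gene-level log2 expression with probe provenance.

    One row per retained gene symbol; each row is the chosen probe's row of
    the filtered probe matrix, and ``provenance`` maps the symbol back to
    that probe id.  Detection p-values travel along so downstream stages
    can re-apply the detection rule restricted to one genotype.
    """

    log2_values: pd.DataFrame  # genes x samples
    detection_p: pd.DataFrame  # genes x samples, aligned
    provenance: pd.Series  # gene symbol -> probe_id

    def __post_init__(self) -> None:
        if not self.log2_values.index.equals(self.detection_p.index):
            raise ValueError("log2_values and detection_p must share gene index")
        if self.log2_values.index.has_duplicates:
            raise ValueError("gene symbols must be unique after collapse")
        if not np.isfinite(self.log2_values.to_numpy()).all():
            raise ValueError("gene-level log2 values must be finite")

    @property
    def gene_symbols(self) -> pd.Index:
        return self.log2_values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.log2_values.columns


def _quantile_normalize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    values = frame.to_numpy(dtype=float)
    n, m = values.shape
    reference = np.sort(values, axis=0).mean(axis=1)
    out = np.empty_like(values)
    for j in range(m):
        col = values[:, j]
        order = np.argsort(col, kind="mergesort")
        ranked = np.empty(n)
        # ties within a column take the mean of their block of reference
        # positions, so tied inputs stay tied after normalization
        i = 0
        sorted_col = col[order]
        while i < n:
            k = i
            while k + 1 < n and sorted_col[k + 1] == sorted_col[i]:
                k += 1
            ranked[i : k + 1] = reference[i : k + 1].mean()
            i = k + 1
        out[order, j] = ranked
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def quantile_normalize(m: ProbeMatrix) -> ProbeMatrix:
    """Quantile-normalize linear intensities so every column shares the
    reference distribution (row-wise mean of per-column sorted values)."""
    if m.scale is not Scale.LINEAR:
        raise ValueError("quantile normalization expects linear-scale intensities")
    if m.intensities.shape[1] < 2:
        logger.warning("quantile_normalize: single column, returned unchanged")
        return ProbeMatrix(m.intensities.copy(), m.detection_p.copy(), m.scale)
    normalized = _quantile_normalize_frame(m.intensities)
    return ProbeMatrix(normalized, m.detection_p.copy(), Scale.LINEAR)


def log2_transform(m: ProbeMatrix, floor: float = 1.0) -> ProbeMatrix:
    """log2(max(v, floor)); the floor guards non-positive background-
    corrected values."""
    if m.scale is not Scale.LINEAR:
        raise ValueError("log2_transform expects linear-scale intensities")
    if floor <= 0:
        raise ValueError(f"floor must be positive, got {floor}")
    values = np.log2(np.maximum(m.intensities.to_numpy(dtype=float), floor))
    frame = pd.DataFrame(values, index=m.intensities.index, columns=m.intensities.columns)
    return ProbeMatrix(frame, m.detection_p.copy(), Scale.LOG2)


def detection_by_condition(
    detection_p: pd.DataFrame, design: StudyDesign, alpha: float
) -> pd.DataFrame:
    """Probe/gene x condition boolean table of the majority detection rule.

    Columns are "GENOTYPE:FRACTION" strings in design order.
    """
    # alpha = 1 is allowed as the degenerate everything-detected identity
    if not 0 < alpha <= 1:
        raise ValueError(f"detection alpha must lie in (0, 1], got {alpha}")
    cols = {}
    for geno, frac in design.conditions():
        sids = design.select(geno, frac)
        need = math.ceil(len(sids) / 2)
        hits = (detection_p[sids] <= alpha).sum(axis=1)
        cols[f"{geno.value}:{frac.value}"] = hits >= need
    return pd.DataFrame(cols, index=detection_p.index)


def filter_detection(
    m: ProbeMatrix, design: StudyDesign, alpha: float
) -> tuple[ProbeMatrix, list[str]]:
    """Drop probes detected in no (genotype, fraction) condition.

    Returns (retained matrix, removed probe ids).
    """
    detected = detection_by_condition(m.detection_p, design, alpha)
    keep = detected.any(axis=1)
    removed = list(m.probe_ids[~keep])
    logger.info("detection filter: removed %d of %d probes", len(removed), len(keep))
    return m.subset(list(m.probe_ids[keep])), removed


def filter_refseq(
    m: ProbeMatrix, ann: ProbeAnnotation
) -> tuple[ProbeMatrix, list[str]]:
    """Drop probes lacking a RefSeq annotation."""
    missing = [p for p in m.probe_ids if p not in ann.table.index]
    if missing:
        raise ValueError(f"probe(s) missing from annotation: {missing[:5]}")
    has_refseq = ann.has_refseq().reindex(m.probe_ids)
    removed = list(m.probe_ids[~has_refseq])
    logger.info("RefSeq filter: removed %d of %d probes", len(removed), len(m.probe_ids))
    return m.subset(list(m.probe_ids[has_refseq])), removed


def collapse_to_genes(m: ProbeMatrix, ann: ProbeAnnotation) -> GeneMatrix:
    """Collapse probes to gene symbols.

    Per symbol, the probe with the highest mean log2 intensity across all
    samples represents the gene; ties break to the lexicographically
    smallest probe id.
    """
    if m.scale is not Scale.LOG2:
        raise ValueError("collapse_to_genes expects log2-scale values")
    symbols = ann.symbols(m.probe_ids)
    means = m.intensities.mean(axis=1)
    choice = pd.DataFrame(
        {"probe_id": m.probe_ids, "symbol": symbols.to_numpy(), "mean": means.to_numpy()}
    )
    choice = choice.sort_values(
        ["symbol", "mean", "probe_id"], ascending=[True, False, True], kind="mergesort"
    )
    best = choice.drop_duplicates("symbol", keep="first")
    probes = best["probe_id"].to_numpy()
    log2 = m.intensities.loc[probes].copy()
    log2.index = best["symbol"].to_numpy()
    det = m.detection_p.loc[probes].copy()
    det.index = best["symbol"].to_numpy()
    provenance = pd.Series(probes, index=best["symbol"].to_numpy(), name="probe_id")
    return GeneMatrix(log2, det, provenance)


def gene_detection_by_genotype(
    g: GeneMatrix, design: StudyDesign, alpha: float
) -> pd.DataFrame:
    """Genes x genotypes boolean table: detected in a genotype when the
    majority rule holds in at least one of its two fractions."""
    cond = detection_by_condition(g.detection_p, design, alpha)
    out = {}
    for geno in design.genotypes():
        cols = [c for c in cond.columns if c.startswith(f"{geno.value}:")]
        out[geno.value] = cond[cols].any(axis=1)
    return pd.DataFrame(out, index=g.detection_p.index)


def preprocess(
    m: ProbeMatrix,
    ann: ProbeAnnotation,
    design: StudyDesign,
    thresholds: Thresholds = Thresholds(),
    log2_floor: float = 1.0,
) -> tuple[GeneMatrix, pd.DataFrame]:
    """Full chain: quantile normalize -> log2 -> detection filter ->
    RefSeq filter -> gene collapse.

    Returns the gene matrix and a removed-probes log (probe_id, reason).
    """
    normalized = quantile_normalize(m)
    logged = log2_transform(normalized, floor=log2_floor)
    detected, removed_det = filter_detection(logged, design, thresholds.detection_alpha)
    annotated, removed_ref = filter_refseq(detected, ann)
    genes = collapse_to_genes(annotated, ann)
    removed = pd.DataFrame(
        {
            "probe_id": removed_det + removed_ref,
            "reason": ["undetected"] * len(removed_det) + ["no_refseq"] * len(removed_ref),
        }
    )
    logger.info(
        "preprocess: %d probes in, %d genes out", len(m.probe_ids), len(genes.gene_symbols)
    )
    return genes, removed
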