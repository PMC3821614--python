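"""RT-qPCR quantification by the relative standard curve method.

For each amplicon a standard curve — ordinary least squares of Ct on
log10(relative quantity) over a serial dilution of total nuclear RNA —
maps observed Ct values of unknowns to relative quantities
Q = 10^((Ct - intercept)/slope).  Quantities are normalized per sample to
a reference transcript (Gapdh), and two derived ratios summarize the
experiment: the IP enrichment (normalized IP / normalized total, per
genotype) and the KO/WT expression fold change on the total fraction.

Quantities are computed per well and averaged within a biological
replicate (technical wells -> experiment value); means and standard
deviations are then taken across biological replicates.  An undetected Ct
(no amplification) propagates as an undetected quantity rather than an
error — the background-level case.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .io import Fraction, Genotype, StudyDesign

logger = logging.getLogger(__name__)

__all__ = [
    "QPCRPlate",
    "StandardCurve",
    "read_plate",
    "fit_standard_curve",
    "fit_all_curves",
    "relative_quantity",
    "quantify_plate",
    "normalize_and_ratio",
]

ROLES = ("standard", "unknown", "no_RT_control")


@dataclass
class QPCRPlate:
    """Well table: target_id, sample_id, role, ct (NaN = undetected),
    log10_dilution (standards only)."""

    wells: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"target_id", "sample_id", "role", "ct", "log10_dilution"}
        missing = required - set(self.wells.columns)
        if missing:
            raise ValueError(f"plate missing column(s): {sorted(missing)}")
        bad = set(self.wells["role"]) - set(ROLES)
        if bad:
            raise ValueError(f"unknown well role(s): {sorted(bad)}")
        std = self.wells[self.wells["role"] == "standard"]
        if std["ct"].isna().any():
            raise ValueError("standards must have observed Ct values")
        for target, grp in std.groupby("target_id"):
            if grp["log10_dilution"].nunique() < 3:
                raise ValueError(
                    f"target {target!r}: standards span "
                    f"{grp['log10_dilution'].nunique()} dilution(s); need >= 3"
                )

    def standards(self, target_id: str) -> pd.DataFrame:
        return self.wells[
            (self.wells["role"] == "standard") & (self.wells["target_id"] == target_id)
        ]

    def targets(self) -> list[str]:
        return sorted(self.wells["target_id"].unique())


@dataclass(frozen=True)
class StandardCurve:
    """Fitted Ct = intercept + slope * log10(quantity) line.

    slope is Ct per decade of template (about -3.32 at 100% efficiency);
    efficiency E = 10^(-1/slope) - 1.
    """

    target_id: str
    slope: float
    intercept: float
    r_squared: float
    efficiency: float
    valid: bool


def read_plate(path) -> QPCRPlate:
    wells = pd.read_csv(path, sep="\t")
    return QPCRPlate(wells)


def fit_standard_curve(
    standards: pd.DataFrame, min_r_squared: float = 0.98
) -> StandardCurve:
    """OLS fit of Ct on log10(relative quantity) for one target's standards.

    A positive slope or an r-squared below ``min_r_squared`` flags the
    curve invalid (it is still returned for inspection).
    """
    if standards["log10_dilution"].nunique() < 3:
        raise ValueError("standard curve needs >= 3 distinct dilutions")
    target = standards["target_id"].iloc[0]
    x = standards["log10_dilution"].to_numpy(dtype=float)
    y = standards["ct"].to_numpy(dtype=float)
    fit = scipy.stats.linregress(x, y)
    r2 = float(fit.rvalue**2)
    slope = float(fit.slope)
    efficiency = 10.0 ** (-1.0 / slope) - 1.0 if slope != 0 else math.nan
    valid = slope < 0 and r2 >= min_r_squared
    if not valid:
        logger.warning(
            "standard curve for %s flagged invalid (slope=%.3f, r2=%.4f)",
            target, slope, r2,
        )
    return StandardCurve(
        target_id=str(target),
        slope=slope,
        intercept=float(fit.intercept),
        r_squared=r2,
        efficiency=float(efficiency),
        valid=valid,
    )


def fit_all_curves(
    plate: QPCRPlate, min_r_squared: float = 0.98
) -> dict[str, StandardCurve]:
    return {
        t: fit_standard_curve(plate.standards(t), min_r_squared)
        for t in plate.targets()
        if not plate.standards(t).empty
    }


def relative_quantity(ct: float, curve: StandardCurve) -> float:
    """Invert the standard curve: Q = 10^((Ct - intercept)/slope).

    An undetected Ct (NaN) yields an undetected quantity (NaN).
    """
    if not curve.valid:
        raise ValueError(f"standard curve for {curve.target_id} is invalid")
    if np.isnan(ct):
        return math.nan
    return float(10.0 ** ((ct - curve.intercept) / curve.slope))


def quantify_plate(
    plate: QPCRPlate, curves: dict[str, StandardCurve]
) -> pd.DataFrame:
    """Per-(target, sample) relative quantities of the unknown wells.

    Technical wells of one sample are averaged into a single experiment
    value; an undetected technical majority yields an undetected quantity.
    Also warns on any no-RT control that amplified.
    """
    no_rt = plate.wells[plate.wells["role"] == "no_RT_control"]
    amplified = no_rt[no_rt["ct"].notna()]
    for row in amplified.itertuples():
        logger.warning(
            "no-RT control amplified for target %s (Ct %.2f)", row.target_id, row.ct
        )
    unknowns = plate.wells[plate.wells["role"] == "unknown"].copy()
    unknowns["quantity"] = [
        relative_quantity(ct, curves[t])
        for ct, t in zip(unknowns["ct"], unknowns["target_id"])
    ]
    grouped = (
        unknowns.groupby(["target_id", "sample_id"])["quantity"]
        .apply(lambda q: q.mean() if q.notna().mean() > 0.5 else math.nan)
        .reset_index()
    )
    return grouped


def normalize_and_ratio(
    quantities: pd.DataFrame,
    reference_target: str,
    design: StudyDesign,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Reference-normalize quantities and derive the summary ratios.

    Returns (normalized, ratios):

    * normalized — per (target, sample): quantity / reference quantity of
      the same sample (the per-sample normalization that removes template
      and scale differences between reactions);
    * ratios — per target and measure, the mean and standard deviation
      across biological replicates of:
        - ``ip_enrichment_<genotype>``: normalized IP / normalized TOTAL,
        - ``expression_fold_ko_vs_wt``: normalized KO TOTAL / WT TOTAL
          (replicates paired by index; folds < 1 are down-regulation).
      An undetected input propagates to an undetected ratio with a reason.
    """
    ref = quantities[quantities["target_id"] == reference_target].set_index("sample_id")[
        "quantity"
    ]
    undetected_ref = [sid for sid, q in ref.items() if np.isnan(q)]
    if undetected_ref:
        raise ValueError(
            f"reference {reference_target!r} undetected in sample(s) {undetected_ref}"
        )
    norm = quantities.copy()
    norm["normalized"] = [
        q / ref[sid] if sid in ref.index else math.nan
        for q, sid in zip(norm["quantity"], norm["sample_id"])
    ]
    wide = norm.pivot_table(
        index="target_id", columns="sample_id", values="normalized", aggfunc="first",
        dropna=False,
    )
    rows = []
    targets = [t for t in wide.index if t != reference_target]
    for target in targets:
        for geno in design.genotypes():
            ip_ids = design.select(geno, Fraction.IP)
            tot_ids = design.select(geno, Fraction.TOTAL)
            per_rep = []
            for ip_id, tot_id in zip(ip_ids, tot_ids):
                ip_q = wide.at[target, ip_id] if ip_id in wide.columns else math.nan
                tot_q = wide.at[target, tot_id] if tot_id in wide.columns else math.nan
                per_rep.append(ip_q / tot_q if tot_q and not np.isnan(tot_q) else math.nan)
            rows.append(
                _summary_row(target, f"ip_enrichment_{geno.value.lower()}", per_rep)
            )
        ko_ids = design.select(Genotype.KO, Fraction.TOTAL)
        wt_ids = design.select(Genotype.WT, Fraction.TOTAL)
        per_rep = []
        for ko_id, wt_id in zip(ko_ids, wt_ids):
            ko_q = wide.at[target, ko_id] if ko_id in wide.columns else math.nan
            wt_q = wide.at[target, wt_id] if wt_id in wide.columns else math.nan
            per_rep.append(ko_q / wt_q if wt_q and not np.isnan(wt_q) else math.nan)
        rows.append(_summary_row(target, "expression_fold_ko_vs_wt", per_rep))
    ratios = pd.DataFrame(
        rows, columns=["target_id", "measure", "mean", "sd", "n_replicates", "status"]
    )
    return norm, ratios


def _summary_row(target: str, measure: str, per_rep: list[float]) -> dict:
    values = np.array([v for v in per_rep if not np.isnan(v)])
    if values.size == 0:
        return {
            "target_id": target,
            "measure": measure,
            "mean": math.nan,
            "sd": math.nan,
            "n_replicates": 0,
            "status": "undetected",
        }
    status = "ok" if values.size == len(per_rep) else "partial"
    return {
        "target_id": target,
        "measure": measure,
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)) if values.size > 1 else math.nan,
        "n_replicates": int(values.size),
        "status": status,
    }
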