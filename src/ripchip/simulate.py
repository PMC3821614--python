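"""Synthetic RIP-Chip fixtures with a ground-truth table.

The generator emulates the statistical structure of a two-genotype x
two-fraction bead-array experiment with biological triplicates: a
log-additive signal model on the log2 scale with Gaussian replicate
noise,

    log2 signal = base + genotype shift (KO totals)
                + log2(planted enrichment) (IP fraction)
                + N(0, sd),

exported as linear intensities.  Planted structure covers every case the
pipeline must distinguish: RNP targets with enrichments in the 2.5-5x
range in one or both genotypes, differentially expressed genes, a
housekeeping-style control at enrichment exactly 1 in both genotypes,
genes absent from one genotype (background-level signal and detection
p > 0.01 there, mirroring a transcript expressed only in the knockout),
multi-probe genes, unannotated decoy probes, and GO terms with one term
deliberately concentrated in the planted targets.  Detection p-values are
generated from signal versus a background threshold — only their position
relative to the 0.01 cutoff matters downstream.

A companion generator produces qPCR plates (standards along a serial
dilution, unknown wells from truth quantities, no-RT controls) for the
relative-standard-curve arithmetic.  Everything is deterministic per
seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    Fraction,
    Genotype,
    ProbeAnnotation,
    ProbeMatrix,
    Sample,
    Scale,
    StudyDesign,
)
from .qpcr import QPCRPlate

__all__ = [
    "ExperimentConfig",
    "SimulatedExperiment",
    "generate_experiment",
    "QPCRTargetTruth",
    "QPCRConfig",
    "generate_qpcr",
    "write_experiment",
]


@dataclass(frozen=True)
class ExperimentConfig:
    """Defaults mirror the study's scale at desk size: 2,000 genes, three
    biological replicates per (genotype, fraction) condition, planted IP
    enrichments up to 5-fold and log2 replicate noise sd 0.25."""

    n_genes: int = 2000
    n_replicates: int = 3
    n_targets: int = 100          # planted RNP targets (both genotypes)
    enrichment_range: tuple[float, float] = (2.5, 5.0)
    n_de: int = 40                # differentially expressed totals (KO vs WT)
    de_shift_range: tuple[float, float] = (1.5, 3.0)  # |log2 shift|
    n_absent_wt: int = 5          # KO-only transcripts, absent in WT
    absent_enrichment_range: tuple[float, float] = (2.5, 4.0)
    control_symbol: str = "Gapdh"
    control_base_log2: float = 11.0  # abundant, but inside the bulk of the distribution
    noise_sd: float = 0.25
    base_log2_mean: float = 8.5   # bell-shaped log2 abundance, like real arrays
    base_log2_sd: float = 1.5
    base_log2_clip: tuple[float, float] = (5.5, 13.5)
    background_log2: float = 4.0
    detection_threshold: float = 5.0
    extra_probe_prob: float = 0.45   # platform has ~1.5 probes per transcript
    extra_probe_offset: float = 1.0  # extra probes sit below the primary probe
    n_unannotated: int = 20          # decoy probes without a RefSeq
    n_go_terms: int = 15
    go_term_size: tuple[int, int] = (20, 100)
    concentrated_term_targets: int = 30
    concentrated_term_others: int = 10

    def __post_init__(self) -> None:
        planted = self.n_targets + self.n_de + self.n_absent_wt + 1
        if planted > self.n_genes:
            raise ValueError(
                f"config plants {planted} genes but has only {self.n_genes}"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class SimulatedExperiment:
    matrix: ProbeMatrix
    annotation: ProbeAnnotation
    design: StudyDesign
    truth: pd.DataFrame  # indexed by gene symbol
    gene_sets: dict[str, tuple[str, frozenset[str]]]


def _design(n_replicates: int) -> StudyDesign:
    samples = []
    for geno in (Genotype.WT, Genotype.KO):
        for frac in (Fraction.TOTAL, Fraction.IP):
            for rep in range(1, n_replicates + 1):
                samples.append(
                    Sample(f"{geno.value}_{frac.value}_{rep}", geno, frac, rep)
                )
    return StudyDesign(samples)


def generate_experiment(
    config: ExperimentConfig = ExperimentConfig(), seed: int = 0
) -> SimulatedExperiment:
    """Generate one complete probe-level experiment plus ground truth."""
    rng = np.random.default_rng(seed)
    cfg = config
    design = _design(cfg.n_replicates)
    n = cfg.n_genes

    symbols = np.array([f"Gene{i:04d}" for i in range(n)], dtype=object)
    symbols[0] = cfg.control_symbol

    base = np.clip(
        rng.normal(cfg.base_log2_mean, cfg.base_log2_sd, size=n), *cfg.base_log2_clip
    )
    base[0] = cfg.control_base_log2  # abundant housekeeping transcript

    # plant targets / DE genes / absent genes on disjoint, non-control genes
    pool = rng.permutation(np.arange(1, n))
    target_idx = pool[: cfg.n_targets]
    de_idx = pool[cfg.n_targets : cfg.n_targets + cfg.n_de]
    absent_idx = pool[cfg.n_targets + cfg.n_de : cfg.n_targets + cfg.n_de + cfg.n_absent_wt]

    enr_wt = np.ones(n)
    enr_ko = np.ones(n)
    enr_wt[target_idx] = rng.uniform(*cfg.enrichment_range, size=cfg.n_targets)
    enr_ko[target_idx] = rng.uniform(*cfg.enrichment_range, size=cfg.n_targets)
    enr_ko[absent_idx] = rng.uniform(*cfg.absent_enrichment_range, size=cfg.n_absent_wt)

    de_shift = np.zeros(n)
    magnitudes = rng.uniform(*cfg.de_shift_range, size=cfg.n_de)
    signs = rng.choice([-1.0, 1.0], size=cfg.n_de)
    de_shift[de_idx] = magnitudes * signs

    absent_in = np.array([""] * n, dtype=object)
    absent_in[absent_idx] = Genotype.WT.value

    # expected log2 signal per gene x sample
    mu = np.empty((n, len(design)))
    for j, sample in enumerate(design):
        enr = enr_ko if sample.genotype is Genotype.KO else enr_wt
        col = base.copy()
        if sample.genotype is Genotype.KO:
            col = col + de_shift
        if sample.fraction is Fraction.IP:
            col = col + np.log2(enr)
        col = np.where(absent_in == sample.genotype.value, cfg.background_log2, col)
        mu[:, j] = col

    noise = rng.normal(0.0, cfg.noise_sd, size=mu.shape) if cfg.noise_sd > 0 else 0.0
    signal = mu + noise

    # second probes for a random subset of genes, sitting one log2 unit lower
    extra_mask = rng.random(n) < cfg.extra_probe_prob
    extra_idx = np.flatnonzero(extra_mask)
    extra_noise = (
        rng.normal(0.0, cfg.noise_sd, size=(len(extra_idx), len(design)))
        if cfg.noise_sd > 0
        else 0.0
    )
    extra_signal = mu[extra_idx] - cfg.extra_probe_offset + extra_noise

    # unannotated decoy probes at background-like levels
    decoy_signal = rng.uniform(
        cfg.background_log2 + 1.5, cfg.background_log2 + 4.0, size=(cfg.n_unannotated, 1)
    ) + rng.normal(0.0, max(cfg.noise_sd, 1e-12), size=(cfg.n_unannotated, len(design)))

    def detection_p(sig: np.ndarray) -> np.ndarray:
        detected = sig > cfg.detection_threshold
        low = rng.uniform(0.0, 0.001, size=sig.shape)
        high = rng.uniform(0.02, 0.9, size=sig.shape)
        return np.where(detected, low, high)

    all_signal = np.vstack([signal, extra_signal, decoy_signal])
    all_detection = detection_p(all_signal)

    probe_ids = (
        [f"PRB{i:06d}" for i in range(n)]
        + [f"PRBX{i:06d}" for i in extra_idx]
        + [f"PRBU{i:06d}" for i in range(cfg.n_unannotated)]
    )
    probe_symbols = (
        list(symbols)
        + list(symbols[extra_idx])
        + [f"Decoy{i:03d}" for i in range(cfg.n_unannotated)]
    )
    refseq = (
        [f"NM_{i:06d}" for i in range(n)]
        + [f"NM_{i:06d}" for i in extra_idx]
        + [""] * cfg.n_unannotated
    )
    annotation = ProbeAnnotation(
        pd.DataFrame(
            {
                "SYMBOL": probe_symbols,
                "REFSEQ": refseq,
                "DEFINITION": [f"synthetic transcript {s}" for s in probe_symbols],
            },
            index=pd.Index(probe_ids, name="PROBE_ID"),
        )
    )
    intensities = pd.DataFrame(
        2.0**all_signal, index=probe_ids, columns=design.sample_ids
    )
    detection = pd.DataFrame(all_detection, index=probe_ids, columns=design.sample_ids)
    matrix = ProbeMatrix(intensities, detection, Scale.LINEAR)

    gene_sets = _go_sets(rng, cfg, symbols, target_idx)
    term_map: dict[str, list[str]] = {s: [] for s in symbols}
    for term_id, (_, members) in gene_sets.items():
        for gene in members:
            term_map[gene].append(term_id)

    truth = pd.DataFrame(
        {
            "base_log2": base,
            "de_shift_log2": de_shift,
            "enr_wt": enr_wt,
            "enr_ko": enr_ko,
            "ratio": enr_ko / enr_wt,
            "absent_in": absent_in,
            "is_control": symbols == cfg.control_symbol,
            "is_target_wt": (enr_wt > 1) & (absent_in != Genotype.WT.value),
            "is_target_ko": (enr_ko > 1) & (absent_in != Genotype.KO.value),
            "go_terms": [";".join(sorted(term_map[s])) for s in symbols],
        },
        index=pd.Index(symbols, name="gene_symbol"),
    )
    return SimulatedExperiment(matrix, annotation, design, truth, gene_sets)


def _go_sets(
    rng: np.random.Generator,
    cfg: ExperimentConfig,
    symbols: np.ndarray,
    target_idx: np.ndarray,
) -> dict[str, tuple[str, frozenset[str]]]:
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    n = len(symbols)
    non_targets = np.setdiff1d(np.arange(n), target_idx)
    # one term concentrated in planted targets, to give over-representation
    # analysis a true positive
    k_t = min(cfg.concentrated_term_targets, len(target_idx))
    k_o = min(cfg.concentrated_term_others, len(non_targets))
    members = np.concatenate(
        [
            rng.choice(target_idx, size=k_t, replace=False),
            rng.choice(non_targets, size=k_o, replace=False),
        ]
    )
    sets["GO:SIM0000"] = ("planted target process", frozenset(symbols[members]))
    for t in range(cfg.n_go_terms):
        size = int(rng.integers(cfg.go_term_size[0], cfg.go_term_size[1] + 1))
        members = rng.choice(n, size=size, replace=False)
        sets[f"GO:SIM{t + 1:04d}"] = (
            f"background process {t + 1}",
            frozenset(symbols[members]),
        )
    return sets


def recovery_metrics(records: pd.DataFrame, truth: pd.DataFrame) -> dict[str, float]:
    """Recall and empirical false-discovery proportion of the union target
    list against planted truth.

    The pipeline's headline output is the union of the two genotypes'
    target sets (the cross-genotype association analysis runs on it), so
    recovery is scored there: a planted target counts as recovered when it
    is called in at least one genotype, and a call is false when the gene
    was planted as a target in neither.
    """
    called = set(records.loc[records["is_target"], "gene_symbol"])
    planted = set(truth.index[truth["is_target_wt"] | truth["is_target_ko"]])
    recall = len(called & planted) / len(planted) if planted else float("nan")
    fdp = len(called - planted) / len(called) if called else 0.0
    return {"recall": recall, "fdp": fdp, "n_called": len(called), "n_planted": len(planted)}


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class QPCRTargetTruth:
    enr_wt: float
    enr_ko: float
    expr_fold_ko_vs_wt: float
    absent_in: str = ""  # "WT"/"KO" -> undetected in that genotype


# default validation panel: enrichment ratios spanning the increased /
# unchanged / reduced association classes, one KO-only transcript and one
# strongly down-regulated gene
DEFAULT_QPCR_TARGETS: dict[str, QPCRTargetTruth] = {
    "TargetA": QPCRTargetTruth(2.5, 8.8, 1.3, absent_in="WT"),  # KO-only, high affinity
    "TargetB": QPCRTargetTruth(2.5, 6.9, 1.2),   # increased association
    "TargetC": QPCRTargetTruth(2.5, 3.1, 0.5),   # unchanged association
    "TargetD": QPCRTargetTruth(2.5, 1.4, 0.4),   # reduced association
    "TargetE": QPCRTargetTruth(2.5, 4.6, 2.5),   # increased, up-regulated
    "TargetF": QPCRTargetTruth(4.0, 4.0, 1.0),   # stable target
}


@dataclass(frozen=True)
class QPCRConfig:
    targets: dict[str, QPCRTargetTruth] = field(
        default_factory=lambda: dict(DEFAULT_QPCR_TARGETS)
    )
    reference: str = "Gapdh"
    n_replicates: int = 3       # biological replicates (independent experiments)
    n_technical: int = 3        # wells per sample
    n_dilutions: int = 5        # 10-fold serial dilution points
    slope: float = -3.3219      # Ct per log10 quantity (100% efficiency)
    intercept_range: tuple[float, float] = (20.0, 24.0)
    ct_noise_sd: float = 0.1
    base_quantity: float = 0.05   # unknowns sit inside the dilution span
    sample_scale_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.n_dilutions < 3:
            raise ValueError("need >= 3 dilution points for a standard curve")
        if self.reference in self.targets:
            raise ValueError("reference must not appear among targets")


def generate_qpcr(
    config: QPCRConfig = QPCRConfig(), seed: int = 0
) -> tuple[QPCRPlate, StudyDesign, pd.DataFrame]:
    """Generate a qPCR plate (standards, unknowns, no-RT controls), the
    matching 2x2x`n_replicates` design, and the truth table."""
    rng = np.random.default_rng(seed)
    cfg = config
    design = _design(cfg.n_replicates)
    all_targets = {**cfg.targets, cfg.reference: QPCRTargetTruth(1.0, 1.0, 1.0)}
    intercepts = {
        t: float(rng.uniform(*cfg.intercept_range)) for t in sorted(all_targets)
    }
    scales = {sid: float(rng.uniform(*cfg.sample_scale_range)) for sid in design.sample_ids}

    def noisy(ct: float) -> float:
        return ct + float(rng.normal(0.0, cfg.ct_noise_sd)) if cfg.ct_noise_sd > 0 else ct

    rows = []
    for target in sorted(all_targets):
        truth = all_targets[target]
        b = intercepts[target]
        for d in range(cfg.n_dilutions):
            log10_q = -float(d)
            rows.append(
                {
                    "target_id": target,
                    "sample_id": f"std_{target}_{d}",
                    "role": "standard",
                    "ct": noisy(b + cfg.slope * log10_q),
                    "log10_dilution": log10_q,
                }
            )
        for sample in design:
            q = cfg.base_quantity * scales[sample.sample_id]
            if sample.genotype is Genotype.KO:
                q *= truth.expr_fold_ko_vs_wt
            if sample.fraction is Fraction.IP:
                q *= truth.enr_ko if sample.genotype is Genotype.KO else truth.enr_wt
            undetected = truth.absent_in == sample.genotype.value
            for well in range(cfg.n_technical):
                rows.append(
                    {
                        "target_id": target,
                        "sample_id": sample.sample_id,
                        "role": "unknown",
                        "ct": np.nan if undetected else noisy(b + cfg.slope * np.log10(q)),
                        "log10_dilution": np.nan,
                    }
                )
        rows.append(
            {
                "target_id": target,
                "sample_id": f"noRT_{target}",
                "role": "no_RT_control",
                "ct": np.nan,
                "log10_dilution": np.nan,
            }
        )
    plate = QPCRPlate(pd.DataFrame(rows))
    truth_table = pd.DataFrame(
        {
            "target_id": sorted(all_targets),
            "enr_wt": [all_targets[t].enr_wt for t in sorted(all_targets)],
            "enr_ko": [all_targets[t].enr_ko for t in sorted(all_targets)],
            "expr_fold_ko_vs_wt": [
                all_targets[t].expr_fold_ko_vs_wt for t in sorted(all_targets)
            ],
            "absent_in": [all_targets[t].absent_in for t in sorted(all_targets)],
            "slope": cfg.slope,
            "intercept": [intercepts[t] for t in sorted(all_targets)],
        }
    )
    return plate, design, truth_table


# ---------------------------------------------------------------------------
# file export (the TSV dialects consumed by the io module)
# ---------------------------------------------------------------------------

def write_experiment(sim: SimulatedExperiment, outdir: str | Path) -> dict[str, Path]:
    """Write probe profile, design, truth and GMT files; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "probe_profile": outdir / "probe_profile.tsv",
        "design": outdir / "design.tsv",
        "truth": outdir / "truth.tsv",
        "gene_sets": outdir / "gene_sets.gmt",
    }
    profile = sim.annotation.table.reset_index().rename(columns={"index": "PROBE_ID"})
    if "PROBE_ID" not in profile.columns:
        profile.insert(0, "PROBE_ID", sim.annotation.table.index)
    for sid in sim.design.sample_ids:
        profile[f"{sid}.AVG_Signal"] = sim.matrix.intensities[sid].to_numpy()
        profile[f"{sid}.Detection_Pval"] = sim.matrix.detection_p[sid].to_numpy()
    profile.to_csv(paths["probe_profile"], sep="\t", index=False, float_format="%.10g")
    sim.design.to_frame().to_csv(paths["design"], sep="\t", index=False)
    sim.truth.reset_index().to_csv(
        paths["truth"], sep="\t", index=False, float_format="%.10g"
    )
    with open(paths["gene_sets"], "w") as fh:
        for term_id in sorted(sim.gene_sets):
            name, members = sim.gene_sets[term_id]
            fh.write("\t".join([term_id, name, *sorted(members)]) + "\n")
    return paths
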