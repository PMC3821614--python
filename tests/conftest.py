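from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from ripchip.io import Fraction, Genotype, ProbeAnnotation, ProbeMatrix, Sample, Scale, StudyDesign
from ripchip.preprocess import GeneMatrix
from ripchip.simulate import generate_experiment

DATA_DIR = Path(__file__).parent / "data"


def make_design(n_replicates: int = 3) -> StudyDesign:
    samples = []
    for geno in (Genotype.WT, Genotype.KO):
        for frac in (Fraction.TOTAL, Fraction.IP):
            for rep in range(1, n_replicates + 1):
                samples.append(Sample(f"{geno.value}_{frac.value}_{rep}", geno, frac, rep))
    return StudyDesign(samples)


def make_gene_matrix(log2: np.ndarray, genes: list[str], design: StudyDesign,
                     detection_p: np.ndarray | None = None) -> GeneMatrix:
    frame = pd.DataFrame(log2, index=genes, columns=design.sample_ids)
    det = pd.DataFrame(
        detection_p if detection_p is not None else np.zeros_like(log2),
        index=genes, columns=design.sample_ids,
    )
    prov = pd.Series([f"PRB{i:06d}" for i in range(len(genes))], index=genes)
    return GeneMatrix(frame, det, prov)


def make_probe_matrix(values: np.ndarray, probes: list[str], samples: list[str],
                      detection_p: np.ndarray | None = None,
                      scale: Scale = Scale.LINEAR) -> ProbeMatrix:
    frame = pd.DataFrame(np.asarray(values, dtype=float), index=probes, columns=samples)
    det = pd.DataFrame(
        detection_p if detection_p is not None else np.zeros_like(frame.to_numpy()),
        index=probes, columns=samples,
    )
    return ProbeMatrix(frame, det, scale)


@pytest.fixture(scope="session")
def default_sim():
    """One default-configuration synthetic experiment, shared read-only."""
    return generate_experiment(seed=7)


@pytest.fixture(scope="session")
def table2_printed() -> pd.DataFrame:
    return pd.read_csv(DATA_DIR / "table2_printed.tsv", sep="\t")
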