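"""Data model, file readers/writers and threshold configuration.

The pipeline works on probe-level bead-array exports: a tab-delimited
"sample probe profile" with one ``<sample>.AVG_Signal`` /
``<sample>.Detection_Pval`` column pair per array, plus probe annotation
columns (``PROBE_ID``, ``SYMBOL``, ``REFSEQ``, ``DEFINITION``).  The study
design is the 2 genotypes (HuR WT / HuR KO) x 2 fractions (total nuclear
RNA / RNP immunoprecipitate) x replicates layout; gene sets come in as GMT.

All tabular outputs are tab-delimited with a header, floats rendered at six
significant digits, and a deterministic row order, so repeated runs diff
cleanly.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "Genotype",
    "Fraction",
    "Sample",
    "StudyDesign",
    "ProbeMatrix",
    "ProbeAnnotation",
    "Thresholds",
    "read_design",
    "read_probe_profile",
    "read_gene_sets",
    "write_records",
    "read_records",
]


class Genotype(str, enum.Enum):
    WT = "WT"
    KO = "KO"


class Fraction(str, enum.Enum):
    TOTAL = "TOTAL"
    IP = "IP"


ANNOTATION_COLUMNS = ("PROBE_ID", "SYMBOL", "REFSEQ", "DEFINITION")


@dataclass(frozen=True)
class Sample:
    """One array: a (genotype, fraction, replicate) cell of the design."""

    sample_id: str
    genotype: Genotype
    fraction: Fraction
    replicate: int

    def __post_init__(self) -> None:
        if self.replicate < 1:
            raise ValueError(f"replicate must be >= 1, got {self.replicate}")


class StudyDesign:
    """Ordered collection of samples with unique ids.

    Sample order is meaningful: matrix columns follow design order
    throughout the pipeline.
    """

    def __init__(self, samples: Sequence[Sample]):
        ids = [s.sample_id for s in samples]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise ValueError(f"duplicate sample_id(s) in design: {sorted(dupes)}")
        self._samples = list(samples)

    def __len__(self) -> int:
        return len(self._samples)

    def __iter__(self):
        return iter(self._samples)

    @property
    def samples(self) -> list[Sample]:
        return list(self._samples)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self._samples]

    def select(
        self,
        genotype: Genotype | str | None = None,
        fraction: Fraction | str | None = None,
    ) -> list[str]:
        """Sample ids of one design cell (or margin), in design order."""
        geno = Genotype(genotype) if genotype is not None else None
        frac = Fraction(fraction) if fraction is not None else None
        return [
            s.sample_id
            for s in self._samples
            if (geno is None or s.genotype == geno)
            and (frac is None or s.fraction == frac)
        ]

    def conditions(self) -> list[tuple[Genotype, Fraction]]:
        """The distinct (genotype, fraction) cells present, in design order."""
        seen: list[tuple[Genotype, Fraction]] = []
        for s in self._samples:
            key = (s.genotype, s.fraction)
            if key not in seen:
                seen.append(key)
        return seen

    def genotypes(self) -> list[Genotype]:
        seen: list[Genotype] = []
        for s in self._samples:
            if s.genotype not in seen:
                seen.append(s.genotype)
        return seen

    def require_replicates(self, minimum: int = 2) -> None:
        """Fail unless every present design cell has >= `minimum` replicates."""
        for geno, frac in self.conditions():
            n = len(self.select(geno, frac))
            if n < minimum:
                raise ValueError(
                    f"condition ({geno.value}, {frac.value}) has {n} replicate(s); "
                    f"statistical testing needs >= {minimum}"
                )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.sample_id for s in self._samples],
                "genotype": [s.genotype.value for s in self._samples],
                "fraction": [s.fraction.value for s in self._samples],
                "replicate": [s.replicate for s in self._samples],
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "StudyDesign":
        required = {"sample_id", "genotype", "fraction", "replicate"}
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"design table missing column(s): {sorted(missing)}")
        samples = [
            Sample(
                sample_id=str(row.sample_id),
                genotype=Genotype(str(row.genotype)),
                fraction=Fraction(str(row.fraction)),
                replicate=int(row.replicate),
            )
            for row in frame.itertuples()
        ]
        return cls(samples)


class Scale(str, enum.Enum):
    LINEAR = "linear"
    LOG2 = "log2"


@dataclass
class ProbeMatrix:
    """Probes x samples intensities with aligned detection p-values.

    ``scale`` records whether ``intensities`` are linear (non-negative) or
    log2 values; the detection p-value for a probe/sample is the
    probability that its signal is indistinguishable from background.
    """

    intensities: pd.DataFrame
    detection_p: pd.DataFrame
    scale: Scale = Scale.LINEAR

    def __post_init__(self) -> None:
        self.scale = Scale(self.scale)
        if not self.intensities.index.equals(self.detection_p.index) or not (
            self.intensities.columns.equals(self.detection_p.columns)
        ):
            raise ValueError("intensities and detection_p must share axis labels")
        if self.intensities.index.has_duplicates:
            dup = self.intensities.index[self.intensities.index.duplicated()][0]
            raise ValueError(f"duplicate probe id: {dup!r}")
        dp = self.detection_p.to_numpy()
        if np.nanmin(dp, initial=0.0) < 0 or np.nanmax(dp, initial=0.0) > 1:
            raise ValueError("detection p-values must lie in [0, 1]")
        if self.scale is Scale.LINEAR and (self.intensities.to_numpy() < 0).any():
            raise ValueError("linear-scale intensities must be non-negative")

    @property
    def probe_ids(self) -> pd.Index:
        return self.intensities.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.intensities.columns

    def subset(self, probe_ids: Sequence[str]) -> "ProbeMatrix":
        return ProbeMatrix(
            self.intensities.loc[list(probe_ids)].copy(),
            self.detection_p.loc[list(probe_ids)].copy(),
            self.scale,
        )


@dataclass
class ProbeAnnotation:
    """Probe id -> gene symbol / RefSeq / free-text definition.

    An empty ``REFSEQ`` string marks a probe without a RefSeq transcript,
    which the preprocessing step removes.
    """

    table: pd.DataFrame  # indexed by probe_id; columns SYMBOL, REFSEQ, DEFINITION

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise ValueError(f"duplicate probe id in annotation: {dup!r}")
        for col in ("SYMBOL", "REFSEQ", "DEFINITION"):
            if col not in self.table.columns:
                raise ValueError(f"annotation missing column {col}")
        self.table = self.table.fillna("")

    def symbols(self, probe_ids: Iterable[str]) -> pd.Series:
        return self.table.loc[list(probe_ids), "SYMBOL"]

    def definitions(self) -> pd.Series:
        return self.table["DEFINITION"]

    def has_refseq(self) -> pd.Series:
        return self.table["REFSEQ"].astype(str).str.len() > 0


@dataclass(frozen=True)
class Thresholds:
    """Every cutoff the pipeline applies, with the study's values as defaults.

    detection_alpha : probe detection p-value cutoff (absent above it)
    test_alpha      : raw t-test p cutoff
    fdr_alpha       : FDR (BH q-value) cutoff
    fold_change_min : linear fold / enrichment cutoff (strict >)
    association_band: closed [lower, upper] KO/WT enrichment-ratio band
                      classified as "unchanged" association
    go_alpha        : hypergeometric p cutoff for GO over-representation
    """

    detection_alpha: float = 0.01
    test_alpha: float = 0.05
    fdr_alpha: float = 0.05
    fold_change_min: float = 2.0
    association_band: tuple[float, float] = (0.70, 1.40)
    go_alpha: float = 0.01

    def __post_init__(self) -> None:
        for name in ("detection_alpha", "test_alpha", "fdr_alpha", "go_alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")
        if self.fold_change_min <= 1:
            raise ValueError("fold_change_min must exceed 1")
        lo, hi = self.association_band
        if not lo < 1 < hi:
            raise ValueError("association_band must bracket 1 (lower < 1 < upper)")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> StudyDesign:
    """Read a tab-delimited design table (sample_id, genotype, fraction, replicate)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    frame["replicate"] = frame["replicate"].astype(int)
    return StudyDesign.from_frame(frame)


def read_probe_profile(
    path: str | Path, design: StudyDesign
) -> tuple[ProbeMatrix, ProbeAnnotation]:
    """Read a sample probe profile into aligned intensity/detection matrices.

    The file is tab-delimited with one header line: annotation columns
    (PROBE_ID, SYMBOL, REFSEQ, DEFINITION) followed by per-sample
    ``<sample>.AVG_Signal`` and ``<sample>.Detection_Pval`` column pairs.
    Column order of the result follows the design, not the file.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str)
    if "PROBE_ID" not in raw.columns:
        raise ValueError("probe profile lacks a PROBE_ID column")
    for sid in design.sample_ids:
        for suffix in (".AVG_Signal", ".Detection_Pval"):
            if f"{sid}{suffix}" not in raw.columns:
                raise ValueError(
                    f"probe profile missing column {sid}{suffix} for design sample {sid!r}"
                )
    probe_ids = raw["PROBE_ID"]
    if probe_ids.duplicated().any():
        dup = probe_ids[probe_ids.duplicated()].iloc[0]
        raise ValueError(f"duplicate probe row: {dup!r}")

    def numeric(colname: str) -> pd.Series:
        col = raw[colname]
        out = pd.to_numeric(col, errors="coerce")
        bad = out.isna() & col.notna()
        if bad.any():
            row = bad.idxmax()
            raise ValueError(
                f"non-numeric value {col[row]!r} at row {row} column {colname!r}"
            )
        return out

    intensity = pd.DataFrame(
        {sid: numeric(f"{sid}.AVG_Signal").to_numpy() for sid in design.sample_ids},
        index=probe_ids.to_numpy(),
    )
    detection = pd.DataFrame(
        {sid: numeric(f"{sid}.Detection_Pval").to_numpy() for sid in design.sample_ids},
        index=probe_ids.to_numpy(),
    )
    ann = pd.DataFrame(index=probe_ids.to_numpy())
    for col in ("SYMBOL", "REFSEQ", "DEFINITION"):
        ann[col] = raw[col].fillna("").to_numpy() if col in raw.columns else ""
    matrix = ProbeMatrix(intensity, detection, Scale.LINEAR)
    return matrix, ProbeAnnotation(ann)


def read_gene_sets(path: str | Path) -> dict[str, tuple[str, frozenset[str]]]:
    """Read GMT gene sets: term id, description, member genes per line.

    Returns term id -> (name, member set).  Empty terms are dropped with a
    warning; a duplicated term id or a line with fewer than three fields is
    fatal.
    """
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"GMT line {lineno}: expected >= 3 tab-separated fields, got {len(fields)}"
                )
            term, name, *genes = fields
            if term in sets:
                raise ValueError(f"GMT line {lineno}: duplicate term id {term!r}")
            members = frozenset(g for g in genes if g)
            if not members:
                logger.warning("GMT line %d: term %s has no members; dropped", lineno, term)
                continue
            sets[term] = (name, members)
    return sets


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

FLOAT_FORMAT = "%.6g"


def write_records(
    records: pd.DataFrame,
    path: str | Path,
    sort_by: Sequence[str] | None = None,
    ascending: bool | Sequence[bool] = True,
) -> None:
    """Write a record table as TSV: header, 6-significant-digit floats,
    deterministic row order (by ``sort_by``, ties broken by all remaining
    columns left to right)."""
    out = records.copy()
    if sort_by:
        out = out.sort_values(
            list(sort_by), ascending=ascending, kind="mergesort"
        )
    out.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


def read_records(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
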