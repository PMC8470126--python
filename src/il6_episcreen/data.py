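"""Domain types and TSV readers/writers for the screening pipeline.

All tabular inputs follow the Xena export convention: tab-separated UTF-8
with a header row. Matrices put feature ids in the first column and sample
ids in the header; missing values are the literal token ``NA`` (the empty
string is also accepted on read and normalised to ``NA`` on write).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohorts import CohortLabel
from .exceptions import FormatError, ParseError, ValidationError

NA_TOKEN = "NA"


class TissueClass(str, enum.Enum):
    TUMOR = "tumor"
    NORMAL = "normal"


class Endpoint(str, enum.Enum):
    OS = "OS"
    PFI = "PFI"


class ProbeRegion(str, enum.Enum):
    TSS1500 = "TSS1500"
    TSS200 = "TSS200"
    UTR5 = "5UTR"
    FIRST_EXON = "1stExon"
    BODY = "Body"
    UTR3 = "3UTR"


class PredictionSource(str, enum.Enum):
    MIRDIP = "mirdip"
    STARMIR = "starmir"


class MirdipClass(enum.IntEnum):
    """Ordinal mirDIP confidence tier: low < medium < high < very_high."""

    LOW = 0
    MEDIUM = 1
    HIGH = 2
    VERY_HIGH = 3

    @classmethod
    def parse(cls, label: str) -> "MirdipClass":
        key = label.strip().lower().replace(" ", "_").replace("-", "_")
        mapping = {
            "low": cls.LOW,
            "medium": cls.MEDIUM,
            "high": cls.HIGH,
            "very_high": cls.VERY_HIGH,
        }
        if key not in mapping:
            raise ValidationError(
                f"unknown mirDIP class {label!r}; allowed: low, medium, high, very high"
            )
        return mapping[key]


class SiteRegion(str, enum.Enum):
    CDS_SEED = "CDS_seed"
    CDS_SEEDLESS = "CDS_seedless"
    OTHER = "other"

    @classmethod
    def parse(cls, label: str) -> "SiteRegion":
        key = label.strip().lower().replace("-", "_")
        mapping = {
            "cds_seed": cls.CDS_SEED,
            "cds_seedless": cls.CDS_SEEDLESS,
            "other": cls.OTHER,
        }
        if key not in mapping:
            raise ValidationError(
                f"unknown site region {label!r}; allowed: CDS_seed, CDS_seedless, other"
            )
        return mapping[key]


@dataclass(frozen=True)
class SampleAnnotation:
    sample_id: str
    cohort: CohortLabel
    tissue_class: TissueClass


@dataclass(frozen=True)
class ProbeAnnotation:
    """450k CpG probe annotated to a gene region at a GRCh37 position."""

    probe_id: str
    gene: str
    region: ProbeRegion
    position: int

    def __post_init__(self) -> None:
        if self.position <= 0:
            raise ValidationError(
                f"probe {self.probe_id}: position must be a positive 1-based coordinate"
            )


@dataclass(frozen=True)
class SurvivalRecord:
    sample_id: str
    endpoint: Endpoint
    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValidationError(
                f"survival record {self.sample_id}/{self.endpoint.value}: "
                f"time must be > 0, got {self.time}"
            )
        if self.event not in (0, 1):
            raise ValidationError(
                f"survival record {self.sample_id}/{self.endpoint.value}: "
                f"event must be 0 or 1, got {self.event}"
            )


@dataclass(frozen=True)
class TargetPrediction:
    """External miRNA->target evidence (mirDIP ordinal tier or StarMir site prob)."""

    mirna_id: str
    gene: str
    source: PredictionSource
    class_score: MirdipClass | None = None
    logit_prob: float | None = None
    site_region: SiteRegion | None = None

    def __post_init__(self) -> None:
        if self.source is PredictionSource.MIRDIP:
            if self.class_score is None or self.logit_prob is not None:
                raise ValidationError(
                    f"mirdip prediction {self.mirna_id}->{self.gene}: "
                    "requires class_score and no logit_prob"
                )
        else:
            if self.logit_prob is None or self.class_score is not None:
                raise ValidationError(
                    f"starmir prediction {self.mirna_id}->{self.gene}: "
                    "requires logit_prob and no class_score"
                )
            if not (0.0 <= self.logit_prob <= 1.0):
                raise ValidationError(
                    f"starmir prediction {self.mirna_id}->{self.gene}: "
                    f"logit_prob {self.logit_prob} outside [0, 1]"
                )


@dataclass(frozen=True)
class ExonDefinition:
    """An exon with GRCh37 coordinates and its role in the isoform contrast."""

    exon_id: str
    gene: str
    chromosome: str
    start: int
    end: int
    role: str  # "isoform_specific" or "constitutive"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValidationError(f"exon {self.exon_id}: start > end")
        if self.role not in ("isoform_specific", "constitutive"):
            raise ValidationError(f"exon {self.exon_id}: unknown role {self.role!r}")


#: The IL6R exon contrast of the transmembrane-isoform analysis (GRCh37/hg19).
IL6R_EXON9 = ExonDefinition("IL6R_Exon9", "IL6R", "chr1", 154426964, 154427057, "isoform_specific")
IL6R_EXON2 = ExonDefinition("IL6R_Exon2", "IL6R", "chr1", 154401672, 154401920, "constitutive")


class OmicsMatrix:
    """A feature x sample numeric matrix with a layer kind and missing mask.

    Thin validated wrapper over a pandas DataFrame (rows = features,
    columns = samples). ``layer`` is ``"expression"`` (finite log2 values)
    or ``"beta"`` (methylation proportions in [0, 1]).
    """

    LAYERS = ("expression", "beta")

    def __init__(self, values: pd.DataFrame, layer: str = "expression"):
        if layer not in self.LAYERS:
            raise ValidationError(f"unknown layer {layer!r}; allowed: {self.LAYERS}")
        if values.index.has_duplicates:
            dupes = values.index[values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate feature ids: {dupes}")
        if values.columns.has_duplicates:
            dupes = values.columns[values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        values = values.astype(float)
        if layer == "beta":
            bad = (values < 0) | (values > 1)
            if bad.any().any():
                r, c = np.argwhere(bad.to_numpy())[0]
                raise ValidationError(
                    f"beta value outside [0, 1] at feature {values.index[r]!r}, "
                    f"sample {values.columns[c]!r}: {values.iat[r, c]}"
                )
        else:
            inf = np.isinf(values.to_numpy())
            if inf.any():
                r, c = np.argwhere(inf)[0]
                raise ValidationError(
                    f"non-finite expression at feature {values.index[r]!r}, "
                    f"sample {values.columns[c]!r}"
                )
        self.values = values
        self.layer = layer

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    def row(self, feature_id: str) -> pd.Series:
        return self.values.loc[feature_id]

    def subset_samples(self, sample_ids: Sequence[str]) -> "OmicsMatrix":
        keep = [s for s in self.sample_ids if s in set(sample_ids)]
        return OmicsMatrix(self.values[keep], self.layer)

    def __repr__(self) -> str:  # pragma: no cover
        n_f, n_s = self.values.shape
        return f"OmicsMatrix(layer={self.layer!r}, {n_f} features x {n_s} samples)"


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_matrix(path: str | Path, layer: str = "expression") -> OmicsMatrix:
    """Read a feature x sample TSV (first column feature ids, header samples)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    dupes = pd.Index(header)[pd.Index(header).duplicated()].unique().tolist()
    if dupes:
        raise FormatError(f"{path}: duplicate sample ids in header: {dupes}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.index = raw.index.astype(str)
    raw.index.name = None
    values = pd.DataFrame(index=raw.index, columns=raw.columns, dtype=float)
    for col in raw.columns:
        cells = raw[col].str.strip()
        cells = cells.mask(cells.isin(["", NA_TOKEN]))
        numeric = pd.to_numeric(cells, errors="coerce")
        bad = numeric.isna() & cells.notna()
        if bad.any():
            feat = raw.index[bad.to_numpy()][0]
            raise ParseError(
                f"{path}: non-numeric cell at feature {feat!r}, sample {col!r}: "
                f"{raw.loc[feat, col]!r}"
            )
        values[col] = numeric
    return OmicsMatrix(values, layer=layer)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    """Write a matrix as TSV with ``NA`` for missing values (full precision)."""
    matrix.values.to_csv(path, sep="\t", na_rep=NA_TOKEN, index_label="feature_id",
                         float_format="%.17g")


def read_sample_annotations(path: str | Path) -> list[SampleAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "cohort", "tissue_class"], path)
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample_id")
    out = []
    for row in df.itertuples(index=False):
        try:
            tissue = TissueClass(row.tissue_class)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: unknown tissue_class {row.tissue_class!r} for {row.sample_id}"
            ) from exc
        out.append(SampleAnnotation(row.sample_id, CohortLabel(row.cohort), tissue))
    return out


def write_sample_annotations(annotations: Iterable[SampleAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.sample_id, a.cohort.code, a.tissue_class.value) for a in annotations],
        columns=["sample_id", "cohort", "tissue_class"],
    ).to_csv(path, sep="\t", index=False)


def read_probe_annotations(path: str | Path) -> list[ProbeAnnotation]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["probe_id", "gene", "region", "position"], path)
    if df.duplicated(subset=["probe_id", "gene"]).any():
        raise FormatError(f"{path}: duplicate (probe_id, gene)")
    out = []
    for row in df.itertuples(index=False):
        try:
            region = ProbeRegion(row.region)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: unknown region {row.region!r} for {row.probe_id}; "
                f"allowed: {[r.value for r in ProbeRegion]}"
            ) from exc
        out.append(ProbeAnnotation(row.probe_id, row.gene, region, int(row.position)))
    return out


def write_probe_annotations(annotations: Iterable[ProbeAnnotation], path: str | Path) -> None:
    pd.DataFrame(
        [(a.probe_id, a.gene, a.region.value, a.position) for a in annotations],
        columns=["probe_id", "gene", "region", "position"],
    ).to_csv(path, sep="\t", index=False)


def read_survival(path: str | Path) -> list[SurvivalRecord]:
    """Read survival endpoint records; one row per (sample, endpoint)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["sample_id", "endpoint", "time", "event"], path)
    if df.duplicated(subset=["sample_id", "endpoint"]).any():
        dup = df[df.duplicated(subset=["sample_id", "endpoint"])].iloc[0]
        raise FormatError(f"{path}: duplicate record for ({dup.sample_id}, {dup.endpoint})")
    out = []
    for row in df.itertuples(index=False):
        try:
            endpoint = Endpoint(row.endpoint)
        except ValueError as exc:
            raise ValidationError(
                f"{path}: unknown endpoint {row.endpoint!r}; allowed: OS, PFI"
            ) from exc
        try:
            event = int(row.event)
        except ValueError as exc:
            raise ValidationError(f"{path}: non-integer event {row.event!r}") from exc
        out.append(SurvivalRecord(row.sample_id, endpoint, float(row.time), event))
    return out


def write_survival(records: Iterable[SurvivalRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(r.sample_id, r.endpoint.value, repr(r.time), r.event) for r in records],
        columns=["sample_id", "endpoint", "time", "event"],
    ).to_csv(path, sep="\t", index=False)


def read_predictions(path: str | Path, source: str | PredictionSource) -> list[TargetPrediction]:
    """Read mirDIP (mirna, gene, class) or StarMir (mirna, exon, site_region, logit_prob)."""
    source = PredictionSource(source)
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: list[TargetPrediction] = []
    if source is PredictionSource.MIRDIP:
        _require_columns(df, ["mirna", "gene", "class"], path)
        for mirna, gene, cls in zip(df["mirna"], df["gene"], df["class"]):
            out.append(TargetPrediction(mirna, gene, source, class_score=MirdipClass.parse(cls)))
    else:
        _require_columns(df, ["mirna", "exon", "site_region", "logit_prob"], path)
        for row in df.itertuples(index=False):
            out.append(
                TargetPrediction(
                    row.mirna,
                    row.exon,
                    source,
                    logit_prob=float(row.logit_prob),
                    site_region=SiteRegion.parse(row.site_region),
                )
            )
    return out


def write_predictions(predictions: Iterable[TargetPrediction], path: str | Path) -> None:
    predictions = list(predictions)
    sources = {p.source for p in predictions}
    if len(sources) > 1:
        raise ValidationError("cannot mix mirdip and starmir predictions in one file")
    source = sources.pop() if sources else PredictionSource.MIRDIP
    if source is PredictionSource.MIRDIP:
        df = pd.DataFrame(
            [(p.mirna_id, p.gene, p.class_score.name.lower()) for p in predictions],
            columns=["mirna", "gene", "class"],
        )
    else:
        df = pd.DataFrame(
            [(p.mirna_id, p.gene, p.site_region.value, repr(p.logit_prob))
             for p in predictions],
            columns=["mirna", "exon", "site_region", "logit_prob"],
        )
    df.to_csv(path, sep="\t", index=False)


def _require_columns(df: pd.DataFrame, columns: list[str], path: str | Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required columns {missing}")
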