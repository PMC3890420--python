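"""Expression matrices, clinical tables, median-centering and cohort z-scores.

The analysis consumes a genes x samples matrix of either raw (strictly
positive) probe intensities or log2 median-centered ratios.  Raw intensities
are normalized per sample to the sample's median intensity,
``log2(intensity / median)``, so a value below zero means expression below the
sample median.  For the polarization likelihood each gene is then standardized
across the whole cohort (tumor and normal together) to a z-score.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panels import canonical_symbol

logger = logging.getLogger("immunopolar")

__all__ = [
    "ExpressionMatrix",
    "ClinicalTable",
    "ZMatrix",
    "ExpressionError",
    "read_matrix",
    "write_matrix",
    "read_clinical",
    "write_clinical",
    "log2_median_center",
    "zscore",
]

RAW = "raw"
LOG2_MEDIAN_RATIO = "log2_median_ratio"

PATHOLOGY_LABELS = ("ER+/PR+", "HER2+", "TN", "normal", "unknown")

CLINICAL_COLUMNS = ("sample", "pathology", "os_months", "os_event")


class ExpressionError(ValueError):
    """Invalid expression matrix or clinical table."""


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a scale flag.

    ``values`` is a DataFrame indexed by canonical gene symbol with sample ids
    as columns.  ``scale`` is ``"raw"`` (strictly positive intensities) or
    ``"log2_median_ratio"``.
    """

    values: pd.DataFrame
    scale: str = RAW

    def __post_init__(self) -> None:
        if self.scale not in (RAW, LOG2_MEDIAN_RATIO):
            raise ExpressionError(f"unknown scale {self.scale!r}")
        df = self.values.copy()
        df.index = [canonical_symbol(g) for g in df.index]
        if df.index.duplicated().any():
            dupes = sorted(set(df.index[df.index.duplicated()]))
            raise ExpressionError(f"duplicate gene symbols: {dupes}")
        if df.columns.duplicated().any():
            dupes = sorted(set(df.columns[df.columns.duplicated()]))
            raise ExpressionError(f"duplicate sample ids: {dupes}")
        try:
            df = df.astype(float)
        except (TypeError, ValueError) as exc:
            raise ExpressionError(f"non-numeric expression value: {exc}") from exc
        if df.isna().any().any():
            gene = df.index[df.isna().any(axis=1)][0]
            raise ExpressionError(f"missing value in gene row {gene!r}")
        if self.scale == RAW and (df.values <= 0).any():
            raise ExpressionError("raw intensities must be strictly positive")
        self.values = df

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


@dataclass
class ZMatrix:
    """Per-gene cohort z-scores plus the mean/sd used to standardize.

    Each nondegenerate gene row has mean 0 and unit sample standard deviation
    across the cohort; this is the data vector entering the polarization
    likelihood.
    """

    z: pd.DataFrame
    gene_mean: pd.Series
    gene_sd: pd.Series

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.z.index)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.z.columns)


@dataclass
class ClinicalTable:
    """Per-sample clinical annotations (pathology, overall survival, group)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table.copy()
        missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
        if missing:
            raise ExpressionError(f"clinical table missing columns: {missing}")
        if df["sample"].duplicated().any():
            raise ExpressionError("clinical table has duplicate sample ids")
        bad = ~df["pathology"].isin(PATHOLOGY_LABELS)
        if bad.any():
            raise ExpressionError(
                f"unknown pathology labels: {sorted(df.loc[bad, 'pathology'].unique())}"
            )
        df["os_months"] = df["os_months"].astype(float)
        if (df["os_months"] < 0).any():
            raise ExpressionError("survival times must be nonnegative")
        events = set(df["os_event"].astype(int).unique())
        if not events <= {0, 1}:
            raise ExpressionError("event indicator must be 0/1")
        df["os_event"] = df["os_event"].astype(int)
        if "group" not in df.columns:
            df["group"] = pd.NA
        self.table = df.reset_index(drop=True)

    @property
    def samples(self) -> tuple[str, ...]:
        return tuple(self.table["sample"])


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_matrix(
    path: str | Path,
    layout: str = "genes_by_samples",
    scale: str = RAW,
    sep: str | None = None,
) -> ExpressionMatrix:
    """Read a delimited expression matrix (TSV/CSV by extension).

    ``layout="samples_by_genes"`` transposes on read, so a transposed export
    loads to the same matrix.  Non-numeric cells and duplicate ids are
    reported as errors with the offending entry named.
    """
    path = Path(path)
    if layout not in ("genes_by_samples", "samples_by_genes"):
        raise ExpressionError(f"unknown layout {layout!r}")
    df = pd.read_csv(path, sep=sep or _sep_for(path), index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for j, col in enumerate(df.columns):
        coerced = pd.to_numeric(df[col], errors="coerce")
        if coerced.isna().any():
            i = int(np.argmax(coerced.isna().values))
            raise ExpressionError(
                f"{path.name}: non-numeric value {df[col].iloc[i]!r} at "
                f"row {df.index[i]!r}, column {col!r}"
            )
        df[col] = coerced
    if layout == "samples_by_genes":
        df = df.T
    return ExpressionMatrix(values=df, scale=scale)


def write_matrix(m: ExpressionMatrix, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    m.values.to_csv(path, sep=sep or _sep_for(path), index_label="gene")


def read_clinical(path: str | Path, sep: str | None = None) -> ClinicalTable:
    path = Path(path)
    df = pd.read_csv(path, sep=sep or _sep_for(path))
    df["sample"] = df["sample"].astype(str)
    return ClinicalTable(table=df)


def write_clinical(c: ClinicalTable, path: str | Path, sep: str | None = None) -> None:
    path = Path(path)
    c.table.to_csv(path, sep=sep or _sep_for(path), index=False)


def log2_median_center(m: ExpressionMatrix) -> ExpressionMatrix:
    """Per-sample median normalization: value -> log2(value / sample median).

    Every output column has median 0; a negative value means the gene is
    expressed below the sample's median.  Invariant to positive rescaling of
    a sample's intensities.
    """
    if m.scale != RAW:
        raise ExpressionError("log2_median_center expects a raw-intensity matrix")
    med = m.values.median(axis=0)
    out = np.log2(m.values / med)
    return ExpressionMatrix(values=out, scale=LOG2_MEDIAN_RATIO)


def zscore(m: ExpressionMatrix, ddof: int = 1) -> ZMatrix:
    """Standardize each gene across all samples of the cohort.

    Uses the sample standard deviation (``ddof=1``) by default.  Zero-variance
    genes are mapped to all-zero z-scores with a warning rather than an error.
    """
    if m.scale != LOG2_MEDIAN_RATIO:
        raise ExpressionError("zscore expects log2 median-centered ratios")
    if m.shape[1] < 2:
        raise ExpressionError("z-scoring needs at least 2 samples")
    mean = m.values.mean(axis=1)
    sd = m.values.std(axis=1, ddof=ddof)
    degenerate = sd == 0
    if degenerate.any():
        logger.warning(
            "zero-variance genes mapped to z=0: %s",
            ", ".join(m.values.index[degenerate]),
        )
    safe_sd = sd.where(~degenerate, 1.0)
    z = m.values.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[degenerate] = 0.0
    return ZMatrix(z=z, gene_mean=mean, gene_sd=sd)
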