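"""Core data containers and ingest transforms.

The whole pipeline operates on two tables:

* :class:`ExpressionMatrix` — a genes × samples real matrix, log2 scale
  after ingest (bulk RNA-seq FPKM-like values are log2(x+1)-transformed).
* :class:`CohortAnnotations` — per-sample clinical labels: tissue
  (tumor/normal), metastasis status, Gleason score, and censored overall /
  recurrence-free survival.

Both round-trip through plain TSV files so cohorts can be inspected and
produced by any tool.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionMatrix",
    "CohortAnnotations",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_annotations",
    "write_annotations",
    "log2_transform",
    "zscore_rows",
]

TISSUE_LEVELS = ("tumor", "normal")
METASTASIS_LEVELS = ("yes", "no", "unknown")

CLINICAL_COLUMNS = [
    "sample_id",
    "tissue",
    "metastasis",
    "gleason",
    "os_time",
    "os_event",
    "rfs_time",
    "rfs_event",
    "subtype",
]


def _check_unique(ids, kind: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression matrix.

    ``values[g, s]`` is the expression of ``gene_ids[g]`` in
    ``sample_ids[s]``. Values are expected to be on log2 scale after
    ingest (see :func:`log2_transform`); no NaNs are allowed.
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} inconsistent with "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains missing values")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def gene_index(self, genes) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def sample_index(self, samples) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in lookup]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return np.array([lookup[s] for s in samples], dtype=int)

    def subset(self, genes=None, samples=None) -> "ExpressionMatrix":
        """Restrict to the given genes and/or samples (order preserved)."""
        gi = self.gene_index(genes) if genes is not None else np.arange(self.n_genes)
        si = self.sample_index(samples) if samples is not None else np.arange(self.n_samples)
        return ExpressionMatrix(
            [self.gene_ids[i] for i in gi],
            [self.sample_ids[i] for i in si],
            self.values[np.ix_(gi, si)],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)


def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a TSV expression matrix (header of sample ids, gene ids in column 1).

    Values are returned untransformed. Duplicate gene or sample ids and
    non-numeric cells are hard errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    genes = [str(g) for g in df.index]
    samples = [str(s) for s in df.columns]
    _check_unique(genes, "gene")
    _check_unique(samples, "sample")
    raw = df.to_numpy()
    values = np.empty(raw.shape, dtype=float)
    for (r, c), cell in np.ndenumerate(raw):
        try:
            values[r, c] = float(cell)
        except (TypeError, ValueError):
            raise ValueError(
                f"non-numeric cell {cell!r} at gene {genes[r]!r}, sample {samples[c]!r}"
            ) from None
    if np.isnan(values).any():
        r, c = np.argwhere(np.isnan(values))[0]
        raise ValueError(f"missing value at gene {genes[r]!r}, sample {samples[c]!r}")
    return ExpressionMatrix(genes, samples, values)


def write_expression_matrix(m: ExpressionMatrix, path) -> None:
    """Write a TSV that :func:`read_expression_matrix` reads back bit-exactly."""
    df = m.to_frame()
    df.index.name = "gene_id"
    # repr() of a float round-trips exactly
    df.to_csv(path, sep="\t", float_format=lambda v: repr(float(v)))


def log2_transform(m: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(x + pseudocount) ingest transform for FPKM-like non-negative data.

    Raises if any value is negative — that usually means the matrix is
    already on log scale and the transform must be skipped.
    """
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    if (m.values < 0).any():
        raise ValueError(
            "negative expression values: input looks already log-transformed, "
            "skip log2_transform"
        )
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), np.log2(m.values + pseudocount))


def zscore_rows(m: ExpressionMatrix) -> ExpressionMatrix:
    """Standardize each gene row to mean 0, sample sd 1 (n−1 denominator)."""
    mu = m.values.mean(axis=1, keepdims=True)
    sd = m.values.std(axis=1, ddof=1, keepdims=True)
    bad = np.where(sd.ravel() == 0)[0]
    if bad.size:
        raise ValueError(f"zero-variance gene rows: {[m.gene_ids[i] for i in bad]}")
    return ExpressionMatrix(list(m.gene_ids), list(m.sample_ids), (m.values - mu) / sd)


@dataclass
class CohortAnnotations:
    """Per-sample clinical annotations backed by a pandas DataFrame.

    Columns: sample_id, tissue ∈ {tumor, normal}, metastasis ∈ {yes, no,
    unknown}, gleason (6–10 or NaN), os_time/rfs_time (months, NaN if
    missing), os_event/rfs_event (0/1 or NaN), subtype (optional integer).
    Missing clinical fields are NaN in memory and empty strings on disk.
    """

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.df.copy()
        if "sample_id" not in df.columns or "tissue" not in df.columns:
            raise ValueError("annotations need at least sample_id and tissue columns")
        for col in CLINICAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        df["sample_id"] = df["sample_id"].astype(str)
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample id: {dup!r}")
        bad = ~df["tissue"].isin(TISSUE_LEVELS)
        if bad.any():
            raise ValueError(f"invalid tissue label: {df.loc[bad, 'tissue'].iloc[0]!r}")
        df["metastasis"] = df["metastasis"].fillna("unknown")
        bad = ~df["metastasis"].isin(METASTASIS_LEVELS)
        if bad.any():
            raise ValueError(f"invalid metastasis label: {df.loc[bad, 'metastasis'].iloc[0]!r}")
        for col in ("gleason", "os_time", "os_event", "rfs_time", "rfs_event", "subtype"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        for col in ("os_time", "rfs_time"):
            if (df[col].dropna() < 0).any():
                raise ValueError(f"negative {col}")
        for col in ("os_event", "rfs_event"):
            vals = df[col].dropna()
            if not vals.isin([0, 1]).all():
                raise ValueError(f"{col} must be 0/1")
        self.df = df[CLINICAL_COLUMNS].reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def check_paired(self, m: ExpressionMatrix) -> None:
        """Every annotated sample must exist in the expression matrix."""
        missing = set(self.sample_ids) - set(m.sample_ids)
        if missing:
            raise ValueError(f"annotated samples absent from expression matrix: {sorted(missing)}")

    def samples_where(self, mask: pd.Series) -> list[str]:
        return list(self.df.loc[mask, "sample_id"])


def read_annotations(path) -> CohortAnnotations:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return CohortAnnotations(df)


def write_annotations(ann: CohortAnnotations, path) -> None:
    ann.df.to_csv(path, sep="\t", index=False, na_rep="")
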