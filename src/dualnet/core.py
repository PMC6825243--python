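"""Shared domain containers and basic expression-matrix operations.

Expression values are log2-scale intensities held in a genes x samples
matrix. A paired study couples one matrix per tissue with a design table
mapping each subject to exactly one sample in each tissue plus covariates
(age in years, sex and smoking status as binary codes).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FormatError",
    "ExpressionMatrix",
    "PairedDesign",
    "PairedExpressionStudy",
    "PValueVector",
    "read_expression_matrix",
    "write_expression_matrix",
    "read_design",
    "write_design",
    "bh_adjust",
    "filter_expressed",
    "standardize_genes",
]

#: fixed float format for every table written by the pipeline
FLOAT_FORMAT = "%.6g"

DESIGN_COLUMNS = ["subject_id", "sample_a", "sample_b", "age", "sex", "smoking"]


class FormatError(ValueError):
    """Raised when an input file violates the expected tabular format."""


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of log2-scale expression intensities.

    Invariants: unique gene and sample identifiers, all values finite.
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
                f"values shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        dup = _duplicates(self.gene_ids)
        if dup:
            raise FormatError(f"duplicate gene id(s): {', '.join(dup)}")
        dup = _duplicates(self.sample_ids)
        if dup:
            raise FormatError(f"duplicate sample id(s): {', '.join(dup)}")
        if not np.all(np.isfinite(self.values)):
            i, j = np.argwhere(~np.isfinite(self.values))[0]
            raise FormatError(
                f"non-finite value at gene {self.gene_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.sample_ids
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        """Return a new matrix restricted to ``gene_ids`` (in the given order)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in index]
        if missing:
            raise KeyError(f"unknown gene id(s): {', '.join(missing[:5])}")
        rows = [index[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows])

    def sample_columns(self, sample_ids: list[str]) -> np.ndarray:
        """Values for the requested samples, genes x len(sample_ids)."""
        index = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [index[s] for s in sample_ids]
        return self.values[:, cols]


@dataclass
class PairedDesign:
    """Subject-to-sample pairing with covariates.

    One row per subject: the subject id, its tissue-A and tissue-B sample
    ids, age (years), sex (0/1) and smoking status (0 = never, 1 = current).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise FormatError(f"design table missing column(s): {', '.join(missing)}")
        self.table = self.table.loc[:, DESIGN_COLUMNS].reset_index(drop=True)
        dup = _duplicates(self.table["subject_id"].astype(str))
        if dup:
            raise FormatError(f"duplicate subject id(s): {', '.join(dup)}")
        for col in ("sample_a", "sample_b"):
            dup = _duplicates(self.table[col].astype(str))
            if dup:
                raise FormatError(f"sample id(s) referenced twice in {col}: {', '.join(dup)}")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    @property
    def subject_ids(self) -> list[str]:
        return self.table["subject_id"].astype(str).tolist()

    @property
    def samples_a(self) -> list[str]:
        return self.table["sample_a"].astype(str).tolist()

    @property
    def samples_b(self) -> list[str]:
        return self.table["sample_b"].astype(str).tolist()

    def covariate_matrix(self) -> np.ndarray:
        """Subjects x 3 array of (age, sex, smoking)."""
        return self.table[["age", "sex", "smoking"]].to_numpy(dtype=float)


@dataclass
class PairedExpressionStudy:
    """Two tissue matrices over an identical gene list plus the pairing design."""

    matrix_a: ExpressionMatrix
    matrix_b: ExpressionMatrix
    design: PairedDesign

    def __post_init__(self) -> None:
        if self.matrix_a.gene_ids != self.matrix_b.gene_ids:
            raise ValueError("tissue matrices must share an identical, ordered gene list")
        for col, matrix, name in (
            ("sample_a", self.matrix_a, "tissue A"),
            ("sample_b", self.matrix_b, "tissue B"),
        ):
            known = set(matrix.sample_ids)
            unknown = [s for s in self.design.table[col].astype(str) if s not in known]
            if unknown:
                raise ValueError(
                    f"design references unknown {name} sample(s): {', '.join(unknown[:5])}"
                )

    @property
    def gene_ids(self) -> list[str]:
        return self.matrix_a.gene_ids

    @property
    def n_subjects(self) -> int:
        return self.design.n_subjects

    def paired_values(self) -> tuple[np.ndarray, np.ndarray]:
        """(A, B) arrays, genes x subjects, columns in design (subject) order."""
        a = self.matrix_a.sample_columns(self.design.samples_a)
        b = self.matrix_b.sample_columns(self.design.samples_b)
        return a, b

    def subset_genes(self, gene_ids: list[str]) -> "PairedExpressionStudy":
        return PairedExpressionStudy(
            self.matrix_a.subset_genes(gene_ids),
            self.matrix_b.subset_genes(gene_ids),
            self.design,
        )


@dataclass
class PValueVector:
    """Raw p-values with their Benjamini-Hochberg adjusted companions."""

    ids: list[str]
    p: np.ndarray
    q: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if self.q is None:
            self.q = bh_adjust(self.p)
        else:
            self.q = np.asarray(self.q, dtype=float)


def _duplicates(items) -> list[str]:
    seen: set[str] = set()
    dup: list[str] = []
    for x in items:
        if x in seen and x not in dup:
            dup.append(x)
        seen.add(x)
    return dup


# ---------------------------------------------------------------------------
# I/O: tab-separated, UTF-8, '.' decimal separator, no quoting.

def read_expression_matrix(path) -> ExpressionMatrix:
    """Read a genes x samples TSV (first column ``gene_id``, header of sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()].tolist()
        raise FormatError(f"duplicate sample id(s): {', '.join(map(str, dup))}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"duplicate gene id(s): {', '.join(map(str, dup))}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = coerced.isna() & df[col].notna()
            row = df.index[bad.to_numpy().argmax()]
            raise FormatError(
                f"non-numeric value at gene {row!r}, sample {col!r}"
            )
    if df.isna().any().any():
        j = int(np.argwhere(df.isna().to_numpy())[0][1])
        i = int(np.argwhere(df.isna().to_numpy())[0][0])
        raise FormatError(
            f"missing value at gene {df.index[i]!r}, sample {df.columns[j]!r}"
        )
    return ExpressionMatrix(df.index.tolist(), df.columns.tolist(), df.to_numpy(dtype=float))


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    """Write a matrix as TSV with 6-significant-digit floats (deterministic)."""
    matrix.to_frame().to_csv(
        path, sep="\t", index_label="gene_id", float_format=FLOAT_FORMAT
    )


def read_design(path) -> PairedDesign:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "sample_a": str, "sample_b": str})
    return PairedDesign(df)


def write_design(design: PairedDesign, path) -> None:
    design.table.to_csv(path, sep="\t", index=False, float_format=FLOAT_FORMAT)


# ---------------------------------------------------------------------------
# Elementary statistics shared across the pipeline.

def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1, monotone).

    The result is invariant to the input order and satisfies ``q >= p``
    element-wise.
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def filter_expressed(matrix: ExpressionMatrix, threshold: float = 3.0) -> ExpressionMatrix:
    """Keep genes whose median log2 intensity across samples is strictly > threshold.

    The comparison is strict, so a gene sitting exactly at the threshold is
    dropped. An empty result is legal but warned about.
    """
    medians = np.median(matrix.values, axis=1)
    keep = medians > threshold
    if not keep.any():
        warnings.warn(
            f"no gene has median expression > {threshold}; returning an empty matrix",
            stacklevel=2,
        )
    genes = [g for g, k in zip(matrix.gene_ids, keep) if k]
    return ExpressionMatrix(genes, list(matrix.sample_ids), matrix.values[keep])


def standardize_genes(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene standardization to mean 0 and sample SD 1 (n-1 denominator)."""
    mean = matrix.values.mean(axis=1, keepdims=True)
    sd = matrix.values.std(axis=1, ddof=1, keepdims=True)
    zero = np.flatnonzero(sd.ravel() == 0)
    if zero.size:
        names = ", ".join(matrix.gene_ids[i] for i in zero[:5])
        raise ValueError(f"zero-variance gene(s) cannot be standardized: {names}")
    return ExpressionMatrix(
        list(matrix.gene_ids), list(matrix.sample_ids), (matrix.values - mean) / sd
    )
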