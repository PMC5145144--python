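"""Reading, validation, isoform collapsing and normalization of stage-profiled
expression tables.

The central container is :class:`ExpressionMatrix`: one RPKM profile per gene
over an ordered developmental :class:`StageAxis` (default: the seven
*C. elegans* whole-organism stages EE, LE, L1, L2, L3, L4, YA).  Expression
tables arrive as tab-separated text with an ID column (or an isoform-ID plus
gene-ID pair of columns) followed by one column per stage; ``#`` lines are
comments.  Isoform-level tables are collapsed to gene level by unweighted
arithmetic averaging of the isoform profiles.

Constant (including all-zero) profiles are never silently transformed:
:func:`normalize_profiles` returns them unscaled together with an explicit
flagged-gene list, and downstream correlation/clustering code excludes them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

DEFAULT_STAGES: tuple[str, ...] = ("EE", "LE", "L1", "L2", "L3", "L4", "YA")

__all__ = [
    "DEFAULT_STAGES",
    "StageAxis",
    "IsoformTable",
    "ExpressionMatrix",
    "ExpressionIOError",
    "StageMismatchError",
    "DuplicateIDError",
    "InvalidValueError",
    "read_expression_table",
    "write_expression_table",
    "collapse_isoforms",
    "normalize_profiles",
    "read_gene_list",
    "write_gene_list",
]


class ExpressionIOError(ValueError):
    """Base class for expression-table validation failures."""


class StageMismatchError(ExpressionIOError):
    """Header stage columns do not match the expected stage axis."""


class DuplicateIDError(ExpressionIOError):
    """An isoform or gene identifier occurs on more than one row."""


class InvalidValueError(ExpressionIOError):
    """A value is negative, non-numeric or non-finite."""


@dataclass(frozen=True)
class StageAxis:
    """Ordered developmental stage labels.

    The order is developmental time order; the trend filter interprets the
    final ``tail_k`` labels as the post-ciliogenesis tail, so at least four
    stages are required (a three-stage tail plus one earlier stage).
    """

    labels: tuple[str, ...] = DEFAULT_STAGES

    def __post_init__(self) -> None:
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(labels) < 4:
            raise ValueError("stage axis needs at least 4 stages")
        if len(set(labels)) != len(labels):
            raise ValueError("stage labels must be unique")

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self):
        return iter(self.labels)


def _validate_values(values: pd.DataFrame, require_nonnegative: bool = True) -> None:
    arr = values.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        bad = values.columns[
            [not np.issubdtype(d, np.number) for d in values.dtypes]
        ].tolist()
        raise InvalidValueError(f"non-numeric values in stage columns {bad}")
    if not np.isfinite(arr).all():
        raise InvalidValueError("non-finite (NaN/inf) expression values")
    if require_nonnegative and (arr < 0).any():
        raise InvalidValueError("negative expression values")


@dataclass
class IsoformTable:
    """Isoform-level expression rows: (isoform_id, gene_id, RPKM per stage).

    ``data`` is indexed by isoform_id with a ``gene_id`` column followed by
    one column per stage label.
    """

    data: pd.DataFrame
    stage_axis: StageAxis = field(default_factory=StageAxis)

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        expected = ["gene_id", *self.stage_axis.labels]
        if cols != expected:
            raise StageMismatchError(
                f"isoform table columns {cols} != expected {expected}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateIDError(f"duplicate isoform IDs: {dups}")
        _validate_values(self.data[list(self.stage_axis.labels)])

    @property
    def n_isoforms(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data[list(self.stage_axis.labels)].to_numpy(dtype=float)


@dataclass
class ExpressionMatrix:
    """Gene-level RPKM profiles: one row per gene, one column per stage.

    ``nonnegative=False`` relaxes the RPKM sign check for derived matrices
    (z-scored profiles are signed).
    """

    data: pd.DataFrame
    stage_axis: StageAxis = field(default_factory=StageAxis)
    nonnegative: bool = True

    def __post_init__(self) -> None:
        cols = list(self.data.columns)
        if cols != list(self.stage_axis.labels):
            raise StageMismatchError(
                f"matrix columns {cols} != stage axis {list(self.stage_axis.labels)}"
            )
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateIDError(f"duplicate gene IDs: {dups}")
        _validate_values(self.data, require_nonnegative=self.nonnegative)

    @property
    def genes(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def n_genes(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def profile(self, gene_id: str) -> np.ndarray:
        return self.data.loc[gene_id].to_numpy(dtype=float)

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in self.genes if g in set(genes)]
        return ExpressionMatrix(
            self.data.loc[genes].copy(), self.stage_axis, self.nonnegative
        )


def read_expression_table(
    path: str | Path,
    has_gene_column: bool = False,
    stage_axis: StageAxis | None = None,
) -> IsoformTable | ExpressionMatrix:
    """Read a tab-separated expression table.

    With ``has_gene_column=True`` the first two columns are isoform_id and
    gene_id and an :class:`IsoformTable` is returned; otherwise the first
    column is gene_id and an :class:`ExpressionMatrix` is returned.  The
    header must name the stages of ``stage_axis`` in order after the ID
    column(s); missing, extra or reordered stage columns, duplicate IDs and
    negative/non-numeric values each raise a distinct error.
    """
    stage_axis = stage_axis or StageAxis()
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str}, header=0)
    n_id = 2 if has_gene_column else 1
    header_stages = list(df.columns[n_id:])
    if header_stages != list(stage_axis.labels):
        raise StageMismatchError(
            f"{path}: stage columns {header_stages} != expected "
            f"{list(stage_axis.labels)}"
        )
    # re-parse stage columns as floats, surfacing non-numeric entries
    for col in header_stages:
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError) as exc:
            raise InvalidValueError(f"{path}: non-numeric value in column {col}: {exc}")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    df.index.name = "isoform_id" if has_gene_column else "gene_id"
    if has_gene_column:
        df = df.rename(columns={df.columns[0]: "gene_id"})
        df["gene_id"] = df["gene_id"].astype(str)
        return IsoformTable(df, stage_axis)
    return ExpressionMatrix(df, stage_axis)


def write_expression_table(
    table: IsoformTable | ExpressionMatrix, path: str | Path
) -> None:
    """Write a table back in the input dialect (TSV, header row of stages)."""
    table.data.to_csv(path, sep="\t")


def collapse_isoforms(table: IsoformTable) -> ExpressionMatrix:
    """Average isoform RPKM profiles into one profile per gene.

    The average is the unweighted arithmetic mean over a gene's isoforms at
    each stage.  Gene order follows first appearance in the isoform table.
    """
    if table.n_isoforms == 0:
        raise ExpressionIOError("cannot collapse an empty isoform table")
    stage_cols = list(table.stage_axis.labels)
    collapsed = (
        table.data.groupby("gene_id", sort=False)[stage_cols].mean().astype(float)
    )
    collapsed.index.name = "gene_id"
    return ExpressionMatrix(collapsed, table.stage_axis)


def normalize_profiles(
    matrix: ExpressionMatrix,
    method: Literal["max", "zscore"] = "max",
) -> tuple[ExpressionMatrix, list[str]]:
    """Normalize each gene profile; constant profiles are flagged, not scaled.

    ``max``: divide by the profile maximum, so the peak stage has value 1.
    ``zscore``: centre to mean 0, scale to sd 1 (ddof=0).

    Returns the normalized matrix and the list of genes whose profile is
    constant (including all-zero); those rows are returned unchanged and
    must be excluded from correlation and clustering downstream.
    """
    if method not in ("max", "zscore"):
        raise ValueError(f"unknown normalization method: {method!r}")
    vals = matrix.values.copy()
    constant = np.ptp(vals, axis=1) == 0
    flagged = [g for g, c in zip(matrix.genes, constant) if c]
    ok = ~constant
    if method == "max":
        peak = vals[ok].max(axis=1, keepdims=True)
        vals[ok] = vals[ok] / peak
    else:
        mu = vals[ok].mean(axis=1, keepdims=True)
        sd = vals[ok].std(axis=1, keepdims=True)
        vals[ok] = (vals[ok] - mu) / sd
    out = pd.DataFrame(vals, index=matrix.data.index, columns=matrix.data.columns)
    result = ExpressionMatrix(out, matrix.stage_axis, nonnegative=(method == "max"))
    return result, flagged


def read_gene_list(path: str | Path) -> list[str]:
    """Read a one-ID-per-line gene list; ``#`` comments and blanks ignored."""
    genes: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line.split("\t")[0])
    return genes


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in genes))
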