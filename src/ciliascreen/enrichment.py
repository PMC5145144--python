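"""Annotation filters and 2x2 enrichment statistics.

Candidate sets from the co-expression screen are validated against external
annotations: presence of a human ortholog, evidence-hit counts in a ciliary
database (the published criterion is strictly more than 12 hits), and
chemoreceptor (serpentine-receptor) class membership.  Enrichment of an
annotation within a candidate set relative to the genome is quantified by
fold enrichment ``(k/m) / (K/N)`` and a chi-squared test on the 2x2
contingency table without continuity correction; small expected cell counts
are reported as a warning rather than silently corrected.

The hypergeometric upper tail used to score bait content of dendrogram
subtrees also lives here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "Contingency2x2",
    "EnrichmentResult",
    "ZeroMarginalError",
    "read_annotation_table",
    "write_annotation_table",
    "filter_by_annotation",
    "fold_enrichment",
    "chi_squared_2x2",
    "hypergeom_p",
    "contingency_from_sets",
    "enrichment_report_row",
]

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("ortholog_flag", "cildb_hits", "chemoreceptor_flag")


class ZeroMarginalError(ValueError):
    """A row or column marginal of the 2x2 table is zero; chi-squared undefined."""


@dataclass(frozen=True)
class Contingency2x2:
    """Counts: a = in-set & annotated, b = in-set & not, c = out & annotated,
    d = out & not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and v >= 0):
                raise ValueError(f"cell {name} must be a non-negative integer")
        if self.n == 0:
            raise ValueError("empty contingency table")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass(frozen=True)
class EnrichmentResult:
    fold: float
    chi2: float
    p: float
    expected_min: float
    small_expected: bool  # True when any expected cell count < 5


def read_annotation_table(path: str | Path) -> pd.DataFrame:
    """Read the annotation TSV: gene_id, ortholog_flag, cildb_hits,
    chemoreceptor_flag."""
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0, dtype={0: str})
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"annotation table missing columns: {missing}")
    if df.index.has_duplicates:
        raise ValueError("duplicate gene IDs in annotation table")
    df["ortholog_flag"] = df["ortholog_flag"].astype(bool)
    df["chemoreceptor_flag"] = df["chemoreceptor_flag"].astype(bool)
    df["cildb_hits"] = df["cildb_hits"].astype(int)
    if (df["cildb_hits"] < 0).any():
        raise ValueError("negative cildb_hits")
    return df


def write_annotation_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")


def filter_by_annotation(
    genes: Iterable[str],
    table: pd.DataFrame,
    criterion: str,
    min_hits: int = 12,
) -> set[str]:
    """Subset of ``genes`` satisfying an annotation criterion.

    criterion: ``"ortholog"`` (has a human ortholog), ``"cildb"``
    (strictly more than ``min_hits`` evidence hits) or ``"chemoreceptor"``.
    Genes absent from the table are dropped with a logged warning.
    """
    if min_hits < 0:
        raise ValueError("min_hits must be >= 0")
    genes = set(genes)
    known = genes & set(table.index)
    missing = genes - known
    if missing:
        logger.warning(
            "%d genes absent from annotation table dropped (e.g. %s)",
            len(missing),
            sorted(missing)[:3],
        )
    sub = table.loc[sorted(known)]
    if criterion == "ortholog":
        keep = sub.index[sub["ortholog_flag"]]
    elif criterion == "cildb":
        keep = sub.index[sub["cildb_hits"] > min_hits]
    elif criterion == "chemoreceptor":
        keep = sub.index[sub["chemoreceptor_flag"]]
    else:
        raise ValueError(f"unknown criterion: {criterion!r}")
    return set(keep)


def fold_enrichment(k: int, m: int, K: int, N: int) -> float:
    """Fold enrichment of an annotation in a set: (k/m) / (K/N)."""
    if m <= 0 or K <= 0 or N <= 0:
        raise ValueError("m, K and N must be positive")
    if k > m or K > N or k > K:
        raise ValueError("infeasible counts")
    return (k / m) / (K / N)


def chi_squared_2x2(table: Contingency2x2) -> EnrichmentResult:
    """Pearson chi-squared test of independence on a 2x2 table, 1 df,
    no continuity correction.

    Equivalent to ``chi2 = N (ad - bc)^2 / ((a+b)(c+d)(a+c)(b+d))``.  Raises
    :class:`ZeroMarginalError` when a marginal is zero.  ``expected_min`` is
    the smallest expected cell count; ``small_expected`` flags < 5.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    obs = np.array([[a, b], [c, d]], dtype=float)
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        raise ZeroMarginalError("zero marginal; chi-squared statistic undefined")
    chi2, p, _, expected = stats.chi2_contingency(obs, correction=False)
    p = float(min(max(p, np.nextafter(0.0, 1.0)), 1.0))
    fold = fold_enrichment(a, a + b, a + c, table.n)
    expected_min = float(expected.min())
    return EnrichmentResult(
        fold=float(fold),
        chi2=float(chi2),
        p=p,
        expected_min=expected_min,
        small_expected=expected_min < 5.0,
    )


def hypergeom_p(k: int, m: int, K: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, m).

    Probability of seeing at least ``k`` annotated genes when ``m`` genes are
    drawn without replacement from ``N`` of which ``K`` are annotated.
    Computed via the stable survival function; never returns exactly 0.
    """
    if not (0 <= K <= N and 0 <= m <= N):
        raise ValueError("need 0 <= K <= N and 0 <= m <= N")
    if not 0 <= k <= min(m, K):
        raise ValueError("k must satisfy 0 <= k <= min(m, K)")
    if k == 0:
        return 1.0
    p = float(stats.hypergeom.sf(k - 1, N, K, m))
    return min(max(p, float(np.nextafter(0.0, 1.0))), 1.0)


def contingency_from_sets(
    candidates: Iterable[str],
    annotated: Iterable[str],
    universe: Iterable[str],
) -> Contingency2x2:
    """Build the 2x2 table (candidate membership x annotation) over a
    gene universe."""
    universe = set(universe)
    candidates = set(candidates) & universe
    annotated = set(annotated) & universe
    a = len(candidates & annotated)
    b = len(candidates - annotated)
    c = len(annotated - candidates)
    d = len(universe) - a - b - c
    return Contingency2x2(a, b, c, d)


def enrichment_report_row(
    criterion: str, table: Contingency2x2, result: EnrichmentResult
) -> dict:
    """One row of the enrichment report TSV."""
    return {
        "criterion": criterion,
        "k": table.a,
        "m": table.a + table.b,
        "K": table.a + table.c,
        "N": table.n,
        "fold": result.fold,
        "chi2": result.chi2,
        "p": result.p,
        "small_expected": result.small_expected,
    }
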