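"""Bait-based Pearson correlation screen with min-p retention.

Every gene in the expression matrix is correlated against each bait profile
(Pearson product-moment correlation over the ordered stage columns) and a
two-sided p-value is attached to each test from the t statistic
``t = r * sqrt((n - 2) / (1 - r^2))`` on ``n - 2`` degrees of freedom, where
``n`` is the number of stage columns.  Because a gene is interesting if it
tracks *any* bait, each gene retains the smallest of its per-bait p-values.
Bait genes exclude their own self-test, so they retain what would otherwise
be the second-smallest p-value — this avoids the circularity of a bait
selecting itself with r = 1.

Constant profiles have undefined correlation and are carried through with an
``excluded`` flag rather than NaN.  A p-value of exactly zero is never
produced: perfect correlations clamp to the smallest positive float, which
keeps downstream log-transforms and rankings stable.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .expression_io import ExpressionMatrix, read_gene_list

__all__ = [
    "BaitSet",
    "ConstantProfileError",
    "BaitError",
    "pearson_r",
    "p_from_r",
    "bait_screen",
    "threshold_candidates",
    "load_bait_set",
    "write_screen_results",
    "SELF_ONLY_REASON",
    "CONSTANT_REASON",
    "P_FLOOR",
]

#: Smallest admissible retained p-value (p = 0 is forbidden by contract).
P_FLOOR = float(np.nextafter(0.0, 1.0))

CONSTANT_REASON = "constant profile"
SELF_ONLY_REASON = "single-bait self test"


class ConstantProfileError(ValueError):
    """Pearson correlation requested for a constant (zero-variance) profile."""


class BaitError(ValueError):
    """Bait set invalid or inconsistent with the expression matrix."""


@dataclass(frozen=True)
class BaitSet:
    """An ordered, duplicate-free set of reference ("bait") gene IDs."""

    gene_ids: tuple[str, ...]
    name: str = "baits"

    def __post_init__(self) -> None:
        ids = tuple(str(g) for g in self.gene_ids)
        object.__setattr__(self, "gene_ids", ids)
        if not ids:
            raise BaitError("bait set is empty")
        if len(set(ids)) != len(ids):
            raise BaitError("duplicate bait IDs")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __iter__(self):
        return iter(self.gene_ids)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in set(self.gene_ids)


def load_bait_set(path: str | Path, name: str | None = None) -> BaitSet:
    """Load a bait set from a one-ID-per-line file ('#' comments allowed)."""
    path = Path(path)
    return BaitSet(tuple(read_gene_list(path)), name=name or path.stem)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length profiles.

    Raises :class:`ConstantProfileError` for zero-variance input; callers are
    expected to pre-flag constant profiles rather than catch this.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("profiles must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0.0:
        raise ConstantProfileError("correlation undefined for constant profile")
    return float(_snap_unit(np.clip((xc @ yc) / denom, -1.0, 1.0)))


def p_from_r(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation on ``n`` observations.

    Uses the exact t-distribution of r under the bivariate-normal null with
    ``n - 2`` degrees of freedom.  ``|r| = 1`` maps to the smallest positive
    representable float rather than zero.
    """
    if n < 3:
        raise ValueError("p_from_r requires n >= 3")
    if not -1.0 <= r <= 1.0:
        raise ValueError("|r| must be <= 1")
    if abs(r) == 1.0:
        return P_FLOOR
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return float(min(max(p, P_FLOOR), 1.0))


def _snap_unit(r):
    """Snap correlations within 1e-12 of +/-1 to exactly +/-1.

    Exactly collinear profiles can come out at 1 - O(eps) in floating
    arithmetic; snapping makes the p-floor clamp contract ("|r| = 1 never
    yields p = 0") reachable and is far below any resolvable effect size.
    """
    return np.where(np.abs(r) > 1.0 - 1e-12, np.sign(r), r)


def _standardize_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-standardize to unit norm; returns (z, constant_mask)."""
    centred = values - values.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centred, axis=1)
    constant = norms == 0.0
    safe = np.where(constant, 1.0, norms)
    return centred / safe[:, None], constant


def bait_screen(matrix: ExpressionMatrix, baits: BaitSet) -> pd.DataFrame:
    """Screen every gene against every bait; retain the minimum p per gene.

    Returns a DataFrame indexed by gene_id with columns ``best_bait``,
    ``r_best``, ``p_retained``, ``is_bait``, ``excluded``,
    ``excluded_reason``, in the matrix's gene order.

    Bait rows exclude their self-test (the "second-smallest" rule); ties
    among equal bait p-values resolve to the earliest bait in the bait-set
    order.  Constant-profile genes are flagged excluded with ``p_retained``
    unset (NaN).  A single-bait screen marks the bait's own row excluded,
    since no non-self test exists for it.
    """
    missing = [b for b in baits if b not in set(matrix.genes)]
    if missing:
        raise BaitError(f"baits absent from matrix: {missing}")
    if len(matrix.stage_axis) < 3:
        raise ValueError("need at least 3 stage columns")

    genes = matrix.genes
    n_stages = len(matrix.stage_axis)
    z, constant = _standardize_rows(matrix.values)
    bait_idx = [genes.index(b) for b in baits]
    zb = z[bait_idx]
    bait_constant = constant[bait_idx]

    # genes x baits correlation, then two-sided t p-values
    r = _snap_unit(np.clip(z @ zb.T, -1.0, 1.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n_stages - 2) / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * stats.t.sf(np.abs(t), df=n_stages - 2)
    p = np.clip(p, P_FLOOR, 1.0)

    # invalid tests: constant gene or constant bait, and self-tests
    p = np.where(bait_constant[None, :], np.inf, p)
    gene_pos = {g: i for i, g in enumerate(genes)}
    is_bait = np.zeros(len(genes), dtype=bool)
    for col, b in enumerate(baits):
        row = gene_pos[b]
        is_bait[row] = True
        p[row, col] = np.inf

    best_col = np.argmin(p, axis=1)  # first minimum: bait-list-order tiebreak
    rows = np.arange(len(genes))
    p_best = p[rows, best_col]
    r_best = r[rows, best_col]

    no_valid_test = ~np.isfinite(p_best)
    excluded = constant | no_valid_test
    reasons = np.where(
        constant, CONSTANT_REASON, np.where(no_valid_test, SELF_ONLY_REASON, "")
    )
    bait_names = np.asarray(list(baits), dtype=object)
    out = pd.DataFrame(
        {
            "best_bait": np.where(excluded, "", bait_names[best_col]),
            "r_best": np.where(excluded, np.nan, r_best),
            "p_retained": np.where(excluded, np.nan, p_best),
            "is_bait": is_bait,
            "excluded": excluded,
            "excluded_reason": reasons,
        },
        index=pd.Index(genes, name="gene_id"),
    )
    return out


def threshold_candidates(
    results: pd.DataFrame,
    alpha: float,
    include_baits: bool = True,
) -> set[str]:
    """Genes with retained p strictly below ``alpha``; excluded genes never pass.

    Baits are included by default (they carry an ``is_bait`` marker in the
    results table); ``include_baits=False`` restricts to prey genes.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must be in (0, 1]")
    ok = (~results["excluded"]) & (results["p_retained"] < alpha)
    if not include_baits:
        ok &= ~results["is_bait"]
    return set(results.index[ok])


def write_screen_results(results: pd.DataFrame, path: str | Path) -> None:
    """Write screen results as TSV sorted by retained p ascending."""
    ordered = results.sort_values(
        "p_retained", na_position="last", kind="mergesort"
    )
    ordered.to_csv(path, sep="\t")
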