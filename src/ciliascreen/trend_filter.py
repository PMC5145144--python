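"""Peak-relative expression-decay ("cilia-like trend") filter.

Ciliogenesis in *C. elegans* is confined to a late-embryonic window, so
cilium-building transcripts peak around LE/L1 and decay afterwards.  The
filter formalizes that as: expression in each of the last ``tail_k``
developmental stages must be at least ``fold``-fold below the profile's peak
(the peak is taken over *all* stages, so a gene peaking inside the tail
trivially fails).  The comparison is non-strict — exactly ``fold``-fold
reduction passes — and all-zero profiles fail because they have no peak.

``tail_mode`` exposes the aggregation over tail stages: ``"all"`` (default,
every tail stage must satisfy the reduction) or ``"any"`` (at least one).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .expression_io import ExpressionMatrix

__all__ = ["TrendConfig", "TrendVerdict", "passes_trend", "apply_trend_filter"]


@dataclass(frozen=True)
class TrendConfig:
    """Parameters of the decay filter.

    fold
        Required peak-to-tail fold reduction (default 10, i.e. tail values
        must be <= peak / 10).
    tail_k
        Number of terminal stages forming the post-ciliogenesis tail
        (default 3: L3, L4 and YA on the default axis).
    tail_mode
        "all": every tail stage must pass; "any": one suffices.
    """

    fold: float = 10.0
    tail_k: int = 3
    tail_mode: Literal["all", "any"] = "all"

    def __post_init__(self) -> None:
        if self.fold < 1.0:
            raise ValueError("fold must be >= 1")
        if self.tail_k < 1:
            raise ValueError("tail_k must be >= 1")
        if self.tail_mode not in ("all", "any"):
            raise ValueError(f"unknown tail_mode: {self.tail_mode!r}")


@dataclass(frozen=True)
class TrendVerdict:
    gene_id: str
    passed: bool
    peak_stage: str
    peak_value: float
    tail_max: float


def passes_trend(
    profile: Sequence[float],
    config: TrendConfig = TrendConfig(),
    stage_labels: Sequence[str] | None = None,
    gene_id: str = "",
) -> TrendVerdict:
    """Evaluate the decay filter on one stage profile."""
    values = np.asarray(profile, dtype=float)
    if values.ndim != 1 or values.size <= config.tail_k:
        raise ValueError("profile must be 1-D and longer than tail_k")
    if (values < 0).any():
        raise ValueError("profile values must be non-negative")
    labels = (
        list(stage_labels)
        if stage_labels is not None
        else [f"s{i}" for i in range(values.size)]
    )
    peak_idx = int(np.argmax(values))
    peak = float(values[peak_idx])
    tail = values[-config.tail_k :]
    tail_max = float(tail.max())
    if peak == 0.0:
        passed = False
    else:
        ok = tail <= peak / config.fold
        passed = bool(ok.all() if config.tail_mode == "all" else ok.any())
    return TrendVerdict(gene_id, passed, labels[peak_idx], peak, tail_max)


def apply_trend_filter(
    matrix: ExpressionMatrix,
    config: TrendConfig = TrendConfig(),
) -> tuple[set[str], pd.DataFrame]:
    """Apply the filter to every gene; return (pass set, verdict table)."""
    if config.tail_k >= len(matrix.stage_axis):
        raise ValueError("tail_k must be smaller than the stage count")
    labels = list(matrix.stage_axis.labels)
    verdicts = [
        passes_trend(matrix.profile(g), config, labels, gene_id=g)
        for g in matrix.genes
    ]
    table = pd.DataFrame(
        {
            "passed": [v.passed for v in verdicts],
            "peak_stage": [v.peak_stage for v in verdicts],
            "peak_value": [v.peak_value for v in verdicts],
            "tail_max": [v.tail_max for v in verdicts],
        },
        index=pd.Index(matrix.genes, name="gene_id"),
    )
    return set(table.index[table["passed"]]), table


def write_trend_verdicts(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t")
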