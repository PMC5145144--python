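"""End-to-end orchestration of the temporal co-expression screen.

``run_screen_pipeline`` chains the stages of the ciliary-gene screen:

    read/simulate -> collapse isoforms -> bait correlation screen ->
    p-value threshold -> developmental trend filter -> max-normalize ->
    hierarchical clustering -> bait-cluster ("cluster 1") extraction ->
    annotation filters + enrichment -> optional promoter motif scan

``run_chemo_pipeline`` is the post-ciliogenesis variant: a single
chemosensory bait, a looser p threshold (default 1e-3), serpentine-receptor
enrichment and E-box presence counting in candidate promoters.

Both return a :class:`RunReport` whose stage counts are monotone
non-increasing along the filtering chain, echo the full configuration, and
are byte-identical across runs with the same config and seed (the analysis
itself is deterministic; the seed only drives the synthetic generators).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import pandas as pd
import yaml

from . import __version__
from .clustering import (
    ClusterSet,
    NoSubtreeError,
    extract_bait_cluster,
    hierarchical_cluster,
    pairwise_distances,
    write_cluster_assignments,
)
from .correlation_screen import (
    BaitSet,
    bait_screen,
    load_bait_set,
    threshold_candidates,
    write_screen_results,
)
from .enrichment import (
    ZeroMarginalError,
    chi_squared_2x2,
    contingency_from_sets,
    enrichment_report_row,
    filter_by_annotation,
    read_annotation_table,
)
from .expression_io import (
    DEFAULT_STAGES,
    ExpressionMatrix,
    StageAxis,
    collapse_isoforms,
    normalize_profiles,
    read_expression_table,
    write_expression_table,
    write_gene_list,
)
from .motif_scan import (
    IUPACMotif,
    PromoterSet,
    extract_promoters,
    genes_with_motif,
    motif_enrichment,
    read_promoter_fasta,
)
from .synthetic_data import (
    SimulationConfig,
    default_archetypes,
    simulate_annotations,
    simulate_matrix,
    simulate_promoters,
    truth_bait_set,
)
from .trend_filter import TrendConfig, apply_trend_filter, write_trend_verdicts

__all__ = [
    "PipelineConfig",
    "RunReport",
    "PipelineError",
    "run_screen_pipeline",
    "run_chemo_pipeline",
    "packaged_bait_path",
]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def packaged_bait_path(which: str = "ciliary") -> Path:
    """Path to a packaged bait fixture: 'ciliary' (41 genes) or
    'chemosensory'."""
    fname = {
        "ciliary": "ciliary_baits.txt",
        "chemosensory": "chemosensory_bait.txt",
    }[which]
    return Path(str(resources.files("ciliascreen").joinpath("data", fname)))


@dataclass(frozen=True)
class PipelineConfig:
    """One flat, YAML-serializable configuration for both pipelines.

    Path fields left as None are filled from the synthetic generators when
    ``simulate`` is true; otherwise missing paths simply skip the
    corresponding optional stage (annotations, promoters).
    """

    # --- inputs ---
    expression_path: str | None = None
    has_gene_column: bool = True
    baits_path: str | None = None
    annotations_path: str | None = None
    promoters_path: str | None = None
    genome_path: str | None = None
    bed_path: str | None = None
    out_dir: str | None = None
    stage_labels: tuple[str, ...] = DEFAULT_STAGES
    # --- thresholds ---
    alpha_cluster: float = 1e-4
    alpha_top: float = 5e-7
    alpha_chemo: float = 1e-3
    cildb_min_hits: int = 12
    # --- trend filter ---
    trend_fold: float = 10.0
    trend_tail_k: int = 3
    trend_tail_mode: str = "all"
    apply_trend: bool = True
    # --- clustering ---
    normalization: str = "max"
    metric: str = "euclidean"
    linkage: str = "complete"
    min_cluster_size: int = 10
    max_cluster_size: int | None = None
    extraction_rule: str = "coverage"
    bait_coverage: float = 1.0
    # --- motif scan ---
    motif_pattern: str = "CANNTG"
    both_strands: bool = True
    upstream: int = 1000
    # --- simulation ---
    simulate: bool = False
    noise_sigma: float = 0.3
    n_ciliary: int = 200
    n_chemo: int = 200
    n_flat: int = 200
    n_baits: int = 41
    isoform_lambda: float = 0.0
    chemo_bait: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("alpha_cluster", "alpha_top", "alpha_chemo"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must be in (0, 1)")
        object.__setattr__(self, "stage_labels", tuple(self.stage_labels))

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["stage_labels"] = list(self.stage_labels)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "stage_labels" in d:
            d = {**d, "stage_labels": tuple(d["stage_labels"])}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    # -- derived pieces ----------------------------------------------
    @property
    def stage_axis(self) -> StageAxis:
        return StageAxis(self.stage_labels)

    @property
    def trend_config(self) -> TrendConfig:
        return TrendConfig(self.trend_fold, self.trend_tail_k, self.trend_tail_mode)  # type: ignore[arg-type]

    def sim_config(self) -> SimulationConfig:
        return SimulationConfig(
            stage_axis=self.stage_axis,
            archetypes=tuple(
                dataclasses.replace(a, isoform_lambda=self.isoform_lambda)
                for a in default_archetypes(self.n_ciliary, self.n_chemo, self.n_flat)
            ),
            noise_sigma=self.noise_sigma,
            seed=self.seed,
            n_baits=self.n_baits,
        )


@dataclass
class RunReport:
    """Stage-by-stage counts and statistics of one pipeline run."""

    pipeline: str
    counts: dict[str, int] = field(default_factory=dict)
    metrics: dict[str, float] = field(default_factory=dict)
    enrichment: list[dict] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    cluster1: list[str] = field(default_factory=list)
    config: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    version: str = __version__

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def check_monotone(self) -> None:
        """Counts must not increase along screen -> alpha -> trend ->
        cluster 1."""
        chain = [
            self.counts.get(k)
            for k in ("screened", "alpha_passing", "trend_and_alpha", "cluster1")
            if self.counts.get(k) is not None
        ]
        if any(b > a for a, b in zip(chain, chain[1:])):
            raise PipelineError(f"filtering-chain counts not monotone: {chain}")


def _stage(report: RunReport, name: str, t0: float, **counts: int) -> None:
    report.counts.update(counts)
    logger.info(
        "stage %-16s %s  (%.2fs)",
        name,
        " ".join(f"{k}={v}" for k, v in counts.items()),
        time.perf_counter() - t0,
    )


def _load_inputs(
    config: PipelineConfig,
) -> tuple[ExpressionMatrix, BaitSet, pd.DataFrame | None, PromoterSet | None, pd.DataFrame | None]:
    """Resolve (matrix, baits, annotations, promoters, truth) from files or
    the simulator."""
    truth = None
    annotations = None
    promoters = None
    if config.simulate:
        sim = config.sim_config()
        table, truth = simulate_matrix(sim)
        matrix = collapse_isoforms(table)
        baits = truth_bait_set(truth)
        annotations = simulate_annotations(truth, sim)
        promoters, _ = simulate_promoters(truth, IUPACMotif(config.motif_pattern), sim)
    else:
        if config.expression_path is None:
            raise PipelineError("stage=input: no expression table and simulate=False")
        parsed = read_expression_table(
            config.expression_path, config.has_gene_column, config.stage_axis
        )
        matrix = (
            collapse_isoforms(parsed) if config.has_gene_column else parsed  # type: ignore[arg-type]
        )
        bait_path = config.baits_path or packaged_bait_path("ciliary")
        baits = load_bait_set(bait_path)
        if config.annotations_path:
            annotations = read_annotation_table(config.annotations_path)
        if config.promoters_path:
            promoters = read_promoter_fasta(config.promoters_path, config.upstream)
        elif config.genome_path and config.bed_path:
            promoters = extract_promoters(
                config.genome_path, config.bed_path, config.upstream
            )
    return matrix, baits, annotations, promoters, truth


def _cluster_stage(
    config: PipelineConfig,
    matrix: ExpressionMatrix,
    candidates: set[str],
    baits: BaitSet,
    report: RunReport,
) -> ClusterSet | None:
    """Normalize, cluster and extract cluster 1 from the candidate set."""
    bait_leaves = candidates & set(baits)
    if len(candidates) < 2 or not bait_leaves:
        report.warnings.append(
            "clustering skipped: fewer than 2 candidates or no bait among them"
        )
        return None
    sub = matrix.subset(candidates)
    normed, flagged = normalize_profiles(sub, config.normalization)  # type: ignore[arg-type]
    if flagged:
        report.warnings.append(
            f"{len(flagged)} constant-profile candidates excluded before clustering"
        )
        normed = normed.subset(set(normed.genes) - set(flagged))
        if normed.n_genes < 2:
            report.warnings.append("clustering skipped after constant exclusion")
            return None
    dist = pairwise_distances(normed, config.metric)  # type: ignore[arg-type]
    dendro = hierarchical_cluster(dist, config.linkage, normed.genes)
    min_size = min(config.min_cluster_size, dendro.n_leaves)
    try:
        clusters = extract_bait_cluster(
            dendro,
            baits,
            min_size=min_size,
            max_size=config.max_cluster_size,
            rule=config.extraction_rule,  # type: ignore[arg-type]
            coverage=config.bait_coverage,
        )
    except NoSubtreeError as exc:
        report.warnings.append(f"cluster extraction failed: {exc}")
        return None
    if config.out_dir:
        out = Path(config.out_dir)
        (out / "dendrogram.nwk").write_text(dendro.to_newick() + "\n")
        write_cluster_assignments(clusters, baits, out / "cluster_assignments.tsv")
    return clusters


def run_screen_pipeline(config: PipelineConfig) -> RunReport:
    """Run the full ciliary screen; returns the populated
    :class:`RunReport`."""
    t0 = time.perf_counter()
    report = RunReport(
        pipeline="screen", config=config.to_dict(), seed=config.seed
    )
    out = None
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)

    matrix, baits, annotations, promoters, truth = _load_inputs(config)
    _stage(report, "input", t0, input_genes=matrix.n_genes, baits=len(baits))
    if out:
        write_expression_table(matrix, out / "expression_collapsed.tsv")
        if truth is not None:
            truth.to_csv(out / "truth.tsv", sep="\t")

    # correlation screen
    try:
        screen = bait_screen(matrix, baits)
    except Exception as exc:
        raise PipelineError(f"stage=screen: {exc}") from exc
    scoreable = int((~screen["excluded"]).sum())
    _stage(report, "screen", t0, screened=scoreable)
    if out:
        write_screen_results(screen, out / "screen_results.tsv")

    # p-value thresholds
    candidates = threshold_candidates(screen, config.alpha_cluster)
    n_top = len(threshold_candidates(screen, config.alpha_top))
    _stage(report, "threshold", t0, alpha_passing=len(candidates), top_genes=n_top)

    # trend filter (counts reported both genome-wide and on candidates)
    trend_all, verdicts = apply_trend_filter(matrix, config.trend_config)
    if config.apply_trend:
        candidates = candidates & trend_all
    _stage(
        report,
        "trend",
        t0,
        trend_passing_total=len(trend_all),
        trend_and_alpha=len(candidates & trend_all),
    )
    if out:
        write_trend_verdicts(verdicts, out / "trend_verdicts.tsv")

    # clustering + cluster-1 extraction
    clusters = _cluster_stage(config, matrix, candidates, baits, report)
    if clusters is None:
        cluster1: set[str] = set()
        report.counts["cluster1"] = 0
    else:
        cluster1 = set(clusters.extracted_cluster)
        report.metrics["bait_recall"] = clusters.bait_recall
        report.metrics["bait_precision"] = clusters.bait_precision
        report.metrics["cluster1_height"] = clusters.node_height
        report.metrics["cluster1_hypergeom_p"] = clusters.hypergeom_pvalue
        _stage(report, "cluster", t0, cluster1=len(cluster1))
    report.cluster1 = sorted(cluster1)

    # annotation filtering + enrichment
    if annotations is not None and cluster1:
        filtered = filter_by_annotation(cluster1, annotations, "ortholog")
        _stage(report, "ortholog", t0, cluster1_with_ortholog=len(filtered))
        universe = set(matrix.genes) & set(annotations.index)
        conserved_cildb = filter_by_annotation(
            universe, annotations, "ortholog"
        ) & filter_by_annotation(universe, annotations, "cildb", config.cildb_min_hits)
        try:
            table = contingency_from_sets(filtered, conserved_cildb, universe)
            res = chi_squared_2x2(table)
            report.enrichment.append(
                enrichment_report_row(
                    f"ortholog&cildb>{config.cildb_min_hits}", table, res
                )
            )
            report.metrics["cildb_fold"] = res.fold
            report.metrics["cildb_p"] = res.p
        except (ZeroMarginalError, ValueError) as exc:
            report.warnings.append(f"cildb enrichment not computable: {exc}")
        if out:
            write_gene_list(sorted(filtered), out / "cluster1_filtered.tsv")

    # optional promoter motif scan over cluster 1
    if promoters is not None and cluster1:
        motif = IUPACMotif(config.motif_pattern)
        fg = cluster1 & set(promoters.genes())
        bg = set(promoters.genes())
        if fg and fg < bg:
            result, table = motif_enrichment(
                fg, bg, promoters, motif, config.both_strands
            )
            report.enrichment.append(
                enrichment_report_row(f"motif:{motif.pattern}", table, result)
            )
            report.counts["cluster1_with_motif"] = table.a
            report.metrics["motif_fold"] = result.fold
            report.metrics["motif_p"] = result.p

    report.check_monotone()
    if truth is not None:
        _recovery_metrics(report, cluster1, truth, config)
    if out:
        report.write(out / "report.json")
    return report


def _recovery_metrics(
    report: RunReport, found: set[str], truth: pd.DataFrame, config: PipelineConfig
) -> None:
    """Planted-set precision/recall when ground truth is available."""
    planted = set(truth.index[truth["archetype"] == "ciliary"])
    if not planted:
        return
    tp = len(found & planted)
    report.metrics["planted_recall"] = tp / len(planted)
    report.metrics["planted_precision"] = tp / len(found) if found else 0.0


def run_chemo_pipeline(config: PipelineConfig) -> RunReport:
    """Single-bait post-ciliogenesis screen (chemoreceptor variant)."""
    t0 = time.perf_counter()
    report = RunReport(pipeline="chemo", config=config.to_dict(), seed=config.seed)
    out = None
    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)

    if config.simulate:
        sim = config.sim_config()
        table, truth = simulate_matrix(sim)
        matrix = collapse_isoforms(table)
        chemo_genes = truth.index[truth["archetype"] == "chemosensory"]
        if config.chemo_bait:
            bait_id = config.chemo_bait
        elif len(chemo_genes):
            bait_id = str(chemo_genes[0])
        else:
            raise PipelineError("stage=input: no chemosensory gene to use as bait")
        annotations = simulate_annotations(truth, sim)
        promoters, _ = simulate_promoters(truth, IUPACMotif(config.motif_pattern), sim)
    else:
        truth = None
        if config.expression_path is None:
            raise PipelineError("stage=input: no expression table and simulate=False")
        parsed = read_expression_table(
            config.expression_path, config.has_gene_column, config.stage_axis
        )
        matrix = (
            collapse_isoforms(parsed) if config.has_gene_column else parsed  # type: ignore[arg-type]
        )
        bait_path = config.baits_path or packaged_bait_path("chemosensory")
        bait_id = load_bait_set(bait_path).gene_ids[0]
        annotations = (
            read_annotation_table(config.annotations_path)
            if config.annotations_path
            else None
        )
        promoters = None
        if config.promoters_path:
            promoters = read_promoter_fasta(config.promoters_path, config.upstream)
        elif config.genome_path and config.bed_path:
            promoters = extract_promoters(
                config.genome_path, config.bed_path, config.upstream
            )

    baits = BaitSet((bait_id,), name="chemosensory")
    _stage(report, "input", t0, input_genes=matrix.n_genes, baits=1)

    screen = bait_screen(matrix, baits)
    candidates = threshold_candidates(screen, config.alpha_chemo, include_baits=False)
    _stage(
        report,
        "screen",
        t0,
        screened=int((~screen["excluded"]).sum()),
        alpha_passing=len(candidates),
    )
    if out:
        write_screen_results(screen, out / "chemo_screen_results.tsv")

    if annotations is not None:
        universe = set(matrix.genes) & set(annotations.index)
        serpentine = filter_by_annotation(universe, annotations, "chemoreceptor")
        n_serp = len(candidates & serpentine)
        report.counts["serpentine_candidates"] = n_serp
        if candidates and candidates < universe:
            try:
                table = contingency_from_sets(candidates, serpentine, universe)
                res = chi_squared_2x2(table)
                report.enrichment.append(
                    enrichment_report_row("chemoreceptor", table, res)
                )
                report.metrics["serpentine_fold"] = res.fold
                report.metrics["serpentine_p"] = res.p
            except ZeroMarginalError as exc:
                report.warnings.append(f"serpentine enrichment not computable: {exc}")

        # E-box presence among the chemoreceptor set (bait included)
        if promoters is not None:
            chemo_set = (candidates & serpentine) | {bait_id}
            motif = IUPACMotif(config.motif_pattern)
            with_motif, _counts = genes_with_motif(
                PromoterSet(
                    {
                        g: promoters[g]
                        for g in chemo_set
                        if g in set(promoters.genes())
                    },
                    promoters.nominal_length,
                    {},
                ),
                motif,
                config.both_strands,
            )
            report.counts["chemo_set"] = len(chemo_set)
            report.counts["chemo_set_with_motif"] = len(with_motif)

    if promoters is not None and candidates:
        fg = candidates & set(promoters.genes())
        bg = set(promoters.genes())
        if fg and fg < bg:
            result, table = motif_enrichment(
                fg, bg, promoters, IUPACMotif(config.motif_pattern),
                config.both_strands,
            )
            report.enrichment.append(
                enrichment_report_row(f"motif:{config.motif_pattern}", table, result)
            )
            report.metrics["motif_fold"] = result.fold
            report.metrics["motif_p"] = result.p

    if truth is not None:
        planted = set(truth.index[truth["archetype"] == "chemosensory"]) - {bait_id}
        if planted:
            tp = len(candidates & planted)
            report.metrics["planted_recall"] = tp / len(planted)
            report.metrics["planted_precision"] = (
                tp / len(candidates) if candidates else 0.0
            )
    if out:
        report.write(out / "chemo_report.json")
    return report
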