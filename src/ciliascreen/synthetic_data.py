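"""Seeded synthetic data with planted ground truth for the whole pipeline.

The generator emulates the structure of a whole-organism developmental
RNA-Seq table over seven stages (EE..YA):

* a "ciliary" archetype peaking in late embryo / L1 with a >=10-fold decay
  over the last three stages (default stage means 30, 100, 80, 8, 4, 3, 2),
  which passes the trend filter by construction in the noiseless limit;
* a "chemosensory" archetype whose peak at L1-L2 trails the ciliary peak
  (default 2, 10, 80, 100, 40, 15, 8) and whose tail decay is too shallow
  for the trend filter;
* a flat "housekeeping" background archetype.

Noise is multiplicative log-normal, drawn independently per stage and
isoform: ``value = mean * exp(N(0, sigma^2))`` with sigma on the natural-log
scale, which preserves non-negativity and the heavy right tail of RPKM
data.  A configurable number of ciliary-archetype genes are designated
baits.  Annotation flags (human ortholog, ciliary-database hit counts,
chemoreceptor class) are drawn at archetype-specific rates, and promoters
are uniform-random sequences with the scan motif scrubbed from the
background by local rejection-resampling, so motif plant rates are exact.

Everything is driven by one integer seed; equal seeds give byte-identical
outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .correlation_screen import BaitSet
from .expression_io import ExpressionMatrix, IsoformTable, StageAxis
from .motif_scan import IUPACMotif, PromoterSet, scan_motif

__all__ = [
    "ArchetypeSpec",
    "SimulationConfig",
    "default_archetypes",
    "default_config",
    "simulate_matrix",
    "simulate_annotations",
    "simulate_promoters",
    "truth_bait_set",
    "planted_genes",
]

CILIARY_MEAN = (30.0, 100.0, 80.0, 8.0, 4.0, 3.0, 2.0)
CHEMOSENSORY_MEAN = (2.0, 10.0, 80.0, 100.0, 40.0, 15.0, 8.0)
HOUSEKEEPING_MEAN = (50.0,) * 7


@dataclass(frozen=True)
class ArchetypeSpec:
    """A planted expression class.

    ``isoform_lambda`` > 0 draws per-gene isoform counts as
    1 + Poisson(lambda); 0 means exactly one isoform per gene.
    """

    name: str
    mean_profile: tuple[float, ...]
    n_genes: int
    isoform_lambda: float = 0.0

    def __post_init__(self) -> None:
        if self.n_genes < 0:
            raise ValueError("n_genes must be >= 0")
        if any(v < 0 for v in self.mean_profile):
            raise ValueError("mean profile must be non-negative")
        if self.isoform_lambda < 0:
            raise ValueError("isoform_lambda must be >= 0")


def default_archetypes(
    n_ciliary: int = 200, n_chemo: int = 200, n_flat: int = 200
) -> tuple[ArchetypeSpec, ...]:
    return (
        ArchetypeSpec("ciliary", CILIARY_MEAN, n_ciliary),
        ArchetypeSpec("chemosensory", CHEMOSENSORY_MEAN, n_chemo),
        ArchetypeSpec("housekeeping", HOUSEKEEPING_MEAN, n_flat),
    )


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic-data generators.

    Rates are per-archetype mappings; archetypes absent from a mapping fall
    back to the mapping's ``"default"`` entry (or 0 / 0.0).
    """

    stage_axis: StageAxis = field(default_factory=StageAxis)
    archetypes: tuple[ArchetypeSpec, ...] = field(default_factory=default_archetypes)
    noise_sigma: float = 0.3
    seed: int = 0
    n_baits: int = 41
    bait_archetype: str = "ciliary"
    ortholog_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "ciliary": 0.9,
            "chemosensory": 0.5,
            "housekeeping": 0.5,
            "default": 0.5,
        }
    )
    cildb_lambda: Mapping[str, float] = field(
        default_factory=lambda: {"ciliary": 20.0, "default": 0.5}
    )
    chemoreceptor_rate: Mapping[str, float] = field(
        default_factory=lambda: {
            "chemosensory": 0.35,
            "housekeeping": 0.05,
            "default": 0.0,
        }
    )
    motif_plant_rate: Mapping[str, float] = field(
        default_factory=lambda: {"chemosensory": 0.9, "default": 0.1}
    )
    promoter_length: int = 1000

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.promoter_length < 1:
            raise ValueError("promoter_length must be >= 1")
        for spec in self.archetypes:
            if len(spec.mean_profile) != len(self.stage_axis):
                raise ValueError(
                    f"archetype {spec.name!r} profile length "
                    f"{len(spec.mean_profile)} != stage count "
                    f"{len(self.stage_axis)}"
                )
        for rates in (
            self.ortholog_rate,
            self.chemoreceptor_rate,
            self.motif_plant_rate,
        ):
            for k, v in rates.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"rate {k}={v} outside [0, 1]")
        names = [a.name for a in self.archetypes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate archetype names")
        # a bait-free simulation (n_baits=0) may omit the bait archetype
        if self.n_baits > 0 and self.bait_archetype not in names:
            raise ValueError(f"bait archetype {self.bait_archetype!r} not simulated")

    def rate(self, mapping: Mapping[str, float], archetype: str) -> float:
        return mapping.get(archetype, mapping.get("default", 0.0))


def default_config(seed: int = 0, **overrides) -> SimulationConfig:
    """The default study conditions with a chosen seed."""
    return replace(SimulationConfig(seed=seed), **overrides)


def simulate_matrix(config: SimulationConfig) -> tuple[IsoformTable, pd.DataFrame]:
    """Draw an isoform-level expression table plus its truth table.

    The truth table is indexed by gene_id with columns ``archetype`` and
    ``is_bait``; the first ``n_baits`` genes of the bait archetype are baits.
    """
    rng = np.random.default_rng(config.seed)
    stages = list(config.stage_axis.labels)
    rows: list[dict] = []
    truth_rows: list[dict] = []
    for spec in config.archetypes:
        mean = np.asarray(spec.mean_profile, dtype=float)
        n_bait_here = config.n_baits if spec.name == config.bait_archetype else 0
        for i in range(spec.n_genes):
            gene = f"{spec.name}_{i:04d}"
            if spec.isoform_lambda > 0:
                n_iso = 1 + int(rng.poisson(spec.isoform_lambda))
            else:
                n_iso = 1
            noise = np.exp(
                rng.normal(0.0, config.noise_sigma, size=(n_iso, mean.size))
            )
            values = mean[None, :] * noise
            for j in range(n_iso):
                rows.append(
                    {
                        "isoform_id": f"{gene}.{j + 1}",
                        "gene_id": gene,
                        **dict(zip(stages, values[j])),
                    }
                )
            truth_rows.append(
                {"gene_id": gene, "archetype": spec.name, "is_bait": i < n_bait_here}
            )
    if not rows:
        raise ValueError("no genes simulated")
    data = pd.DataFrame(rows).set_index("isoform_id")
    truth = pd.DataFrame(truth_rows).set_index("gene_id")
    if config.n_baits > int(truth["is_bait"].sum()):
        raise ValueError("n_baits exceeds genes in the bait archetype")
    return IsoformTable(data, config.stage_axis), truth


def truth_bait_set(truth: pd.DataFrame, name: str = "planted-baits") -> BaitSet:
    return BaitSet(tuple(truth.index[truth["is_bait"]]), name=name)


def planted_genes(truth: pd.DataFrame, archetype: str) -> set[str]:
    return set(truth.index[truth["archetype"] == archetype])


def simulate_annotations(
    truth: pd.DataFrame, config: SimulationConfig
) -> pd.DataFrame:
    """Draw per-gene annotation flags at archetype-specific rates.

    ortholog_flag ~ Bernoulli, cildb_hits ~ Poisson, chemoreceptor_flag ~
    Bernoulli; seeded independently of the expression draw (seed + 1).
    """
    if truth.empty:
        raise ValueError("truth table is empty")
    rng = np.random.default_rng(config.seed + 1)
    arch = truth["archetype"]
    p_orth = arch.map(lambda a: config.rate(config.ortholog_rate, a)).to_numpy()
    lam = arch.map(
        lambda a: config.cildb_lambda.get(a, config.cildb_lambda.get("default", 0.0))
    ).to_numpy()
    p_chemo = arch.map(
        lambda a: config.rate(config.chemoreceptor_rate, a)
    ).to_numpy()
    return pd.DataFrame(
        {
            "ortholog_flag": rng.random(len(truth)) < p_orth,
            "cildb_hits": rng.poisson(lam),
            "chemoreceptor_flag": rng.random(len(truth)) < p_chemo,
        },
        index=truth.index.copy(),
    )


_BASES = np.frombuffer(b"ACGT", dtype="S1")


def _scrub_motif(seq: np.ndarray, motif: IUPACMotif, rng: np.random.Generator) -> None:
    """Redraw bases under motif occurrences (either strand) until none remain."""
    w = len(motif)
    for _ in range(10_000):
        hits = scan_motif(seq.tobytes().decode(), motif, both_strands=True)
        if not hits:
            return
        for h in hits:
            seq[h.offset : h.offset + w] = rng.choice(_BASES, size=w)
    raise RuntimeError("motif scrubbing did not converge")


def simulate_promoters(
    truth: pd.DataFrame,
    motif: IUPACMotif,
    config: SimulationConfig,
) -> tuple[PromoterSet, set[str]]:
    """Uniform-random promoters with the motif planted at archetype rates.

    Background sequences are scrubbed of chance motif occurrences on both
    strands, so a gene's promoter contains the motif iff the gene was
    planted; planted genes receive one concrete expansion of the IUPAC
    pattern at a uniform random position.  Returns the promoter set and the
    set of genes that actually received a planted instance.
    """
    if config.promoter_length < len(motif):
        raise ValueError("promoter_length shorter than motif")
    rng = np.random.default_rng(config.seed + 2)
    expansions = motif.expansions()
    seqs: dict[str, str] = {}
    planted: set[str] = set()
    for gene in truth.index:
        arch = truth.loc[gene, "archetype"]
        rate = config.rate(config.motif_plant_rate, str(arch))
        seq = rng.choice(_BASES, size=config.promoter_length)
        _scrub_motif(seq, motif, rng)
        if rng.random() < rate:
            instance = expansions[int(rng.integers(len(expansions)))]
            pos = int(rng.integers(config.promoter_length - len(motif) + 1))
            seq[pos : pos + len(motif)] = np.frombuffer(
                instance.encode(), dtype="S1"
            )
            planted.add(gene)
        seqs[gene] = seq.tobytes().decode()
    out = PromoterSet(seqs, config.promoter_length, {g: 0 for g in seqs})
    return out, planted


def to_expression_matrix(table: IsoformTable) -> ExpressionMatrix:
    """Convenience: collapse the simulated isoform table to gene level."""
    from .expression_io import collapse_isoforms

    return collapse_isoforms(table)
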