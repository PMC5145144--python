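# ciliascreen

Bait-based temporal co-expression screening for ciliary gene discovery from
staged whole-organism RNA-Seq profiles.

## The problem

Ciliogenesis in *C. elegans* happens in a discrete late-embryonic window, so
transcripts needed to build cilia peak around the late embryo / L1 larva and
decay afterwards. Genes that share this temporal signature with known
ciliary genes are strong candidates for novel ciliary components — and the
same logic, shifted one stage later, finds post-ciliogenesis chemoreceptor
genes. `ciliascreen` implements this screen as a reusable, tested pipeline
for anyone with a gene (or isoform) × developmental-stage expression table,
a curated bait list, and optionally annotation tables and promoter
sequences.

## The method

Given an expression matrix **X** (RPKM, rows = genes, columns = ordered
stages EE, LE, L1, L2, L3, L4, YA) and a bait set *B* of known ciliary
genes:

1. **Isoform collapsing** — per-gene profiles are the unweighted mean of
   the gene's isoform RPKM profiles.
2. **Correlation screen** — for every gene *g* and bait *b*, the Pearson
   correlation r(g, b) over the *n* stage columns, with a two-sided p-value
   from t = r·√((n−2)/(1−r²)) on n−2 df. Each gene retains
   p(g) = min over baits of p(g, b); baits exclude their self-test (the
   "second-smallest" rule), avoiding circular self-selection. Candidates
   are genes with p(g) < α (defaults: 1e-4 for clustering, 5e-7 "top",
   1e-3 for the single-bait chemoreceptor screen).
3. **Trend filter** — expression in each of the last 3 stages must be
   ≤ peak/10 (peak over all stages); all-zero profiles fail.
4. **Clustering** — candidates are max-normalized, Euclidean distances,
   agglomerative clustering (single/average/complete linkage; complete by
   default); "cluster 1" is extracted as the smallest genuine subtree
   containing all baits present among the leaves (a hypergeometric-optimal
   rule is also available; see `docs/methods.md`).
5. **Validation** — fold enrichment (k/m)/(K/N) and a 2×2 chi-squared test
   (1 df, no continuity correction) for annotation criteria: human-ortholog
   presence, ciliary-database evidence (> 12 hits), chemoreceptor class.
6. **Promoter motifs** — 1000 bp upstream of the start codon (FASTA, or
   extracted from genome FASTA + BED6), scanned for an IUPAC consensus
   (default `CANNTG`, the canonical bHLH E-box), with presence counts and a
   presence-enrichment chi-squared contrast.

A seeded synthetic-data generator plants a ciliary archetype, a trailing
chemosensory archetype and flat background under multiplicative log-normal
noise, with matching annotation flags and promoter motifs, so the entire
pipeline is exercisable with ground truth and no downloads.

## Worked example

Run the full screen on synthetic data (600 genes: 200 planted ciliary
including 41 baits, 200 chemosensory, 200 flat; noise σ = 0.3):

```sh
ciliascreen run-all --simulate --seed 3
```

The report (abridged) prints:

```json
{
  "counts": {
    "input_genes": 600, "baits": 41, "screened": 600,
    "alpha_passing": 200, "trend_passing_total": 200,
    "trend_and_alpha": 198, "cluster1": 198,
    "cluster1_with_ortholog": 170
  },
  "metrics": {
    "bait_recall": 1.0, "bait_precision": 0.202,
    "cildb_fold": 3.49, "cildb_p": 4.3e-125,
    "planted_recall": 0.99, "planted_precision": 1.0
  }
}
```

Reading it: of 600 genes, 200 pass the correlation threshold (α = 1e-4)
against the 41 baits, 198 of those also show the ≥10-fold late-stage decay,
and the extracted bait cluster contains all 41 baits plus 157 prey genes —
99% of the planted ciliary class, with no false positives
(`planted_recall`/`planted_precision` are computed against the simulation's
truth table). The cluster is 3.5-fold enriched for conserved
ciliary-database genes relative to this synthetic genome (chi-squared
p ≪ 1e-4).

The chemoreceptor variant (`ciliascreen run-chemo --simulate --seed 3`)
screens with one chemosensory bait at α = 1e-3 and reports the serpentine-
receptor enrichment of the candidates and the fraction of receptor
promoters carrying an E-box (18 of 20 at this seed).

The same commands run on real data by replacing `--simulate` with a YAML
config pointing at an expression TSV, a bait list (the 41-gene ciliary
fixture ships with the package), an annotation TSV and promoters
(FASTA or genome + BED6); see `PipelineConfig` for all keys.

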