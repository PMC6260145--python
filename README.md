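# csrnc

Quantitation and profiling of **non-coding class-switch-recombination
(CSRnc) transcription** — the sterile "germline" transcripts initiating at
the unannotated I-exons of the human immunoglobulin heavy-chain (IGH)
locus.

Class switch recombination (CSR) replaces the expressed constant-region
(C_H) gene of an antibody, switching its class from IgM to IgG, IgA or IgE.
CSR requires transcription through the repetitive, AGCT-rich switch (S)
region upstream of each C_H gene, initiated at a non-coding I-exon. Neither
the I-exons nor the S regions are annotated in GRCh38, so standard
gene-level RNA-seq pipelines never see them. This package provides the
building blocks for measuring this transcription directly from coverage
tracks, for anyone studying B-cell responses in bulk RNA-seq compendia:

- **`locus_map`** — switch-region mapping by AGCT motif density in 500 bp
  bins along the locus, plus the curated GRCh38.p10 catalog of the 10
  I-exons, 8 S regions and 9 C_H genes (1-based inclusive coordinates;
  BED I/O converts at the boundary).
- **`quantify`** — per-region RPKM from coverage AUC
  (`RPKM = (AUC / read_length) * 1e9 / (L * library_reads)`), per-sample
  mean log2 RPKM, the high / low / none classification against the
  compendium cutoff of 2.65 log2 RPKM, and per-region Z-scores. RPKM = 0
  cells are a distinct "absent" class: masked, never log-transformed.
- **`profiles`** — k-means clustering of per-sample I-exon Z-profiles into
  expression archetypes, with a missing-value-aware Euclidean distance
  (partial squared distance rescaled by D/m) and best-of-100 restarts.
- **`enrichment`** — tissue-by-cluster 2x2 Fisher exact tests (two-sided,
  point-probability rule) with joint Benjamini–Hochberg correction.
- **`diffexpr`** — per-region OLS contrasts on log2 RPKM with
  empirical-Bayes moderated variances, `s~² = (d0·s0² + d·s²)/(d0 + d)`,
  the prior (d0, s0²) estimated by digamma/trigamma moment matching of
  log s²; Bonferroni correction (appropriate for a 10-region panel); plus
  Wilcoxon signed-rank / rank-sum comparisons.
- **`qpcr`** — 2^(−ΔΔCt) relative quantitation against a reference gene
  and calibrator condition, with per-condition summaries.
- **`synthetic_data`** — cohort, locus and coverage generators that plant
  recoverable structure (tissue archetypes, zero inflation, coding/
  non-coding correlation), so the full pipeline is testable offline.

## Worked example

Generate a synthetic 1,000-sample cohort with the default compendium-like
conditions, classify it, cluster the Z-profiles and test tissue enrichment:

```python
from csrnc import synthetic_data as sd, quantify as q, profiles as pr, enrichment as en

config = sd.SyntheticCohortConfig(n_samples=1000, seed=7)
meta, i_expr, c_expr = sd.generate_cohort(config)

records, summary = q.classify_samples(i_expr)
print(f"high {summary['n_high']} ({summary['pct_high']}%), "
      f"low {summary['n_low']} ({summary['pct_low']}%), "
      f"none {summary['n_none']} ({summary['pct_none']}%)")

Z = q.zscore_by_region(i_expr.log2())
Z = Z.loc[Z.notna().any(axis=1)]          # the non-zero "clustering set"
model = pr.kmeans_profiles(Z, pr.ClusterConfig(k=10, n_runs=100, seed=7))

result = en.enrich(model.assignments, meta.set_index("sample_id"))
sig = result[result["significant"]]
print(f"{len(sig)} of {len(result)} tissue x cluster pairs significant at FDR < 0.01")
print(sig.nsmallest(3, "q")[["tissue", "cluster", "odds_ratio", "q"]].to_string(index=False))
```

prints

```
high 330 (33.0%), low 321 (32.1%), none 349 (34.9%)
51 of 120 tissue x cluster pairs significant at FDR < 0.01
 tissue cluster  odds_ratio            q
 testis      Z9   31.680672 2.088487e-18
thyroid      Z7   29.167421 8.508237e-16
thyroid      Z9   16.975484 2.909677e-13
```

About a third of the samples transcribe no I-exon at all ("none"), a third
sit below the 2.65 log2 RPKM cutoff ("low") and a third above it ("high"),
mirroring the zero-inflated compendium the generator emulates. The
enrichment scan then recovers the planted tissue structure: testis and
thyroid samples, generated from the Imu/Igamma1/Igamma4 archetype,
concentrate in the clusters that captured that profile (odds ratios ~17–32
at vanishing q).

The same stages are available from a shell:

```sh
csrnc simulate --n 1000 --seed 7 --coverage --out cohort/
csrnc quantify --tracks cohort/coverage --out quant/
csrnc classify --matrix quant/rpkm.tsv --out classes.tsv
csrnc cluster  --z z.tsv --k 10 --runs 100 --seed 7 --out clust/
csrnc enrich   --assignments clust/assignments.tsv --metadata cohort/metadata.tsv --out enrich.tsv
csrnc scan-switch --fasta locus.fa --bin 500 --motif AGCT --out switch.bed
csrnc de   --matrix log2.tsv --design meta.tsv --contrast tissue:spleen-vs-whole_blood --out de.tsv
csrnc qpcr --ct ct.tsv --reference HPRT --calibrator resting_B --out qpcr/
```

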