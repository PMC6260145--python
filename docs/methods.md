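# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, the conditions the synthetic-data generator emulates,
and the limits of what the test suite demonstrates.

## Coordinates and the region catalog

All internal coordinates are 1-based and inclusive, so
`length = end − start + 1`; this convention reproduces every published
length in the packaged IGH catalog (e.g. Iμ 105,861,311–105,862,213 →
903 bp, Sμ 105,856,501–105,860,500 → 4,000 bp). BED input/output converts
to 0-based half-open at the boundary (`bed_start = start − 1`,
`bed_end = end`), and the round trip is an identity.

The packaged catalog carries the 10 I-exons and 8 S regions at their
curated coordinates on chromosome 14 (GRCh38.p10). The nine constant-gene
rows use approximate gene-body coordinates from public GRCh38 annotation;
they exist to support coding/non-coding pairing and are not authoritative
interval definitions.

## Switch-region mapping

S regions are located by the density of the AGCT motif — the core AID
hotspot, shared by all human switch regions — in fixed 500 bp bins along
the locus (105,583,700–105,863,000 spans 559 bins). Occurrences are counted
at every start position, case-insensitively; IUPAC ambiguity codes never
match. A motif is assigned to the bin containing its **start** position,
which is unambiguous for motifs crossing bin edges. AGCT is its own reverse
complement, so single-strand scanning is complete; non-palindromic user
motifs are additionally scanned as their reverse complement and the counts
summed.

No numeric peak-calling rule accompanies the published S coordinates (they
were finalized by visual inspection), so calling is a declared, exposed
convention: bins exceeding `mean + 2 SD` (sample SD) of the whole profile
are flagged and adjacent flagged bins merge into one interval. On planted
AGCT-dense regions this recovers a 4,000 bp switch region to within one
bin; the threshold multiplier is a config parameter for users who want a
different operating point.

## Quantitation and classification

Expression of an unannotated interval is RPKM computed from the area under
per-base coverage: `reads = AUC / read_length` (default 100 bp) and
`RPKM = reads × 1e9 / (L × library_reads)`. Library size is user-supplied
mapped reads; when absent it is derived from the track as
`total_AUC / read_length`. This emulates, rather than restates, the
compendium's own AUC-to-count scaling, whose exact constants are not
republished here.

RPKM = 0 is treated as a distinct "absent" class throughout: zeros are
masked, never pseudocounted or log-transformed. The per-sample summary is
the mean log2 RPKM over **non-zero** I-exons (the declared policy for a
question the source leaves open), absent when every I-exon is zero.
Samples classify against the compendium-derived cutoff of 2.65 log2 RPKM
(≈ 6.29 RPKM): high strictly above, low in (0, cutoff], none all-zero. A
mean exactly at the cutoff is "low", preserving the strict ">" semantics
of the high class. Partition percentages are reported to one decimal;
applied to the published counts (21,017 / 23,074 / 26,512 of 70,603) the
arithmetic yields 29.8% high and 62.4% non-zero. (The published table's
own percentage column prints 37.1/62.9 for the last two rows, inconsistent
with its counts; this package reports what the counts imply.)

Z-scores standardize each region column of the log2 matrix over unmasked
entries with sample SD (n − 1, a convention the source does not fix).
Zero-variance columns map to Z = 0; columns with fewer than two observed
values stay masked with a warning.

## Profile clustering

Per-sample I-exon Z-profiles are clustered by k-means (default k = 10,
best of 100 restarts, Euclidean distance, Lloyd iteration to an assignment
fixpoint or 300 iterations). Absent cells remain masked in the Z matrix,
and the distance follows the scaled-partial-distance convention:

    d(x, c)² = (D / m) · Σ_observed (x_i − c_i)²

with D the dimension and m the observed coordinates — profiles with
different missingness stay comparable. Restart r uses `seed + r`; ties in
within-cluster SS keep the lowest run index. Empty clusters are re-seeded
from the point farthest from its centroid.

Centroid updates average observed contributions per coordinate, weighted
by each member's D/m factor. The weighting makes every Lloyd step provably
non-increasing in the masked-distance objective (asserted per iteration in
the tests); for fully observed data it reduces to the plain per-coordinate
mean. Whether the original analysis imputed or masked absent cells is
unknown; masking is this package's declared choice.

Cluster summaries report median, quartiles and masked fraction per
cluster × region over observed entries; a cluster is "high" for a region
when its median Z exceeds 0 (Z = 0 corresponds to the 2.65 log2 RPKM
mean).

## Enrichment

For each tissue × cluster pair a 2×2 table (in-tissue ∧ in-cluster, …) is
tested with a two-sided Fisher exact test. The two-sided p is the
point-probability definition — the sum of hypergeometric probabilities of
all tables with the observed margins whose probability does not exceed the
observed one, with relative tie tolerance 1e-7 (the convention of standard
implementations); degenerate margins give p = 1. The implementation sums
vectorized hypergeometric log-pmfs and is verified against exhaustive
exact-integer enumeration for every table with n ≤ 40 (agreement ~1e-14).

BH correction is applied jointly over **all** tested tissue × cluster
pairs — the conservative reading, since the original family size is
unstated — and significance is q < 0.01. The odds ratio is the sample
ratio ad/bc (infinity allowed, no continuity correction); direction is
enriched above 1, depleted below.

## Moderated differential expression

Each region is fit by OLS against a shared design matrix after dropping
that region's masked samples (n must exceed the number of design columns;
rank-deficient designs are rejected naming candidate collinear columns).
With only ~10 regions tested, per-region variances are noisy, so they are
shrunk under a scaled-F prior: s² ~ s0²·F(d, d0), with (d0, s0²) estimated
by matching the mean and variance of log s² through digamma/trigamma
identities (trigamma inverted by safeguarded Newton). The moderated
variance is s̃² = (d0 s0² + d s²)/(d0 + d); the t-statistic rescales the
OLS standard error by √(s̃²/s²) and gains d0 extra degrees of freedom.
Two boundary cases: zero observed dispersion of log s² gives d0 = ∞ with
s0² equal to the common variance (the degenerate point prior — the
chi-square moment correction presumes scatter that is absent); d0 → 0
recovers the ordinary t-test. Moderation uses the minimum residual df
across regions when masking makes them unequal — with ≤ 10 regions the
difference is immaterial. Bonferroni (not FDR) correction is applied over
the regions tested, appropriate for a 10-region panel; significance is
adjusted p < 0.05.

Simulation checks at the sizes used in the tests: on 10,000 regions with
d = 10, d0 = 4, s0² = 1 the prior is recovered well within ±20% (d0) /
±10% (s0²), and the null type-I error of the moderated t at α = 0.05 on
10,000 two-group (6 + 6) regions stays inside (0.04, 0.06).

Nonparametric comparisons delegate to SciPy: paired data use the Wilcoxon
signed-rank test (zero differences dropped; exact null for n ≤ 25, normal
approximation with continuity correction beyond), unpaired data the
rank-sum test with continuity correction. Technical-replicate correlation
adjustment is out of scope; replicates must be collapsed upstream (mean
per biological unit).

## qPCR

Fold change is 2^(−ΔΔCt): ΔCt is target minus reference gene (HPRT by
default) within a sample, ΔΔCt subtracts the calibrator condition's ΔCt
(mean over calibrator samples), and the negative sign makes fewer cycles
(more template) a fold > 1 — the conventional orientation. Technical
replicates are averaged on the Ct (log) scale before differencing.
Amplification efficiency is fixed at 100% (base 2); efficiency-corrected
models are out of scope. Group summaries report mean and SD on the fold
scale with a signed-rank test against the baseline condition (paired when
group sizes match, rank-sum otherwise; single-sample groups report the
fold with no p and a warning).

## Synthetic cohorts: what is emulated, and what is not

The generator plants the structure each downstream stage must recover:

- **Tissue archetypes** — each tissue draws its log2 RPKM means from one of
  five default archetype profiles (all-low; constitutive Iμ only; Iμ+Iα2
  mucosal; Iμ+Iγ1+Iγ4; all-high lymphoid), the patterns the published
  clusters describe. "Low" is 0.5 and "high" 7.0 log2 RPKM, straddling the
  2.65 cutoff; constant genes sit 5 log2 units above their paired I-exon
  (the printed compendium means differ by 7.82 − 2.65 ≈ 5.2).
- **Zero inflation** — a sample is all-zero across I-exons with probability
  0.375 (the published 26,512 / 70,603 partition); per-region dropout
  (default 5%) additionally zeroes cells of expressing samples.
- **Noise** — Gaussian on the log2 scale, default SD 2.75, the median of
  the published within-tissue SDs (1.5, 2.3, 3.2, 3.9). These defaults are
  calibrated to those printed summaries only; no claim is made that they
  reproduce the full GTEx dispersion structure.
- **Coding/non-coding correlation** — one standard-normal latent factor per
  sample enters both members of each I-exon/C-gene pair with weight √ρ
  (default ρ = 0.6), the simplest mechanism producing the observed
  Z-score correlation.

Coverage tracks are uniform per-base depth per region
(`depth = RPKM × library × read_length / 1e9`), since quantitation
consumes AUC only; the quantify ∘ generate round trip is exact for
non-zero RPKM, and the ≤ 5% acceptance band allows for future read-level
generators. Inter-region background defaults to 0 with a configurable
constant depth for robustness tests. The locus generator writes i.i.d.
background bases at a target GC fraction and stamps AGCT copies evenly
into each 500 bp window of a planted region so every window meets its
motif target.

Not emulated: read-level sampling (FASTQ), alignment and splice junctions,
batch/study effects, library-preparation biases, and the long-tailed
study-size distribution of a real compendium. Passing tests therefore
demonstrate correctness of the computations and recoverability of planted
structure — not that real compendium data would yield the same clusters.

## Problem sizes and numerical choices

Test and acceptance runs use: the full 135,751-table Fisher sweep (n ≤ 40);
1,000 random 10 kb sequences for the motif-scan oracle; 400-sample cohorts
for cluster recovery (two archetypes, 4 log2-unit separation, unit noise,
ARI ≥ 0.9); 10,000 regions for moderation calibration. k-means uses
tol 1e-6 on relative within-SS decrease alongside the assignment fixpoint;
Fisher ties use 1e-7 relative tolerance; Z-scores require ≥ 2 observed
values per column. Seeds are explicit everywhere; identical configuration
reproduces bit-identical output.

## Known limitations

- The S-region caller is a stand-in for a rule the source never formalized;
  calls on real sequence should be reviewed against epigenomic evidence.
- Library size from `total_AUC / read_length` is exact only when reads lie
  fully within the track's span.
- The moderated model assumes a common residual df across regions when
  estimating the prior.
- `enrich` treats samples as exchangeable; study-level pseudo-replication
  in a real compendium would require a hierarchical treatment out of scope
  here.
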