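# Methods

## The problem

Resequencing and array panels in livestock genetics routinely contain
missing genotype calls. Imputation fills them by exploiting linkage
disequilibrium: individuals that share a recent ancestor share long
haplotype blocks, so an observed neighbourhood of markers identifies the
haplotype a missing call sits on. In strongly stratified populations
(multi-breed panels), a pooled reference panel mixes haplotypes from all
subpopulations; each target individual then searches a larger, noisier
haplotype space than necessary. The strategy implemented here partitions
individuals into genetic subgroups first (silhouette-guided K-means) and
imputes each subgroup against its own reference panel, which contains
fewer, longer, more relevant haplotypes.

## Clustering stage

Individuals are clustered on their raw additive genotype coordinates
(0/1/2) with Euclidean distance; missing calls are replaced by the
heterozygote placeholder `1` for the clustering step only. No
standardization is applied: markers all live on the same 0–2 scale, and
rescaling would reweight low-frequency markers. For every k in 2..10,
K-means runs with 25 random restarts and the mean silhouette coefficient
s(i) = (b−a)/max(a,b) is recorded; the k with the highest mean silhouette
wins, ties going to the smaller k (larger clusters mean larger reference
panels). Singleton clusters contribute s(i) = 0. With fewer than three
individuals, clustering is skipped (K = 1, logged). Because silhouette is
quadratic in sample count, inputs beyond 2,000 individuals or 5,000
markers are subsampled for the silhouette computation only (thresholds
configurable). Clusters smaller than 3 individuals are merged into their
nearest centroid neighbour before imputation: a haplotype-copying panel
needs at least two other individuals to be informative.

## Imputation engine

The engine is a Li–Stephens haplotype-copying hidden Markov model over
an unphased diploid target. The hidden state at marker m is the ordered
pair of panel haplotypes the individual's two chromosomes are copying.

* Initial distribution: uniform over all H² ordered pairs.
* Transition: each copy independently stays with probability 1−s or
  jumps to a uniformly chosen haplotype with probability s per adjacent
  marker interval (`switch_prob`, default 0.01). No genetic map is used
  — the marker panel is treated as a single pseudo-chromosome with
  uniform intervals, consistent with how map-free panels are analysed.
* Emission: each copied allele passes through a symmetric flip channel
  with error `mismatch_prob` (default 0.005); the observed genotype is
  the sum of the two emitted alleles. Missing markers emit probability 1.

Because the transition kernel factorizes over the two copies and is
"stay or jump uniformly", a forward or backward step costs O(H²) rather
than O(H⁴): the kernel is two rank-one updates (row sums, then column
sums). Posteriors at missing markers come from forward–backward with
per-step normalization; the reported genotype distribution at a missing
marker is the predictive distribution through the same emission channel,
collapsed to dosages {0, 1, 2}. The imputed call is the posterior argmax;
exact ties prefer the heterozygote, then the major homozygote. Forward
matrices are kept in float64; on panels small enough to enumerate, the
posteriors match exhaustive path sums to ~1e−13.

Each individual is decoded against the panel *excluding its own two
haplotypes* (leave-one-out), so its posteriors never condition on a copy
of itself. The pair state space is quadratic in panel size, so panels are
capped at `max_panel` = 200 haplotypes by seeded random subsampling —
clustering itself is the primary mechanism that keeps H small.

### Panel construction (phasing)

Reference haplotypes are phased from the target individuals themselves:
homozygous sites are forced, heterozygous sites start at random phase,
and missing sites start at a Bernoulli draw from the marker's allele
frequency. Iterative conditional phasing then sweeps the panel: each
individual's first haplotype is matched against all other haplotypes by
Viterbi decoding under the copying model and adopts the copied alleles at
ambiguous sites; the second haplotype is forced to the genotype
complement at heterozygous sites and follows its own Viterbi template at
missing sites. Sweeps stop when no site changes or after `em_iters`
(default 10) passes.

Known limitation: this deterministic scheme has symmetric local optima.
Two individuals heterozygous at exactly the same set of markers can
"mirror-lock" — each phases consistently against the other's arbitrary
phase — because Viterbi assigns no frequency bonus to haplotypes that are
duplicated in the panel. Phase error of this kind barely affects genotype
imputation (the pair emission is symmetric in the two copies), but the
panel should not be treated as a statement about true phase. On simulated
structured panels the phased haplotypes match the generating haplotypes
at >90% of sites.

## Orchestration

The full strategy runs in six stages: validate input → placeholder-fill
and select K → split rows by cluster → impute clusters (independent jobs,
thread pool) → collect → reorder to the original taxa order. Determinism
is independent of the worker count: every cluster's seed derives from the
master seed and the cluster index through a counter-based scheme
(`SeedSequence`), and results are merged by cluster index. Forcing K = 1
reproduces whole-panel imputation bit for bit under the same master seed.
A marker that a cluster observes nowhere (reachable after splitting, even
though the whole panel observes it) is filled from the whole-panel modal
genotype with the whole-panel genotype frequencies as its posterior.

The benchmark harness masks a known-complete matrix (exactly
`round(rate·cells)` cells, uniformly, never leaving a marker fully
missing), imputes, and scores the **matching rate**: the fraction of
masked cells whose imputed genotype equals the hidden truth exactly —
heterozygotes get no partial credit. Wall time is recorded from data
input through the matching-rate computation but is never asserted in
tests (hardware-dependent). A haplotype-accounting report counts distinct
haplotypes over fixed-length marker windows in the pooled panel (N) and
in each cluster panel (N_i): each N_i is far below N on structured data,
which is the complexity argument for splitting (per-individual decoding
work is proportional to its panel's haplotype count). Note that the
pooled *union* count can never exceed ΣN_i for exact window counting;
the reduction that matters is per cluster.

## Synthetic populations

The generator emulates a stratified livestock panel without any real
data. Ancestral allele frequencies are Uniform(0.05, 0.95) — the 0.05
floor keeps major/minor coding stable. Subpopulation frequencies follow
the Balding–Nichols Beta model Beta(p(1−F)/F, (1−p)(1−F)/F), so the
`divergence` parameter plays the role of F_ST (verified against an
independent Weir–Cockerham estimator to ±0.05). Each subpopulation owns
`pool_size` founder haplotypes (default 12) drawn per-site Bernoulli;
every individual receives two founder mosaics with per-interval switch
probability `recomb_rate` (default 0.01). This produces the two features
that matter here — long shared haplotype blocks within subpopulations and
divergent frequencies between them — while remaining desk-scale. It does
not model mutation, selection, sex chromosomes, pedigrees, or realistic
LD decay profiles, so passing tests demonstrate the machinery and the
qualitative structure effect, not calibrated accuracy on any real
species.

Default regimes used in tests and the reproduction script:

* structured: 3 subpopulations × 30 individuals, divergence 0.3 —
  mirrors a three-breed panel;
* homogeneous: 1 subpopulation, divergence 0;
* GBLUP panel: 1 subpopulation × 200 individuals, 3,000 markers,
  pool 12, recomb 0.01 — a *related* panel. This matters: on an
  unrelated panmictic panel the genomic relationship matrix is close to
  identity and variance components are unidentifiable at n = 200;
  heritability recovery requires genuine relatedness, which is also the
  realistic setting for herd data.

## Downstream evaluation

Phenotypes are simulated as y = Zβ + e: QTN positions uniform without
replacement, effects standard normal, and the residual variance set from
the *realized* additive variance, V_E = V_A(1−h²)/h², so every replicate
hits the target heritability (default 0.75; 20 QTNs for association
studies, 10 for prediction).

The association scan is a single-marker linear model (intercept +
dosage), two-sided t-test on the slope, computed in closed form across
markers; monomorphic markers get p = 1. This is a deliberate,
declared substitution for multi-locus mixed-model scans: the package's
contribution is the imputation strategy, and the accounting that follows
is invariant to the scan used. Detection uses Bonferroni 0.05/markers by
default (configurable). Scoring: power = detected QTNs / total QTNs
(each of 20 QTNs is worth exactly 5%); `fdr` = false positives / non-QTN
markers; `type1` = false positives / all markers. The `fdr` definition
divides by non-QTN markers rather than by detections; because that is
nonstandard, the conventional FP/(FP+TP) is always emitted alongside as
`fdr_conventional`, never silently swapped.

Genomic prediction uses GBLUP: G is the VanRaden method-1 matrix
ZZᵀ/(2Σp(1−p)) with Z centered by 2p and monomorphic markers excluded.
Variance components are estimated by REML through a single
eigendecomposition of the training block of G (diagonal jitter 1e−8),
profiling the restricted likelihood over the variance ratio
δ = σ²_E/σ²_A with a coarse log-grid followed by bounded 1-D refinement;
ĥ² = 1/(1+δ). Held-out genetic values are BLUPs through the off-diagonal
block of G. Cross-validated accuracy is the Pearson correlation between
predicted and simulated phenotypes computed *within each test fold* and
averaged over folds and replicates; pooling predictions across folds
instead would inject a mechanical anti-correlation of about
−n_test/n_train through the fold-specific intercepts, which is an
artifact of the scorer, not of prediction quality.

## Numerical and design choices

* Genotype containers use int8 with −1 as the missing sentinel.
* Allele-frequency ties when recovering major/minor from HapMap break
  alphabetically; half-missing diploid calls normalize to missing.
* HapMap reading trusts the `alleles` metadata column for major/minor
  order when informative (keeping numeric→HapMap→numeric an exact
  identity) and falls back to the frequency rule otherwise.
* Numeric files carry no positions; imported markers are placed on a
  single pseudo-chromosome "1" at pos = column index + 1.
* Modal-genotype ties in the frequency baseline take the lower code.
* Every stochastic stage takes a seed; nested seeds derive from
  (master seed, counters) via `SeedSequence`, so enlarging a replicate
  grid never perturbs earlier cells.
* Study sizes in the test suite are desk-scale (tens of individuals,
  hundreds of markers for the HMM contrasts; 200 × 3,000 for GBLUP),
  chosen so the full suite exercises every end-to-end property in
  minutes on one CPU. The mask-rate monotonicity check uses nested masks
  (the 5% mask is a subset of the 10% mask) as a paired design; with
  independent masks the per-seed differences at this scale sit inside
  Monte-Carlo noise.

## Limitations

* The external Beagle backend is a thin optional shell (VCF out, jar,
  VCF in); it requires a Java runtime and is excluded from the test
  suite's claims.
* The HMM imputes genotypes at markers typed in the panel; it does not
  impute ungenotyped markers from an external reference, handle
  multi-allelic sites or indels, or use genotype likelihoods.
* Phasing quality is sufficient for imputation, not for haplotype
  inference per se (see the mirror-lock note above).
* The silhouette criterion can select K > 1 on genuinely homogeneous
  data; the pipeline's accuracy is empirically insensitive to such
  splits, but no guard prevents them.
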