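# Methods

## The screen design being modeled

A modifier screen crosses one sensitized donor strain to a panel of fully
inbred, fully sequenced lines and measures a quantitative phenotype in the F1
progeny — here whole-fly glucose (µg per fly) measured on replicate samples of
pooled flies (3–5 samples per strain) after an overnight fast.  Because every
F1 individual from one cross is genetically identical, the strain is the unit
of analysis: replicate measurements are averaged into a strain mean, and that
mean is the response of the association model.  F1 males inherit their X from
the donor strain, so only autosomal variants are informative; the X is never
simulated and can be excluded from external genotype inputs.

## Phenotype statistics

* `strain_means` takes the arithmetic mean of all replicates of a strain in
  one condition.  Unbalanced designs (2 vs 3 replicates) are handled by the
  plain mean; the ANOVA below uses every individual point.
* `anova_strain_effect` is the classical one-way fixed-effect ANOVA,
  F = MS_between / MS_within, p from the upper F tail.  Zero within-group
  variance with non-zero between-group variance returns the degenerate limit
  (F = ∞, p = 0); all-identical data is an error, not a statistic.
* `pearson_between_conditions` correlates strain means on the strain
  intersection; p is two-sided via the t transform on n − 2 df (sidedness is a
  package choice; one-sided use cases can halve it).
* `protein_control` applies the same ANOVA to protein and correlates
  glucose with protein per sample, dropping missing protein pairwise.  Both
  should be null if glucose variation is glycemic rather than body-size.

## Mixed-model association

Model on strain means y (length n), marker dosage x in {0, 2}:

    y = alpha + x beta + u + eps
    u ~ MVN(0, lambda * tau_inv * K),   eps ~ MVN(0, tau_inv * I_n)

K is the centered GRM, K = (1/m) sum_k (x_k - xbar_k)(x_k - xbar_k)^T, after
per-variant mean imputation of missing dosages.  Centering makes the constant
vector an exact null direction (zero row sums), so K is PSD with at least one
zero eigenvalue.

Estimation uses the spectral trick: with K = U D U^T, rotating by U^T turns
the covariance into diag(lambda d_i + 1) (times tau_inv), so the profile
(restricted) likelihood is one-dimensional in lambda.  The optimizer is a
61-point log-grid on lambda in [1e-5, 1e5] followed by bounded Brent
refinement in the best bracket; REML is the default objective (ML available).
Negative eigenvalues of K within tolerance are clipped at zero; K failing PSD
beyond 1e-6 (relative) is an error.

Per-variant tests are Wald t statistics with n − 2 df.  Two scan modes:

* `null_lambda_reused` (default): lambda-hat from the null model is reused for
  every variant, reducing each fit to a weighted two-column regression solved
  in closed form array-wise.  This is the standard population-scale
  approximation and is exact under the null.
* `per_variant_lambda`: lambda re-optimized for each variant; exact but
  linear-scan slow, intended for sensitivity analysis on small panels.

With lambda forced to 0 the scan reduces to OLS simple regression exactly
(tested to 1e-6 relative).  Variants constant after imputation yield NA rather
than aborting a genome scan.  No multiple-testing correction is applied to the
screening threshold (p < 1e-4 by default) — the design is a hypothesis
generator, not a confirmatory test — but a Benjamini–Hochberg column can be
emitted for orientation.

Filtering order: non-biallelic records, excluded chromosomes, monomorphic
variants, then (only when requested) MAF < threshold.  The default applies no
MAF filter: rare modifier alleles are part of the design, and the MAF > 0.05
re-filter is exposed for sensitivity analysis.

## SNP-to-gene assignment

Coordinates are 1-based fully closed (GFF3).  A variant is assigned to every
gene whose body extended by the window contains it; the window default is
1,000 bp and the boundary is inclusive at exactly 1,000 bp (1,001 bp misses) —
the inclusive reading of "within ±1 kb" is a documented package choice.  Site
classes: exon, then UTR (5′ and 3′ share one priority tier), else intron
inside the body; upstream/downstream by strand in the flank.  Multi-gene hits
are resolved by priority exon > UTR > intron > flank, ties by smaller
distance, then lexicographic gene ID.  The candidate table keeps both views:
all assignments (a variant may support several candidate genes) and the
resolved unique assignment (used for site-class counts and for GSEA).
Exonic consequence sub-classes (synonymous/nonsynonymous/start-gain) need
transcript and codon data and are accepted as a precomputed input column, not
computed internally.

Lookup uses an interval tree per chromosome; correctness is pinned to a
brute-force O(genes × variants) scan on random fixtures.

## GSEA

Gene score = −log10(min p over the gene's uniquely assigned variants); zero
p-values are capped at −log10 of the smallest positive double.  Ranking is
descending with gene-ID tie-break so the order is total.  For a set S of
N_H genes in a universe of N:

    P_hit(i)  = sum_{j<=i, j in S} |s_j|^w / N_R
    P_miss(i) = sum_{j<=i, j not in S} 1/(N - N_H)

ES is the running sum's value at its maximum absolute deviation; weight
exponent w defaults to 1 (w = 0 recovers the classical unweighted KS
statistic, asserted in tests).  The leading edge contains the members at or
before the extremum (after it for negative ES).

The null permutes gene labels on the fixed score vector, preserving set size;
p = (1 + #{perm ES ≥ observed}) / (1 + n_perm) on the positive side, the +1
avoiding zero p-values.  Gene-label permutation matches a rank-list-only
input; phenotype permutation would require re-running the GWA per permutation
and is out of scope.  Output filters mirror the screening convention:
ES > 0, membership ≥ 3 (the comparator is configurable to strictly-greater —
both conventions exist in practice and the package defaults to ≥), p < 0.05.
Null distributions are cached per set size within one call, so equal-sized
sets share permutations; this only couples their Monte-Carlo noise.

## Interaction subnetwork

Candidate u is retained iff some candidate v ≠ u is adjacent, or a
non-candidate b is adjacent to both u and some candidate v ≠ u (one bridging
node; paths with two intermediates never qualify).  Bridges are the
non-candidates mediating at least one retained pair; all edges among retained
nodes are kept.  Edge weights never affect retention — the criterion is
topological — but are carried through for display.  The interaction network
is always a user-supplied edge list; no online service is queried.  The rule
is pairwise and monotone (adding edges never removes a retained candidate)
and is pinned to a BFS-depth-2 brute force in tests.

## Synthetic data generator

What it emulates, and the defaults (all overridable in `SimConfig`):

* **Panel**: 200 fully inbred lines, dosages {0, 2}, optional missing calls
  mean-imputed downstream.  4 autosomal arms of 1 Mb each (names 2L, 2R, 3L,
  3R).  Positions are uniform draws; no linkage-disequilibrium decay, no
  sequence content.
* **Allele frequencies**: a Beta(0.8, 0.8) bulk rescaled to [0.05, 0.5] plus a
  rare tail — 30% of variants uniform on (0.005, 0.05) — reflecting a panel
  that retains rare alleles.  Alt/minor folding is random.
* **Relatedness**: Balding–Nichols cluster divergence — cluster frequency
  ~ Beta(p(1−F)/F, (1−p)(1−F)/F) around ancestral p with F = `fst`.  One
  cluster (F = 0) gives a structureless panel; the structured tests use
  F = 0.25–0.3 with 2–3 clusters, strong enough to inflate naive OLS.
* **Phenotypes**: strain genetic value = Σ effect × dosage + polygenic draw
  MVN(0, σ_g²K); replicates add N(0, σ_e²) with σ_e = 0.25 µg/fly around a
  1.2 µg/fly baseline, 3 replicates per strain — matching the measured
  screen's scale (strain means ~0.4–2.4 µg/fly).  σ_g² is set from
  `h2_polygenic` so the model's λ equals h2/(1−h2) exactly (σ_g² = λσ_e²/r
  for r replicates), which is what the λ-recovery tests exploit.  Values are
  truncated at zero because glucose is a concentration; at the default
  signal-to-noise the truncation is rare and is a documented mild deviation
  from Gaussianity.
* **Annotation**: genes of 2–8 kb tile each arm with 3–12 kb intergenic gaps,
  each gene carrying UTRs and 1–4 exons whose intervals tile the body exactly
  (introns are the gaps); an overlap fraction can slide genes into each
  other's flanks to exercise multi-gene assignment.  Gaps above 2 kb
  guarantee positions farther than 1 kb from every gene.
* **Gene sets / interactions**: random sets of 5–100 genes plus one planted
  set containing the causal genes; random edge lists plus planted
  candidate–candidate and candidate–bridge–candidate motifs of known counts.

Every generator is deterministic under `seed`; independent named streams
(genotypes, phenotypes, annotation, sets, edges) come from spawned
`SeedSequence`s so changing one stage's usage cannot shift another's draws.

What the generator does **not** model — and hence what green tests do not
certify about real panels: linkage disequilibrium and local haplotype
structure, segregating inversions, batch/block effects in phenotyping,
genotyping error, and residual heterozygosity (treated as missing on VCF
import).

## Problem sizes and numerical choices

Tests and the acceptance script run at the design scale where that is cheap
(n = 200–300 lines; 2,000–5,000 variants; 20–50 replicate seeds; 200–20,000
permutations) — these sizes make the Monte-Carlo intervals used in assertions
tight enough to be meaningful while keeping the whole suite in the minutes
range on one CPU.  Key tolerances: GRM PSD tolerance 1e-6 (relative);
λ grid [1e-5, 1e5] with 1e-6 bracket refinement; OLS-equivalence asserted at
1e-6 relative; binomial/KS bands in stochastic tests are stated inline next
to the sample sizes they correspond to.

Known limitations: the EMMAX approximation slightly misstates per-variant λ
under strong single-locus effects (the exact mode exists for that); the
permutation GSEA tests set-size-conditional significance, not the
phenotype-level null; the one-bridge network rule is pairwise — a candidate
retained only through a bridge shared with an otherwise-unretained candidate
is a convention documented here, since both readings exist.

## Pipeline

`modscreen run` executes simulate → phenostats → gwa → annotate → gsea →
network from one YAML config (defaults in `modscreen.pipeline.DEFAULT_CONFIG`;
any subset of stages can be toggled, with file inputs replacing the simulate
stage).  Each run writes a manifest with the config digest, seeds, package
version and SHA-256 of every output; re-running with an unchanged config is a
no-op unless `--force`.  Exit codes: 0 success, 2 config error, 1 runtime
error.
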