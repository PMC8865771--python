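# Methods

`modepairs` implements the comparative statistics of a replicated
sexual-versus-parthenogenetic genome study: per-individual heterozygosity from
variant calls, structural-variant (SV) quality filtering and population
merging, branch-site positive-selection summaries, and permutation inference
for reproductive-mode effects across species pairs. The unit of replication
throughout is the **species pair** — one sexual species and its closest
parthenogenetic relative — which separates the consequences of
parthenogenesis from lineage-specific effects.

## Heterozygosity estimation

Per-individual SNP heterozygosity is

    het rate = (# heterozygous SNPs passing filters) / (# callable sites),

with a conservative filter: variant quality >= 300 (phred) and depth >= 15x
in at least one individual carrying the record (`filter_snps`, both
thresholds configurable; a `per_sample` depth rule is available). Missing
genotypes never enter the numerator; the denominator comes only from the
callable mask (BED, 0-based half-open, normalized by merging overlaps and
bookends). VCF positions are 1-based; all internal interval arithmetic is
0-based half-open, converted at the format boundary. Any genotype with two
distinct allele indices (including e.g. `1/2`) counts as heterozygous.

Species pairs are compared by the fold-difference of species-level rates,
`mean(sexual individuals) / mean(parthenogen individuals)` (median available;
an exactly zero parthenogen aggregate yields infinity with an explicit flag).
The origin of parthenogen variation is summarized by the shared-SNP fraction:
the proportion of parthenogen SNP positions that are also polymorphic
(alternate allele in >= 1 individual) in the sexual relative, positions taken
as given on a shared coordinate system.

## Heterozygosity decay under automixis

`expected_heterozygosity(h0, lambda, mu, t)` models the erosion of
heterozygosity in an automictic parthenogen as a per-generation loss process
with mutational input:

    h_{t+1} = (1 - lambda) h_t + 2 mu
    h_t = (h0 - h*) (1 - lambda)^t + h*,   h* = 2 mu / lambda   (lambda > 0)
    h_t = h0 + 2 mu t                                           (lambda = 0)

`lambda` is the per-generation fraction of heterozygous sites rendered
homozygous (inbreeding-like loss under automixis), `mu` the per-site
per-generation mutational heterozygosity input. These are free knobs of the
simulator, not estimates; the generator can drive the parthenogen
heterozygosity from this recurrence (`use_decay`).

## SV filtering and merging

Manta-style SV calls (DEL/INS/DUP/INV with breakpoints, split-read and
read-pair support, and locus coverage) are filtered by three rules: length
>= 31 bp (calls of 30 bp or less are discarded), at least one supporting
split read or read pair, and locus coverage inside the sample's expected
window. Heterozygous calls at roughly twice the expected coverage are the
signature of collapsed repeats and similar false positives, and the window
filter removes them. Windows default to `[0.5, 1.5] x median(sample depth)`
— a reproducible stand-in for per-sample inspection of coverage
distributions; the multipliers are this package's parameterization.

Filtered calls are merged into population calls by single-linkage clustering
within each (chromosome, type, strand) stratum: two calls link iff **both**
breakpoint distances are strictly below 100 bp (an `any_breakpoint` variant
links on either). Single linkage is transitive, so chains can span more than
100 bp end to end; this matches the behavior of the standard SV-merging
tools. The cluster representative is the member with the smallest
(start, end, sample); output order is deterministic, and the clustering is
invariant to input order. Strand defaults to `+/+` for non-inversion types.
The implementation (sorted sweep + union-find) is checked in the tests
against a brute-force transitive closure over the pairwise link relation.

## Selection summaries

Per gene and terminal branch, the branch-site likelihood-ratio statistic is
stored on the scale to which its null applies (the doubled log-likelihood
difference). P-values use the upper tail of chi-square(1) by default;
a 50:50 boundary mixture of chi-square(1) and a point mass at zero
(`mixture50`, p = 0.5 * tail for positive statistics) is offered because the
boundary mixture is the common asymptotic for this test. Q-values are
Benjamini–Hochberg, pooled across **all branches of all genes** (statsmodels
implementation; the tests hold it to a brute-force step-up oracle). A branch
is called positively selected when q < threshold, strictly; thresholds 0.05
and 0.01 are the conventional operating points.

Gene-set overlap between species is tested against the uniform-draw null:
expected k-set overlap `N * prod(|S_i|/N)`, an exact hypergeometric upper
tail for k = 2, and seeded Monte-Carlo for k >= 2; per-combination p-values
are BH-corrected across combinations.

## Paired permutation inference

All mode-effect inference shares one machinery with two randomization
schemes:

* **within_pair** (canonical): the (sexual, parthenogenetic) labels are
  swapped independently inside each pair — 2^P labelings for P pairs,
  enumerated exactly when 2^P <= `exact_cap` (default 4096), otherwise
  seeded Monte-Carlo. Exact p-values are tail fractions over the full
  enumeration (identity included, so p >= 1/2^P); Monte-Carlo p-values use
  the add-one estimator (b+1)/(B+1). Ties count as exceedances within 1e-12.
* **free**: each species' data (value, count pair, or score summary) is
  permuted wholesale across the design, reassigning mode and pair together,
  by seeded Monte-Carlo. This is an exact randomization when per-species
  data are exchangeable. Note that relabeling modes while holding pair
  assignments fixed is *not* such a randomization once the statistic adjusts
  for pair — we measured it anticonservative for the F statistic and badly
  conservative for raw coefficients — hence the data-permutation definition.

Three tests:

* `mode_permutation_test` for per-species quantities (heterozygosity rate,
  SV rate, TE fraction). Statistics: the F for mode in a two-factor
  (mode + pair) fixed-effects ANOVA, or the mean within-pair difference
  (within-pair scheme only). Rates are log10-transformed by the pipeline
  (offset 1e-12 keeps exact zeros finite) so that no single pair dominates
  the statistic across orders of magnitude.
* `paired_count_test` for per-species (selected, tested) gene counts. The
  statistic is the mode coefficient of a binomial logit regression on mode
  plus fixed pair effects. This replaces a random-pair-effect GLMM: with
  five pairs the random-effect variance is weakly identified, while fixed
  pair effects plus within-pair permutation give exact finite-sample
  inference; a Wald p-value from the observed fit is reported alongside for
  comparison.
* `score_permutation_glm`, threshold-free: the mode coefficient of a linear
  model of per-branch LRT scores on mode plus fixed pair effects, with whole
  species relabeled (all branches move together). With pair fixed effects
  the coefficient reduces to `sum_j w_j d_j / sum_j w_j`, `w_j = n_u n_v /
  (n_u + n_v)` and `d_j` the within-pair difference of species mean scores,
  which makes the permutation loop a closed-form batched computation.

Under the free scheme both coefficient tests default to the studentized
statistic (coefficient / standard error): heterogeneous draws make the raw
coefficient non-pivotal, while the t-form restores calibration (measured
type-I 0.042–0.05 at nominal 0.05 over 500 null studies). Within-pair
draws are all balanced, so the raw coefficient is used there. The batched
statistics (FWL-residualized F, weighted OLS coefficient and t, IRLS
binomial coefficient and SE) are each verified against statsmodels fits in
the unit tests.

Discreteness matters at five pairs: one-sided exact within-pair p-values
live on {k/32}, so the smallest attainable p is 1/32 ≈ 0.031; the two-sided
mean-difference and the ANOVA-F within-pair nulls have duplicated tails
(every labeling and its global complement give the same statistic), so their
minimum p is 1/16 and they can never reach 0.05. The pipeline therefore uses
the directional mean-pair-difference on log rates for heterozygosity and SV
rates (the study's directional prediction), and the ANOVA F for TE content.

## Synthetic studies

`simulate_study` writes a complete desk-scale study: a design table (P pairs,
one sexual and one parthenogenetic species each, n individuals per species),
one VCF and callable BED per individual, an SV call table, a branch-score
table, and per-species TE read fractions. Everything is deterministic under
one master seed with named child streams per component and species, so e.g.
adding individuals does not perturb the branch scores.

Defaults are chosen once to echo the study's scales: 5 pairs x 5
individuals; L = 1e6 callable sites on a single chromosome (the real genomes
are ~1.4 Gbp; chromosome structure is irrelevant to every statistic here
except SV merging, which gets multi-chromosome fixtures in the tests);
sexual per-site heterozygosity 4e-3 and parthenogen 5e-6 (below the 1e-5
order observed for parthenogens); shared-SNP fraction 0.12 (within the
observed 6–19% band); 7155 genes scored per terminal branch with selection
fractions 0.06 (sexual) vs 0.03 (parthenogen) and LRT noncentrality 25;
SV rate 2e-5/bp with false positives planted at 5e-6/bp and twice the mean
coverage, plus a 15% fraction of too-short (<= 30 bp) calls; TE read
fractions 0.218 ± 0.004 with a +0.013 clade shift shared by both members of
the affected pairs and no mode effect. Depths are Poisson around 40x and
qualities pass the default filters unless a failure fraction is configured.

What the generator does *not* emulate: sequence context (no reads, k-mers or
alignments), linkage and coalescent structure, per-species heterozygosity
scatter beyond the mode means, mapping artifacts other than the planted
2x-coverage class, and polyphyletic parthenogenetic lineages. Passing tests
therefore demonstrate that the estimators and tests recover the statistical
structure they assume — unbiased rate recovery, exact permutation
distributions, planted-artifact removal — not that the filters are optimal
for any particular real dataset.

## Numerical choices and limitations

* Exact tail p-values include the identity labeling, so p is never 0; ties
  count as exceedances with tolerance 1e-12.
* Constant responses make the F statistic undefined; the test returns p = 1
  with a warning rather than failing.
* The IRLS for the batched binomial fits clips the linear predictor at ±12
  and adds a 1e-8 ridge, so separated configurations stay finite with their
  ranking preserved.
* Problem sizes in the test suite (e.g. 2e4-site genomes and 150–300 genes
  in the 500-replicate calibration, 1e6–2e6 sites for estimator checks) are
  the package's desk-scale operating points; all scale linearly.
* The shared-SNP operation does not lift coordinates between assemblies;
  cross-species comparability of positions is the caller's responsibility.
* No phylogenetically explicit correction beyond the pair structure; no
  breakend/translocation SV handling; no BCF or indexed VCF access.
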