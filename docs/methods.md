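# Methods

## Design

The pipeline analyses a two-arm (GDM vs control), three-timepoint (t1 early
pregnancy, t2 late pregnancy, t3 postpartum) cohort in a self-controlled
fashion: all inference is on within-subject *changes*, never on raw
cross-sectional abundances. The unit of analysis is the interval log-ratio

L[s, f] = ln((a_f(s, later) + ε) / (a_f(s, earlier) + ε))

on per-sample relative abundances, with a fixed pseudocount ε = 1e-6
(configurable). The pseudocount keeps L finite when a feature is absent at
one timepoint and preserves exact antisymmetry under timepoint exchange.
Any per-subject multiplicative offset of the composition cancels exactly in
L, which is the point of the self-controlled design.

## Permutation testing

The per-feature statistic is the difference of group means of L. The null
is generated by permuting group labels at the **subject** level (never at
the sample level — within-subject pairing must be preserved), applying the
same permutation to every feature in a round so that cross-feature
dependence is carried into the null. Two-sided p-values use the add-one
estimator p = (1 + #{|stat_perm| ≥ |stat_obs|}) / (n_perm + 1), so p is
never 0 and never below 1/(n_perm + 1). A tolerance of 1e-12·(1 + |stat|)
guards the ≥ comparison: a permutation logically identical to the observed
labeling must count as an exceedance even when floating-point summation
order perturbs the last bits. Default n_perm = 1,000; the statistic is
computed for all rounds at once as a (n_perm × subjects) × (subjects ×
features) matrix product.

OTU families are BH-adjusted within each interval separately and gated at
FDR < 0.1 into Set1 (t2 vs t1) and Set2 (t3 vs t2). Pathways are gated on
raw permutation p < 0.05 with no FDR step — the pathway stage is treated as
a screening layer whose members are interpreted jointly (clusters,
recurrence), not individually. BH is delegated to
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`.

The test statistic is deliberately the plain mean difference under label
permutation rather than a repeated-measures ANOVA F: under subject-label
exchange the two are monotonically related for a single interval contrast,
and the mean difference keeps the permutation distribution interpretable in
log-units. This choice is recorded in every run manifest.

## Pathway activity

Activity is the linear aggregation activity[s, p] = Σ_f contrib[p, f] ·
relabundance[s, f]. The phylogenetic hidden-state prediction that produces
contribution matrices (PICRUSt2) is upstream of this package; its output
contract (pathways × features weights, MetaCyc-style ids) is the module
boundary. Activities are non-negative and linear/homogeneous in the
composition; all-zero pathways are flagged, not dropped. Activity changes
reuse the identical log-ratio + permutation machinery (same ε).

The direction test for selected pathways is a two-sided Fisher exact test
on the 2×2 table of arms × sign of the mean activity change (positive vs
non-positive). A table with a zero margin yields p = 1 with a warning.

## Clustering and outliers

Significant pathways' change profiles (rows = pathways, columns =
per-subject activity log-ratios, GDM subjects first) are column-centered
(not scaled — activities share units), projected by PCA with a
deterministic sign convention (each loading's largest-magnitude entry made
positive), and clustered by best-of-50 k-means++ (k = 3 by default) on the
first two PC scores — the space in which results are plotted and in which
the outlier rule is defined. The outlier filter removes pathways with
PC2 < −5 or PC2 > 5 (strict inequalities; values exactly at ±5 are kept)
and is applied to the Set2 analysis only. Cluster ids are canonicalized by
descending cluster size with ties broken by the lexicographically smallest
member pathway id, so labels are stable across platforms.

## Metabolite recurrence

Within each pathway cluster, every catalog compound is counted by the
number of member pathways containing it; compounds with count > 1 are
*recurrent*. Recurrent compounds are intersected with a
hormone-metabolism-related compound set (preserving recurrence order), and
a cluster's *representative pathways* are those whose compound sets
intersect a focal family (packaged: butanoate-related — butanoate,
butanoyl-CoA, crotonyl-CoA, acetoacetyl-CoA; mevalonate-related —
(R)-mevalonate, DMAPP, IPP, GPP, GGPP, MEP), ranked by intersection size
then selection p. "Enrichment" is operationalized as this non-empty
intersection ranking because no parametric enrichment statistic is implied
by the recurrence screen; an optional hypergeometric enrichment p against
the catalog's compound universe is available for users who want one.
Compound identity is exact string match; synonym resolution is the
catalog's job. A currency-metabolite blocklist (H2O/ATP-type compounds) is
available and off by default.

## Diversity and ordination

Alpha diversity is computed per sample via scikit-bio: observed richness,
Shannon entropy with natural log, and Simpson as 1 − Σp² (the common
ecology convention; the reciprocal form 1/Σp² is not used — the choice is
recorded in the manifest). No rarefaction is applied; library depth is
reported next to the indices so depth confounding can be judged. Group
comparisons per timepoint use the two-sided Wilcoxon rank-sum test — exact
null when both groups have ≤ 10 samples and no ties, tie- and
continuity-corrected normal approximation otherwise (the continuity
correction keeps the approximation within 0.02 of the exact p at n = 10).

Ordination selects the top-100 features by mean absolute deviation
(MAD = mean |x − mean x|) of relative abundance across all samples,
excluding MAD = 0 features, and projects samples onto the first two Fisher
discriminants of the six group × timepoint classes. The discriminant
solver is written against the generalized eigenproblem
S_b w = λ S_w(s) w with the shrunk within-scatter
S_w(s) = (1 − s)S_w + s·(tr S_w/p)·I, because the ridge semantics at the
boundary s = 1 (within-scatter replaced by an identity scaling, so
discriminants become eigenvectors of the between-scatter) must hold
exactly; default shrinkage 0.1. Singular within-scatter at s = 0 raises an
error that suggests shrinkage rather than silently regularizing.

## Clinical statistics

Each clinical feature is tested with a pooled-variance Student's t-test
when Shapiro–Wilk finds p > 0.05 in **both** arms (the conservative
per-group reading of "normally distributed"; Welch is available), and the
Wilcoxon rank-sum test otherwise. A constant arm (Shapiro undefined) falls
to the rank-sum path with a warning. The family of p-values is BH-adjusted
and significance called at FDR 0.05. The packaged 16-entry reference
p-value family (`REFERENCE_CLINICAL_P`) reproduces its published FDR
column to four decimals, including the min-step plateau at 0.9300.

## Synthetic cohorts

The generator emulates the cohort structure the analysis assumes — 27 + 27
subjects, three timepoints, ~300 OTUs — as a Dirichlet-multinomial model on
a softmax composition:

* log-normal baseline log-abundances across features (σ = 1.2);
* a per-subject × feature random intercept (σ = 0.8), shared across
  timepoints, carrying the between-subject variation that the
  self-controlled statistic is designed to cancel;
* within-subject Dirichlet perturbation with concentration
  `overdispersion × composition` (default 10,000) — most 16S
  overdispersion in repeated-measures designs is between subjects, which
  the intercept carries, so the within-subject concentration is
  deliberately high;
* log-normal library sizes around `sequencing_depth` (default 50,000,
  CV 0.3), multinomial counts.

Planted effects: `n_planted_set1` features diverge between the arms by
`effect_log_units` (default 1.5, natural log) over t1→t2, `n_planted_set2`
features over t2→t3. Three construction choices keep the planted cohort
honest, and all three were made from the compositional analysis of the
model rather than tuned:

1. **Symmetric half-shifts.** GDM moves by +s·effect/2 and control by
   −s·effect/2 (sign s alternating across planted features, as real
   two-arm cohorts show taxa moving in both directions). The group
   contrast is exactly `effect_log_units`, while the second-order (even)
   perturbation of the softmax normalizer is identical in both arms and
   cancels in the contrast.
2. **Share balancing.** The up- and down-shifted blocks' total baseline
   shares are equalized exactly, so the first-order normalizer
   perturbation vanishes. Without 1–2, renormalization leaks a common
   spurious log-ratio shift onto every unplanted feature and they cease to
   be true nulls.
3. **Moderate prevalence.** Planted baselines are redrawn with a narrow
   spread (σ = 0.5) at typical abundance, so planted features have
   adequate counts in every subject; otherwise zero counts hit the ε floor
   and small-α digamma bias inflates the realized contrast well beyond the
   nominal effect. A depth too low to give planted features an expected
   count ≥ 1 triggers a manifest warning, not an error.

The pathway-DB generator groups pathways into latent clusters that
concentrate 90% of their contribution weight on a shared feature block
(up-shifted planted, down-shifted planted, unplanted, …) plus 10% on
random background features; cluster members share one signature compound
(drawn from the butanoate/mevalonate families) which becomes a planted
recurrent metabolite, plus 1–5 private compounds each. The clinical
generator draws unit-SD normals (log-normals for skew-flagged features)
with specified standardized mean differences.

What the generator does **not** emulate: phylogenetic correlation between
taxa, realistic sparsity patterns (a `dropout_low_fraction` knob forces a
near-zero rare tail but defaults to 0, emulating a prevalence-filtered
feature table — note that heavily zero-inflated features make permutation
p-values conservative, not anticonservative), taxon-specific library
biases, or longitudinal autocorrelation beyond the shared intercept.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated model, not robustness to every
property of real 16S data.

## Problem sizes and numerical choices

Calibration and recovery checks run at the cohort's native size (27 + 27
subjects, 200 features, 1,000 permutations) with 10–50 replicate cohorts,
and 100 replicates for single-pathway recovery — enough that the measured
rates sit well inside their bands (recovery ≈ 1.0 against the ≥ 0.9
requirement; false-discovery proportion ≈ 0.09, the BH design point, against
the ≤ 0.10 bound). Sub-seeds for every stochastic stage are derived by
SHA-256 hashing of (master seed, stage name), so adding a stage never
perturbs another stage's stream and all results are bit-reproducible for a
given seed. Degenerate inputs are first-class: zero-sum samples, single
groups, sub-minimum group sizes, zero-variance matrices and zero-margin
contingency tables all raise typed errors (or warn, where the design says
warn) rather than producing silent numbers.

## Known limitations

* The permutation test is exact only under exchangeability of subjects
  within arms; covariate imbalance (age, BMI) is assumed handled by cohort
  matching, and no covariate adjustment is offered.
* Pathway activities are linear aggregates without 16S copy-number
  correction or per-taxon stratification.
* Recurrence counts depend on the compound catalog's granularity and
  synonym conventions; counts are not comparable across catalogs.
* k = 3 clusters is a configuration constant, not selected by any
  model-selection criterion.
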