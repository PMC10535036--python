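# Methods

## The analysis model

`metabolodiv` treats a metabolome as an ecological community: each spectral
feature (an ion with a given m/z and retention time, in one ESI polarity) is
a species, each LC-MS sample a sampling unit, and ion abundance the species'
abundance. This is an analogy, not a mechanistic model; its value is that the
community-ecology toolkit (accumulation curves, nonparametric richness
estimators, entropy-based diversity, null rank-abundance models) quantifies
the *compositional* response of the metabolome to treatment without
requiring any compound identification. Identification enters only at the
final stage, and only presumptively (mass-based, MSI level-3 style).

Feature identity is the triple (m/z rounded to 4 decimals, rt rounded to
2 decimals, ESI mode). The rounding precisions are configurable because the
matching tolerance used by acquisition software to delimit a feature is
instrument-dependent and typically unreported; two features differing only
in polarity are always distinct, since the underlying ions differ.

## Diversity stage

* **Shannon H′** uses the natural logarithm. With thousands of features the
  natural-log scale puts H′ in the mid single digits and makes
  J′ = H′/ln S directly interpretable as proportional evenness.
* **Incidence counts.** Chao1 and the jackknives are applied to
  presence/absence across samples (singletons Q₁ = features seen in exactly
  one sample, doubletons Q₂ = exactly two). Abundance-based "singletons" are
  ill-defined for continuous intensities, so incidence is the only coherent
  reading. Presence means intensity strictly above the detection threshold
  (default 0: any nonzero abundance counts as detected).
* **Chao1** uses the classic form S + Q₁²/(2Q₂) and switches to the
  bias-corrected S + Q₁(Q₁−1)/2 when Q₂ = 0 (the classic form is undefined
  there). Jackknife orders 1 and 2 follow the standard incidence formulas.
* **Accumulation curves.** The permutation method averages richness-at-k
  over 100 random sample orderings by default (seeded); its step-wise SD is
  the spread the curve plots carry. The exact method evaluates the
  analytical sample-based rarefaction expectation
  E[S(k)] = Σᵢ (1 − C(m−mᵢ, k)/C(m, k)) and is the oracle the permutation
  method converges to.
* **Rank-abundance fits.** The null model is the broken stick,
  pᵢ = (1/S) Σ_{k=i..S} 1/k, which has no free parameters. Geometric-series
  preemption (one parameter, fitted by least squares on log proportions) and
  a lognormal (two parameters, linear fit of log abundance on normal scores)
  are provided as alternatives. Goodness of fit is the G-statistic deviance
  2 Σ xᵢ ln(xᵢ/fittedᵢ) on abundances with fitted counts scaled to the
  observed total; AIC = deviance + 2·(number of parameters). A perfect fit
  has deviance exactly 0.
* **Group profiles** sum replicate abundances within a group before
  computing H′ and J′ (one pooled community per group); richness estimators
  use the within-group per-sample incidence pattern.
* **ANOVA/Tukey.** One-way F (scipy) plus Tukey HSD (statsmodels). The
  compact letter display assigns one letter per maximal clique of the
  "not significantly different" graph, so two groups share a letter iff
  Tukey does not separate them. Distributional assumptions are not tested.
* **Percentages** in all printed summaries are *truncated* to two decimals
  (998/1818 → 54.89), the convention used consistently across the pipeline's
  bookkeeping outputs.

## Chemometrics stage

Quantile normalization maps every sample column to the mean order-statistic
profile (ties get rank-average interpolation); it runs on raw intensities,
*before* the log, so zeros map cleanly, and is idempotent. The log step is
log₂(x + 1) by default. "No scaling" means PCA centers features but does not
scale them to unit variance. Ward linkage is applied directly to
1 − Pearson correlation distances (Ward.D style). Ward's criterion is
derived for Euclidean distances, so this is a documented approximation — the
one in common use for metabolomics correlation heatmaps.

Factor ranking fits one depth-≤3 regression tree per feature, predicting
that feature's intensity from the four encoded design factors, and sums each
factor's impurity reduction across features, weighting each tree by the
feature's variance so flat features contribute nothing. Scores are reported
as percentages of the total. The formulation (per-feature trees rather than
one classifier, impurity aggregation as the importance measure) is a design
choice of this package; shallow trees keep the scores interpretable as main
effects plus low-order interactions.

## Differential stage

Contrasts always compare 4 mM (side A) against 0.2 mM nitrate (side B)
within a genotype × organ cell, with both sampling times pooled into each
side; that yields four contrasts per ESI mode, eight across the two modes,
reduced to four after cross-mode merging. Fold change is computed on raw
group-mean intensities with pseudocount 1 — FC = (mean_A + 1)/(mean_B + 1) —
not on normalized values, so a fold change of 2 means a genuine doubling of
ion abundance. The differential rule is two-sided and inclusive:
max(FC, 1/FC) ≥ 2. Welch's t on log₂(x + 1) supplies volcano p-values when
both groups have ≥ 2 replicates, but no p-filter is applied by default and
no multiple-testing correction is performed: the marker definition is the
fold-change threshold alone. Mode merging is a set union of per-mode
differential sets (features keep their polarity tags); the API refuses to
compute fold changes on a pre-merged library, because pooling ionization
modes before calling mixes ionization efficiencies (mutual suppression).

## Annotation and enrichment stage

Default adducts: positive [M+H]⁺, [M+Na]⁺, [M+K]⁺, [M+NH₄]⁺; negative
[M−H]⁻, [M+Cl]⁻, [M+HCOO]⁻ (configurable via a TSV rule file). Default
tolerance 10 ppm. A feature may annotate to several compounds (hits are
ordered by |ppm error| and all are reported); a compound counts once toward
enrichment regardless of how many features hit it. Fisher enrichment is the
upper-tail hypergeometric probability of ≥ k pathway members among |hits|
draws from the annotatable universe. The permutation null draws the same
number of compounds uniformly without replacement and uses the add-one
estimator p = (1 + #{null ≥ observed})/(1 + B), so p is never 0 and its
floor is 1/(B+1). A pathway is *prevalent* when it is enriched (k ≥ 1 and
p_fisher ≤ 0.05) in strictly more than half of the contrasts.

## The synthetic-data generator

The generator emulates what the analysis assumes about real dual-mode
libraries, with complete ground truth:

* per-sample intensity of feature i in sample j is
  exp(bᵢ + effectᵢⱼ + σ·εᵢⱼ) with feature baselines bᵢ ~ N(μ, feature_sigma²)
  (defaults μ = ln 1000, feature_sigma = 1.0) and replicate noise σ = 0.3.
  The baseline spread shapes the rank-abundance curve; the replicate σ is
  small enough that at 6 replicates/group the chance of a spurious
  |log₂FC| ≥ 1 is negligible under the null;
* a rare tail: 30% of features suffer per-sample dropout with probability
  0.6 (vs. 0.02 for common features), reproducing the steep-then-plateau
  accumulation-curve shape. Dropout is applied after effects, so planted
  fold changes act on the mean as defined;
* planted effects are multiplicative on the mean in the factor's treatment
  level (mutant genotype, 0.2 mM, 30 dag, root), on disjoint feature blocks,
  with an up/down mix; the true per-feature FC is recorded;
* annotatable features inherit m/z from compound masses through a
  mode-matching adduct with Gaussian ppm noise truncated at ±3 SD (default
  SD 2 ppm, so planted features always sit inside the 10 ppm tolerance);
  decoys are rejection-sampled to stay at least 3 tolerances away from every
  adduct-transformed compound mass — unambiguous negative controls;
* generated compound databases place masses on a jittered grid whose
  spacing guarantees every pairwise gap exceeds twice the tolerance at the
  mass-range midpoint, so annotation is never ambiguous by construction.

What the generator does **not** emulate: chromatographic structure (rt is
uniform random), isotope patterns, correlated features from shared
biosynthetic origin, in-source fragments/adduct clusters of the same
metabolite, and batch effects. Passing recovery tests therefore demonstrates
the correctness of the estimators and the calling logic under the stated
statistical model, not robustness to every artifact of real spectra.

A separate study-scale fixture builds contrast-membership sets (identifiers
only, no intensities) whose unique/shared structure reproduces the headline
bookkeeping of the motivating study exactly; it exists to exercise the
reporting arithmetic at realistic scale and carries no spectral content.

## Numerical and design choices

* Percent truncation (not rounding) to two decimals in printed summaries.
* Binarization is strict (> threshold), so a cell equal to the threshold is
  absent.
* The pseudocount in FC and log transforms defaults to 1 (configurable);
  with mean intensities around 10³ it perturbs ratios by < 0.2%.
* Random draws all flow from `numpy.random.default_rng(seed)`; identical
  seeds and parameters give byte-identical outputs across the whole
  synthetic module.
* Degenerate inputs: J′ is NaN (flagged undefined) at S = 1; an all-zero
  abundance vector, a constant vector in correlation, and an empty presence
  matrix are errors; empty differential partitions report total 0 with
  undefined fractions and a flag rather than dividing by zero.
* Problem sizes in the test and acceptance runs (a few hundred features,
  2–6 replicates per design cell) are chosen so every property is measured
  with comfortable margins while the full suite stays fast; sensitivity
  and false-positive targets are evaluated at 6 replicates/group, the
  replicate depth the recovery analysis is designed around.

## Known limitations

* Ward on correlation distances is not Euclidean-consistent (see above).
* The decision-tree factor ranking is one of many defensible formulations;
  its scores are comparable within a run, not across datasets.
* Annotation is presumptive: a hit is a mass coincidence within tolerance,
  not an identification; the multiplicity policy surfaces, rather than
  resolves, ambiguous masses.
* The broken-stick fit is assessed by deviance/AIC only; no formal
  goodness-of-fit p-value is attached.
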