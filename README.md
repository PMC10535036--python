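# metabolodiv

Ecology-style analysis of dual-polarity untargeted LC-MS feature tables.

Untargeted metabolomics experiments produce, per electrospray-ionization
(ESI) polarity, a table of spectral features — ions identified by a
mass-to-charge ratio (m/z) and a retention time (rt) — by sample, with ion
abundances in the cells. `metabolodiv` implements a four-stage pipeline for
comparing such metabolomes across experimental conditions (here: *Arabidopsis
thaliana* wild type vs. the nitrate-reductase-deficient *nia1/nia2* double
mutant, grown at 4 mM vs. 0.2 mM nitrate, sampled at 15 and 30 days after
germination, rosettes and roots analysed separately):

1. **Diversity** — each m/z_rt feature is treated as a *species*. Richness S,
   Shannon diversity H′ = −Σ pᵢ ln pᵢ, Pielou evenness J′ = H′/ln S,
   sample-based species-accumulation curves (permutation and exact
   rarefaction), the nonparametric richness estimators Chao1
   (S + Q₁²/2Q₂), first-order jackknife (S + Q₁(m−1)/m) and second-order
   jackknife, rank–abundance curves with the broken-stick null model,
   Pearson r/R² correlation of richness against diversity, and one-way ANOVA
   with Tukey-HSD letter displays.
2. **Chemometrics** — quantile normalization to the mean order-statistic
   profile followed by log₂(x+1); PCA (centering only) of samples; Ward
   hierarchical clustering on 1 − Pearson correlation distances; per-feature
   regression trees that rank the four design factors by aggregate variance
   reduction.
3. **Differential markers** — per-ESI-mode pairwise contrasts of 4 mM
   vs. 0.2 mM nitrate within each genotype × organ cell; a feature is a
   differential chemical marker when max(FC, 1/FC) ≥ 2, with
   FC = (mean_A + c)/(mean_B + c). Per-mode differential sets are merged by
   set union only *after* calling (pooling modes first biases fold changes —
   the mutual suppression effect), then partitioned into features unique to
   one contrast vs. shared by several.
4. **Annotation & enrichment** — presumptive (MSI level-3 style) annotation:
   each observed m/z is inverted through adduct rules
   ([M+H]⁺, [M+Na]⁺, … , [M−H]⁻, [M+Cl]⁻, …) to candidate neutral masses
   M = |z|·mz − Δ and matched against a compound database within a ppm
   tolerance; pathway over-representation by the upper-tail hypergeometric
   (Fisher) probability and by an empirical permutation null; pathway
   prevalence across contrasts and "k of K" activity counts.

Because real studies of this design rarely deposit their spectral libraries,
the package ships a first-class synthetic-data generator
(`metabolodiv.synthetic_data`) producing log-normal feature communities with
rare-feature tails, planted multiplicative fold-change effects, and features
derived from known compound masses via adduct arithmetic plus ppm noise —
with complete ground truth for every planted structure.

## Worked example

Simulate a dual-mode metabolome with a planted 4× nitrate effect on 20% of
features (6 replicates per design cell), profile its diversity, and recover
the planted markers with the FC ≥ 2 caller:

```python
from metabolodiv import synthetic_data as syn, differential as diff, diversity as div

tables, truth = syn.simulate_feature_table(
    syn.full_design(6),
    syn.CommunityParams(n_features_per_mode=250,
                        dropout_prob_rare=0.0, dropout_prob_common=0.0),
    effects=[syn.PlantedEffect("n_conc", 0.2, 4.0)],
    seed=42,
)
pos = tables["positive"]
for p in div.diversity_profiles(pos, ["n_conc_mM"]):
    print(f"group {p.group}: S={p.S}  H'={p.H_prime:.3f}  J'={p.J_prime:.3f}  chao1={p.chao1:.1f}")

planted = set(truth.differential_features["n_conc"])
called = set()
for spec in diff.build_contrasts(pos.meta, "per_mode_4"):
    res = diff.call_differential(diff.fold_change_contrast(tables[spec.mode_scope], spec))
    called |= res.differential_features()
print(f"planted differential features: {len(planted)}")
print(f"recovered at FC >= 2: {len(planted & called)}  "
      f"(sensitivity {len(planted & called)/len(planted):.2f})")
```

prints

```
group 0.2: S=250  H'=4.828  J'=0.874  chao1=250.0
group 4.0: S=250  H'=5.037  J'=0.912  chao1=250.0
planted differential features: 100
recovered at FC >= 2: 100  (sensitivity 1.00)
```

The 4 mM group is slightly more even (higher J′): the planted effect makes a
fifth of the features either much more or much less abundant in the 0.2 mM
samples, skewing that community's abundance distribution. Every planted
marker clears the two-sided FC ≥ 2 threshold, and with no dropout and
replicate noise σ = 0.3 nothing else does.

A `metabolodiv` console script exposes each stage
(`simulate | diversity | chemometrics | differential | annotate | enrich |
report`); every subcommand writes tab-separated outputs with a provenance
comment header.

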