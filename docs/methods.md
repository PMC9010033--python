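# Methods

This note documents the statistical procedures, numerical choices and the
synthetic-data model that `coalesce-kit` implements, and what its
validation does and does not demonstrate.

## Data model

A cohort is a sample × OTU count matrix annotated with patient, body site
(`oral`/`stool`) and an integer day coordinate (day 0 = first day of
chemotherapy; pre-treatment baseline samples carry negative days), plus a
rooted phylogeny over the OTUs, a taxonomy map, a per-patient per-drug
ledger of *antimicrobial therapy days* (a calendar day with any
administration counts once, regardless of dose, route or frequency), and
per-patient outcomes (neutrophil-recovery day, optional death day,
infection flags). Samples with zero total counts are dropped with a logged
warning; no minimum-depth filter or rarefaction is applied (a count
transformation hook exists but is off by default). OTU presence, wherever
set operations are needed, means count ≥ 1.

## Diversity metrics

Shannon diversity uses the natural logarithm (the R vegan/phyloseq
convention). Bray-Curtis operates on raw counts,
`BC(x,y) = 1 − 2 Σ min(xᵢ,yᵢ) / (Σx + Σy)`. UniFrac is computed from a
single post-order pass that accumulates per-branch descendant proportions;
the weighted variant is the **normalized** one
(`Σ l_b |A_b − B_b| / Σ l_b (A_b + B_b)`), chosen so that all three
metrics share the range [0, 1] and per-patient minima can be pooled and
ranked on a common scale. Slow per-pair reference implementations
(`coalescekit.reference`) share no code with the fast kernels and back the
agreement tests (1e-10 on random ≤ 16-tip instances); an external
cross-check against scikit-bio is also part of the suite.

## Ordination and global structure

PCoA is classical scaling: Gower double-centering of squared distances,
eigendecomposition, coordinates scaled by √λ. Negative eigenvalues (possible
for semi-metric dissimilarities) are *dropped* with a warning rather than
corrected — the simplest defensible default; variance explained is
reported relative to the retained spectrum. PERMANOVA uses Anderson's
pseudo-F computed from squared distances, with free permutation of sample
labels (no strata) and `p = (1 + #{F* ≥ F}) / (1 + n_perm)`; 999 seeded
permutations by default, with exhaustive enumeration available for ≤ 9
samples. Confidence-ellipse co-membership uses per-group mean and sample
covariance of the first two PCoA axes with the χ²₂(0.95) radius; this is
one concrete formalization of "samples inside both site ellipses".
Hierarchical clustering is average-linkage on the distance matrix (the
linkage is configurable; ties follow scipy's deterministic rule).

## Coalescence classification

For each patient, all oral × stool sample pairs are formed regardless of
collection day, and the minimum pairwise distance is the patient's
statistic. Patients with fewer than `min_pairs = 3` cross-site pairs are
ineligible. Eligible patients are ranked ascending; the bottom quartile —
rank ≤ ⌊n_eligible/4⌋, an integer rank rule rather than a numeric
quantile estimator, which avoids quantile-definition ambiguity and yields
exactly 23 calls from 92 eligible patients — is classified as coalesced.
The default metric is weighted-normalized UniFrac (configurable to
unweighted or Bray-Curtis). The event day assigned to a coalesced patient
is the *later* collection day of the minimizing pair: the coalesced state
is only demonstrably present once both samples exist. Ties in the minimum
break by earlier event day, then patient id, making the output invariant
to input order.

Two validation views accompany the calls. The shared:unique OTU ratio
matches oral and stool samples greedily by nearest day within a ±3-day
window (configurable) and reports |intersection| / |symmetric difference|
of the presence sets; pairs with no unique OTUs are flagged undefined and
excluded from model fits. Domination events require a single genus
*strictly* above 30% relative abundance in a sample; the `unclassified`
aggregation bucket is not a genus and never dominates. Concordant
domination means the same genus dominates at least one oral and one stool
sample of the patient at any study day — simultaneity is not required.

## Time-varying Cox model of antibiotic exposure

Only drugs given to strictly more than 15% of the cohort are analyzed.
Each patient's follow-up runs from day 0 to the coalescence event day, or
to censoring at neutrophil recovery or death (whichever first); the risk
clock is days since chemotherapy start, and therapy days before day 0 do
not count. Follow-up is split into counting-process rows `(start, stop]`
on which covariates are constant: a therapy day *d* becomes effective at
the start of day *d + 1* (the interval `(d, d+1]`), so an exposure can
never explain an event that precedes it, and risk sets
`{j : start_j < t ≤ stop_j}` handle delayed entry — together this removes
immortal-time bias. Two encodings are provided: `cumulative` (running
count of therapy days; HR per additional day) and `any` (absorbing 0→1
indicator; HR once exposed). A coalescence event on day 0 leaves no
at-risk interval and is a validation error; an event day after the
censoring day likewise.

The partial likelihood uses the **Breslow** tie approximation (events are
day-granular, so ties are expected; Efron handling would be a natural
extension) and is maximized by Newton-Raphson with step-halving,
converging when the score falls below 1e-9. Standard errors come from the
observed information; Wald CIs are `exp(β ± 1.96·se)`. A covariate with no
variation inside any event's risk set yields β = 0 with infinite standard
error, flagged rather than fabricated; runaway estimates (monotone
likelihood / separation) are flagged as non-converged. Models are
univariate per drug, mirroring a per-drug screening table; no
multivariable adjustment is attempted. Equivalence checks: a 1-D
brute-force maximization of the same coded likelihood (1e-6 agreement), a
standard Cox fit on unexpanded data for time-fixed covariates, and
lifelines' time-varying fitter on simulated tables.

## Longitudinal mixed models

Shannon diversity (per site) and the shared:unique ratio are modeled with
fixed effects day, coalescence status, and their interaction, plus a
random intercept per patient — intercept-only, since the analysis targets
population-average slopes. Estimation is REML via statsmodels `MixedLM`;
coefficients carry large-sample Wald z tests with no denominator-df
correction (a deliberate simplification that can differ slightly from
small-sample-corrected toolchains). The interaction is additionally tested
by a likelihood-ratio comparison of maximum-likelihood fits with and
without the term (1-df χ²), the ANOVA-style test. Rank-sum and
signed-rank group tests use scipy; Benjamini-Hochberg adjustment is the
standard step-up `q(i) = min_{j≥i} m·p(j)/j`, applied within an explicitly
supplied family (e.g. one taxonomy level per call).

## Outcome association

Coalescence vs infection is a 2×2 Pearson χ² (1 df, no Yates continuity
correction, matching Stata's default) over eligible patients, with the
odds ratio `ad/bc` and Woolf log-scale CI; a zero cell triggers a 0.5
continuity correction of all four cells, flagged in the output. Fisher's
exact test is available for small cells via scipy but is not the default.

## Synthetic cohort generator

The generator reproduces the *structure* of an induction-chemotherapy
cohort, with every distributional choice a stand-in (the motivating
observational data carry no generative model); defaults aim at the
published cohort's scale:

- **Sampling**: a baseline sample at day −2, then both sites every 3 days
  (≈ twice weekly) until neutrophil recovery, drawn discrete-uniform on
  [18, 35] days (bracketing the ≈ 3 weeks typically elapsed before maximal
  coalescence). Death is rare (2%) independent censoring that exercises
  the censoring path.
- **Communities**: 40 oral-specific, 60 gut-specific and 20 shared taxa on
  a random bifurcating tree; per-patient site compositions are Dirichlet
  (concentration 0.3, giving realistically uneven communities) over the
  site's support; reads are multinomial at Poisson(5000) depth. Genus
  labels cycle through typical oral (Streptococcus, Veillonella, ...) and
  gut (Bacteroides, Blautia, ...) genera so genus-level summaries and
  domination detection have realistic targets.
- **Antibiotics**: every patient starts a prophylactic fluoroquinolone at
  day 0; with probability 0.7 a neutropenic-fever day (uniform on days
  3–10) switches prophylaxis off and starts empiric drugs (cefepime for 7
  days; meropenem in 40% until end of follow-up; linezolid in 25% for 10
  days).
- **Onset hazard**: each day `t`, coalescence onset fires with probability
  `1 − exp(−h_t)` where `log h_t = log h₀ + Σ_d β_d · cum_d(t)` and
  `cum_d(t)` counts therapy days of drug *d* through day `t − 1` — exactly
  the cumulative covariate the Cox builder constructs, so the fitted model
  is correctly specified. Default generative effects are moderate
  (per-day HRs 0.97–1.12 around h₀ = 0.006, yielding ≈ 20–25% coalescers):
  published per-day estimates are cohort-averaged associations, and
  compounding strong per-day multipliers over a month of therapy would
  drive the hazard to degenerate extremes.
- **Mixing**: after onset the stool target composition is
  `(1 − w)·gut + w·oral` with `w` increasing by 0.15 per day and capped at
  0.95 — a rapid ecological takeover consistent with antibiotic gut
  decontamination creating a permissive environment; it ensures coalescence
  is expressed in the samples within about a week of onset.
- **Outcomes**: infection flags are drawn with odds ratios 4.93
  (pre-recovery, base rate 0.25) and 2.72 (post-recovery, base rate 0.20)
  conditional on the true coalescence flag.

Fixed seed and configuration give byte-identical output files. The
dedicated recovery generators (`simulate_exposure_cohort`,
`simulate_diversity_trajectories`) strip away the microbiome layer: the
exposure generator draws event times in *continuous* time from the
piecewise-constant daily hazard, so tied event times have measure zero and
Breslow-vs-truth comparisons are free of tie-approximation bias.

### What passing tests show — and what they do not

Parameter-recovery tests demonstrate that the estimators are correctly
implemented and calibrated *under their own model assumptions*
(proportional hazards in accumulated therapy days, linear mean
trajectories, random intercepts, multinomial sampling noise). The
generator does not emulate compositional overdispersion beyond the
Dirichlet layer, within-patient temporal autocorrelation of communities,
taxon-specific antibiotic susceptibility, measurement batch effects, or
informative censoring — so green tests certify the machinery, not the
biological conclusions one would draw from any particular real cohort.

## Problem sizes used in validation

The shipped calibration runs use 92 patients for the quartile-classifier
count, 20 × 2000-patient cohorts per hazard-ratio recovery (per-day HRs
1.15, 1.13, 1.10, 0.75), 200 × 200-patient replicates for the interaction
slope (−0.017), 1000 random instances for the beta-diversity agreement
check, 500 replicates for PERMANOVA type-I calibration, and a 100-patient
end-to-end pipeline run; each recovery is judged against its truth within
three Monte-Carlo standard errors of the replicate mean.

## Known limitations

- Breslow tie handling slightly attenuates estimates under heavy ties;
  the day-granular cohort pipeline accepts this, and the recovery studies
  avoid it by continuous-time event generation.
- PCoA negative-eigenvalue mass is discarded, not corrected; ellipse
  membership depends on the chosen two axes.
- LMM p-values are asymptotic; no Satterthwaite/Kenward-Roger correction.
- The quartile rule is relative to the analyzed cohort: a cohort with
  globally similar sites would still call ⌊n/4⌋ patients "coalesced".
  Interpretation requires the pooled distance distribution alongside the
  calls.
- 16S OTU data cannot establish strain-level transmission between sites;
  nothing here attempts it.
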