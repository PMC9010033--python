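# coalesce-kit

Analysis toolkit for **oral–stool microbial community coalescence** in
longitudinally sampled patient cohorts.

In patients undergoing intensive chemotherapy, the normally distinct oral
and gut bacterial communities can merge ("coalesce"): typically oral taxa
expand ectopically in the intestine until a patient's stool community
becomes nearly indistinguishable from their own oral community.
`coalesce-kit` implements a complete, tested pipeline for detecting and
characterizing this phenomenon from paired 16S OTU count data:

- **Diversity** — observed OTUs, Shannon entropy `H = −Σ pᵢ ln pᵢ`,
  Bray-Curtis dissimilarity, and unweighted / weighted-normalized UniFrac
  computed from first principles on a rooted phylogeny
  (`d_w = Σ_b l_b |A_b − B_b| / Σ_b l_b (A_b + B_b)`).
- **Community structure** — classical PCoA, PERMANOVA (Anderson's
  pseudo-F with permutation or exhaustive p-values), 95% confidence-ellipse
  co-membership of oral and stool samples, hierarchical clustering.
- **Coalescence calling** — for each patient, the *minimum* beta-diversity
  distance over all intra-patient oral × stool sample pairs; patients in
  the bottom quartile of these minima (rank ≤ ⌊n/4⌋) are classified as
  coalesced. Validations: the shared:unique OTU ratio of day-matched pairs
  over time, and genus-level domination events (> 30% relative abundance)
  occurring concordantly at both body sites.
- **Antibiotic exposure survival analysis** — per-drug time-varying Cox
  proportional-hazards models of coalescence onset. Exposure enters as
  *antimicrobial therapy days* in a cumulative (per-additional-day HR) or
  any-exposure encoding on a counting-process grid, with Breslow partial
  likelihood maximized by Newton-Raphson, censoring at neutrophil recovery
  or death, and a >15%-of-cohort prevalence filter.
- **Longitudinal mixed models** — random-intercept LMMs of Shannon
  diversity (and the shared:unique ratio) with a coalescence × time
  interaction; Mann-Whitney / Wilcoxon group tests with Benjamini-Hochberg
  FDR adjustment.
- **Outcomes** — Pearson χ² and odds ratios (Woolf CI) for coalescence vs
  infection before and in the 90 days after neutrophil recovery.
- **Synthetic cohorts** — a generator with known ground truth (Dirichlet-
  multinomial two-site communities, proportional-hazards coalescence onset
  driven by therapy-day accumulation, convex post-onset mixing of stool
  toward oral composition, infection outcomes with configurable odds
  ratios) used to validate every estimator by parameter recovery.

## Worked example

Everything is driven from a cohort directory of plain-text files
(`otu_table.tsv`, `taxonomy.tsv`, `tree.nwk`, `exposures.tsv`,
`outcomes.tsv`). Generate a synthetic 100-patient cohort and run the
pipeline:

```sh
coalesce-kit simulate --out demo --seed 7
coalesce-kit validate demo
coalesce-kit coalescence demo --metric unifrac-w
coalesce-kit cox demo --encoding cumulative
coalesce-kit outcomes demo
```

which prints (output from the commands above):

```
samples: 2102
otus: 120
patients: 100
tree tips: 120
exposure rows: 2148
outcome rows: 100
ok
25 of 100 eligible patients coalesced (100 total); outputs in demo
        drug   encoding       hr   ci_low  ci_high        p  converged note
    cefepime cumulative 0.940670 0.829933 1.066182 0.338495       True   ok
levofloxacin cumulative 1.021424 0.977409 1.067421 0.345552       True   ok
   linezolid cumulative 0.996275 0.901315 1.101239 0.941787       True   ok
   meropenem cumulative 1.112666 1.058440 1.169670 0.000028       True   ok
           window  chi_square        p  odds_ratio   ci_low   ci_high  corrected
     pre-recovery    8.823529 0.002974    4.030303 1.557081 10.431916  False
post-recovery-90d    3.111111 0.077760    2.315789 0.899433  5.962510  False
```

Reading this: 25 of 100 patients fall in the bottom quartile of minimum
intra-patient oral–stool weighted UniFrac distance and are called
coalesced. In the per-drug time-varying Cox panel each additional
meropenem therapy day multiplies the daily hazard of coalescence by ≈ 1.11
(this cohort was generated with a true per-day effect of 1.12; the other
drugs' weaker true effects are not individually resolvable at n = 100).
Coalesced patients have ≈ 4-fold higher odds of infection before
neutrophil recovery (χ² = 8.8, p = 0.003). The written artifacts
(`calls.tsv`, `dominations.tsv`, `shared_ratio.tsv`, `table1.tsv`,
`association.tsv`) carry the full per-patient and per-drug detail, and
`truth.json` holds the generative ground truth for comparison.

The same operations are available as a library
(`coalescekit.coalescence.classify_coalescence`,
`coalescekit.survival.fit_cox_tv`, `coalescekit.models.fit_lmm`, ...).

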