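# nevi — Neighborhood Environmental Vulnerability Index

A reusable pipeline for building, comparing, and profiling a **Neighborhood
Environmental Vulnerability Index (NEVI)**: a hierarchical, ToxPi-style
composite score that summarizes, per census tract, the social and structural
conditions that can amplify the health impacts of environmental pollution.
It is aimed at environmental epidemiologists and environmental-justice
analysts who want an *adaptable*, theory-driven alternative to single-score
deprivation indices — one that reports not just how vulnerable a
neighborhood is, but which kinds of vulnerability drive the score.

## The index

Features (tract-level percentages, counts, medians from ACS- and
PLACES-style sources) are organized in a tree: 4 equally weighted
**domains** (demographics, economic, residential, health status) containing
24 **subdomains** over 54 features. For tract *t* and feature *j*:

1. standardize: `z_tj = (x_tj − mean_j) / sd_j` (sample sd);
2. direction-align: negate `z` for inverse-coded features (e.g. median
   income), so larger always means more vulnerable;
3. re-center each feature so its minimum is 0;
4. subdomain score: `s_ts = minmax( Σ_{j∈s} z̃_tj )` over tracts, in [0, 1];
5. overall score: `NEVI_t = Σ_s w_s · s_ts` with `w_s = (1/4)(1/n_d)`
   (e.g. 1/28 for a subdomain in a 7-subdomain domain); domain scores are
   unweighted means of their subdomain scores, so the overall score equals
   the mean of the four domain scores.

The registry (the tree, weights, direction flags) is data — a YAML file you
can edit — not code. Around the scorer the package provides: the study's
tract exclusion filters (population < 20, then missing features), an
adapted first-principal-component Neighborhood Deprivation Index (NDI) for
comparison, Spearman rank comparisons overall/by stratum, quartile
classification, complete-linkage hierarchical clustering with gap-statistic
selection of the number of clusters, "high composition" race/ethnicity
sensitivity summaries, and a latent-factor synthetic tract generator so the
whole pipeline is testable without any data downloads.

## Worked example

```python
import nevi

registry = nevi.build_default_registry()          # 4 domains / 24 subdomains / 54 features
cfg = nevi.SimConfig(n_tracts=500, seed=7)        # synthetic five-borough tract table
table, latent = nevi.generate_feature_table(cfg, registry)
retained, log = nevi.apply_tract_filters(table)
print(f"retained {log.n_retained} of {log.n_input} tracts (excluded: {log.counts})")

scores = nevi.run_nevi_pipeline(retained, registry)
print(scores[["overall", "demographics", "economic", "residential", "health_status"]]
      .head(3).round(3))

ndi = nevi.compute_ndi(retained, registry=registry)
cmp = nevi.spearman_compare(scores["overall"], ndi.scores, groups=retained["borough"])
print(cmp.rho.round(3))
```

prints

```
retained 481 of 500 tracts (excluded: {'low_population': 12, 'missing_feature': 7})
             overall  demographics  economic  residential  health_status
geoid
36061000001    0.588         0.550     0.627        0.574          0.602
36081000002    0.570         0.575     0.510        0.496          0.697
36081000003    0.299         0.263     0.315        0.260          0.356
           group    rho    n
0        overall  0.946  481
1          Bronx  0.949   69
2       Brooklyn  0.941  163
3      Manhattan  0.931   71
4         Queens  0.944  157
5  Staten Island  0.948   21
```

Each tract gets an overall score and four domain scores in [0, 1]
(higher = more vulnerable); two tracts with the same overall score can have
very different domain profiles. The Spearman table shows the NEVI agreeing
strongly with the deprivation-only NDI while remaining a distinct,
decomposable measure.

The same workflow is available from a shell:

```sh
nevi simulate --n-tracts 500 --seed 7 --out-dir runs/sim
nevi score    --input runs/sim/features.csv --out-dir runs/scores
nevi compare  --input runs/sim/features.csv --scores runs/scores/scores.csv --out-dir runs/cmp
nevi cluster  --scores runs/scores/scores.csv --out-dir runs/cl
nevi sensitivity --input runs/sim/features.csv --composition runs/sim/composition.csv --out-dir runs/sens
```

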