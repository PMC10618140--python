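# Methods

## Index construction

The NEVI is a ToxPi-style hierarchical composite. Each feature is z-scored
across the retained tracts (sample standard deviation, denominator n−1 —
the default of mainstream statistical software; the construction is
otherwise insensitive to this choice because of the min-max step).
Inverse-coded features are negated at the z-score stage; negating raw
values first would give identical final scores, the z-score variant is used
for numerical symmetry. Every feature column is then shifted so its minimum
is zero, mirroring how ToxPi treats negative inputs, which preserves the
distribution shape without truncation. Feature values are summed within
each subdomain and the sums min-max transformed to [0, 1] across tracts.
The overall score is the weight-sum of subdomain scores with
`w_s = (1/n_domains)(1/n_subdomains_in_domain)`; these weights are kept as
exact rationals so the conservation invariants (Σw = 1, Σ per domain =
1/n_domains) are testable without float drift. Domain scores are unweighted
means of their subdomain scores, which makes the overall score exactly the
mean of the domain scores.

Degenerate inputs are defined, not errors: a zero-variance feature
contributes z ≡ 0, and a subdomain whose sums have zero range scores 0 for
every tract. Both choices keep all scores in [0, 1]. Scoring uses only the
retained tracts — excluded tracts never influence means, sds, or ranges.
All tracts contribute equally (no population weighting).

The registry is a checked-in YAML file, so the feature tree, direction
flags, and hence the weights can be adapted without touching code.
Direction flags in the default registry: median household income,
high-blood-pressure medication use, and the eight prevention-practice
features are inverse-coded (higher values plausibly reduce vulnerability);
all other features are adverse proportions and are direct-coded. The
household-density subdomain sits in the residential domain (the feature
tree's own structure governs, and its weight is 1/28 accordingly). "Age of
housing" is a single numeric feature in years, direct-coded; deriving it
from a median-year-built variable is the data supplier's job. Aggregate
travel time to work is used as supplied (a tract total, not per-worker).

## Exclusion filters

Tracts with population below 20 are removed first, then tracts with at
least one missing feature value among the remainder; the order affects only
which reason a doubly-affected tract is logged under, not the retained set.
Any null is treated as missing (no distinction for suppressed or unreliable
source estimates). GEOIDs are opaque strings; leading zeros survive I/O.

## Adapted Neighborhood Deprivation Index

The comparison NDI is the classic Messer-style construction: z-score a
deprivation variable list, extract the first principal component of the
correlation matrix (via eigendecomposition), and standardize the component
scores. An optional stratification performs the extraction separately per
stratum (borough), following the Shmool-style spatial adaptation. The
component's sign is anchored so the loading on a designated deprivation
variable (default: % below poverty) is positive. The default variable list
— the registry's seven economic features plus female-led households and
household crowding — is a configurable approximation: published NDI
adaptations differ in their exact variable lists and stratification
schemes, so both are parameters rather than fixed choices, and results
using the default list should be described as an adapted NDI.

## Clustering and the gap statistic

Tracts are clustered on their 24 subdomain scores (the level at which
profiles are reported; a domain-level matrix can be passed instead)
with agglomerative hierarchical clustering, Euclidean distance, complete
linkage. The number of clusters is selected with the gap statistic:
`gap(k) = mean_b log W*_kb − log W_k`, where `W` is Tibshirani's pooled
within-cluster dispersion `Σ_r D_r/(2n_r)` and the B reference datasets are
drawn uniformly over each feature's observed range (the simpler reference
distribution; defaults B = 100, k_max = 10). Reference sets are clustered
with the same hierarchical procedure. The chosen k is the smallest k with
`gap(k) ≥ gap(k+1) − se(k+1)`, where `se = sd·√(1 + 1/B)`; if no k
satisfies the rule, k_max is reported. The whole computation is
deterministic given the seed. Merging is delegated to scipy's linkage
implementation, whose tie handling is deterministic; on continuous score
data, equal-distance merge candidates have probability zero, and the test
suite verifies exact agreement with an independent O(n³) agglomerative
implementation on small tie-free inputs. Cluster labels are renumbered by
first appearance in row order, so labels are reproducible but arbitrary;
cross-run comparisons should use the partition, not label identities.
Profile heatmap matrices standardize each subdomain's cluster medians
across clusters using the sample sd; constant columns (including the
single-cluster case) standardize to zero.

## Race/ethnicity sensitivity analyses

The primary registry excludes racial/ethnic identity composition on the
grounds that structural racism's downstream effects — not identity — drive
vulnerability; the sensitivity registry adds one demographics subdomain
with four composition features (Hispanic/Latino of any race, Black
non-Hispanic, Asian non-Hispanic, other non-White non-Hispanic), making
demographics weights 1/32. Placing all four features in a single new
subdomain is an assumption of this implementation. "High composition" means
a tract's group proportion strictly exceeds the median across retained
tracts — a tract exactly at the median is not flagged — and a tract can be
high-composition for several groups. The summary table of median overall
and domain scores per flagged group is purely descriptive. The composition
table may carry more groups (AI/AN, NH/PI, multiple race) than the four
features entering the sensitivity registry; the two sets are deliberately
decoupled.

## Synthetic data generator

The generator emulates what the index presumes about real tract data:
features that co-vary positively within subdomains through a shared latent
vulnerability factor plus per-domain factors, borough-level mean shifts,
inverse-coded features moving opposite to the latent, a small fraction of
very-low-population tracts, and scattered missing values. Defaults are the
study-scale conditions: 2,167 tracts over five boroughs (weights roughly
the boroughs' tract shares: Brooklyn 0.35, Queens 0.31, Bronx 0.16,
Manhattan 0.13, Staten Island 0.05), latent shifts +0.8 (Bronx), +0.2
(Brooklyn), 0 (Manhattan, Queens), −0.8 (Staten Island), feature loading
1.0, domain loading 0.5, noise sd 0.5, 51 tracts forced below population
20, 30 tracts given exactly one missing value — so the filters retain 2,086
tracts by construction. Loadings were chosen to make latent recovery stable
but not trivial (overall-score vs latent Spearman ≈ 0.97 at these
defaults). Raw scales (percent prevalences clipped to [0, 100], income in
USD, etc.) are cosmetic: z-scoring removes them, though clipping mildly
distorts the factor model in the tails.

What the generator does **not** emulate: spatial autocorrelation between
neighboring tracts, ACS sampling margins of error, the PLACES small-area
estimation model, realistic marginal distributions (real features are
often skewed), or heterogeneous factor loadings across features. Passing
tests on synthetic data therefore demonstrate the *arithmetic and
statistical machinery* — not that any particular city's published score
distributions, cluster count, or borough medians will be reproduced.
Reproducing a specific study's numbers requires that study's archived
input data; synthetic borough medians and cluster counts reported by
`scripts/acceptance.py` are analogues, not replications.

The toy fixture is a 5-tract, 2-domain miniature whose expected scores
were computed with an independent loop-based transcription of the scoring
arithmetic and frozen as exact fractions; the same transcription lives in
the test suite and is also run against random tables.

## Numerical choices and problem sizes

Tolerances: exact rational equality for weights; 1e-12 for algebraic
identities (overall = mean of domains, round-trip I/O); 1e-9 for
oracle-vs-pipeline agreement. Spearman correlations use average ranks for
ties (scipy). Quartile classification uses minimum ranks,
`label = ((rank−1)·4)//n + 1`, so tie groups share a label and a fully tied
input is labelled 1 — labels depend only on ranks. Default problem sizes in
tests and the acceptance script (n = 200 blob simulations, 500-tract NDI
recovery, 1,000-tract parameter recovery, one 2,167-tract study-scale run)
keep the full suite around several seconds while leaving the statistical
checks comfortably away from their thresholds.

## Known limitations

- The NDI variable list and stratification are approximations; treat
  cross-index correlations as sensitive to that configuration.
- Gap-statistic selection on data without planted cluster structure (e.g.
  the smooth synthetic latent) is legitimately unstable across seeds; only
  the planted-structure checks assert specific k values.
- Scores are relative to the scored tract set: adding or removing tracts
  changes every standardization and min-max constant, so scores from
  different runs are not directly comparable.
- No spatial statistics: choropleth mapping is out of scope; outputs are
  keyed by GEOID for joining to external geometries.
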