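# Methods

This note records the models, conventions and design choices behind
`ermimap`, in the order the pipeline runs them.

## Index conventions (ermi)

*Log floor.* MSQPCR non-detects are stored as concentration 0. The log
transform maps any concentration below the floor (default 1 cell/mg) to a
log value of 0, so SLG sums are nonnegative and a home with no detected
species has SLG1 = SLG2 = ERMI = 0. The floor is exposed
(`log_transform(..., log_floor=...)`, CLI `--log-floor`) because assay
detection limits vary in practice.

*Quartiles.* Cut points are the empirical 25/50/75 percentiles with linear
interpolation between order statistics; values equal to a cut point fall in
the lower quartile, and an all-equal sample degenerates to quartile 1 for
every home. Quartiles are computed within the supplied sample; mapping to a
fixed national reference scale is a caller decision.

## Synthetic survey generator (synth)

The generator emulates the anatomy a national dust survey presents to this
analysis. On the log10 scale, for home *h* and species *s*:

    x[h,s] = mu_s + gamma_lon_s · lon_h + gamma_lat_s · lat_h
             + loading_s · F[factor_s, h] + community offset + e[h,s]

with latent factors `F` i.i.d. standard normal per (factor, home),
residuals `e ~ N(0, sigma_resid_s)`, concentrations `10^x`, and
left-censoring to 0 below the detection limit.

Defaults (the study conditions every test and acceptance check runs under):

| parameter | default | rationale |
|---|---|---|
| n_homes | 1083 | survey size |
| n_locales | 82 | number of metropolitan sampling locales |
| locale_spread | 0.3° | within-metro scatter of homes |
| mu | 1.5 log10 cells/mg | no per-species distributions are published; a mid-scale mean |
| sigma_resid | 0.8 log10 units | same; gives realistic detect rates (~95%) at the default floor |
| gamma | 0.002·Z per degree for species significant in the published regressions, else 0 | the publication reports Z statistics, not slopes; this scaling yields weak gradients with the published signs (≈ −0.018 log10/degree for the strongest species) |
| factor, loading | published cluster id, √(own-cluster R²) | the minimal home-level latent structure reproducing the published block-correlation pattern |
| detection_limit | 1 cell/mg | matches the log floor |

Locale centroids are drawn uniformly in the continental bounding box
(24–50°N, 66–125°W); no real city list is used, since the analysis needs
spatial grouping, not geography. Two correlated species with loadings
*a*, *b* and residual sd σ have correlation `ab/√((a²+σ²)(b²+σ²))`, which
the tests verify empirically.

`spatially_unstructured()` is the null generator: identical marginals and
species-correlation structure, but latent factors and residuals independent
of locale membership and coordinates. Optional *community structure*
(`n_communities`, `community_sd`) assigns whole locales to communities
sharing per-species mean offsets, which plants the coherent home subsets
the validity scan should detect.

What the generator does **not** emulate: survey weights and the two-stage
PSU design, nonresponse, the exclusion of seven low-density states,
per-assay detection limits, or non-Gaussian concentration tails. Passing
tests therefore demonstrate correctness of the algorithms under a faithful
correlation/gradient/censoring structure, not distributional realism of
any real survey.

## Geographic regressions (georeg)

Each response (per-species log10 concentration; untransformed SLG1, SLG2,
ERMI) is regressed on longitude and latitude with an intercept by Gaussian
maximum likelihood: OLS coefficients with the n-denominator variance
estimate, Wald `Z = beta/SE`, and two-sided standard-normal p-values. At
n ≈ 1083 this is indistinguishable from t-based OLS inference (the tests
verify the exact n/(n−p) relation against statsmodels). Homes with
non-detects are retained. A response that is an exact linear function of
the coordinates is returned with exact coefficients, infinite Z and a
degenerate-fit warning rather than an error. Significance counting uses
p < α on either coordinate (α = 0.05 by default), which reproduces the
published 13-of-26 / 8-of-10 counts from the packaged table.

## Partition validity (validity)

Standardization uses the population (n-denominator) standard deviation;
constant columns standardize to zero with a warning. The scan grid is
{Euclidean, Manhattan, correlation} × {k-means, k-medoids} × k ∈ 2..10
(k-means is scored only under the Euclidean metric it optimizes).

k-means is Lloyd's algorithm with k-means++ seeding and 10 seeded restarts,
keeping the lowest inertia; empty clusters are re-seeded on the farthest
point. k-medoids is PAM: greedy BUILD, then a SWAP phase that evaluates
every (medoid, candidate) exchange in a vectorized pass and applies the
single best exchange until none lowers the total distance — so the final
cost never exceeds the BUILD cost. Silhouette widths use the precomputed
distance matrix; singleton partitions score 0 by convention. A
configuration is *flagged* when its average silhouette exceeds 0.25, a
conservative reading of "compact, well-separated"; unstructured survey-like
data scores ≈ 0.02–0.05 for every configuration, so the flag threshold's
exact value is immaterial to the null conclusion.

## Variable clustering (varclus)

The clustering works on the correlation matrix of the standardized
columns.

*Splitting.* All variables start in one cluster. While any cluster's
second eigenvalue exceeds `max_eig2` (default 1.0 — "remaining structure no
stronger than one average variable"), the worst cluster is split: each
member joins whichever of the first two principal components it correlates
with more strongly (|corr| with PC k is √λ_k |v_jk|), followed by one local
refinement pass against the two subgroup FPCs. This approximates the
orthoblique-rotation split of the classic procedure.

*Reassignment.* After splitting completes, a best-first full search runs.
A variable's fit to its **own** cluster is judged leave-one-out — its
squared correlation with the component of the *other* members — because the
self-included r² of a small stranded fragment is inflated enough to make
fragments self-stabilizing (a pair always explains each member at
r² ≥ 0.5). A singleton, however, is *perfectly* explained by its own
component, so fit can never justify dissolving it; a singleton is absorbed
into its best-fitting cluster only when the merged cluster *decisively*
satisfies the splitting criterion: merged second eigenvalue
≤ max_eig2 − √(m/n), where √(m/n) is the null sampling scale of
correlation-matrix eigenvalues for m variables on n observations. The move
with the largest gain is applied, components are recomputed, and the
split/reassign alternation repeats until stable (capped; exceeding the cap
raises an iteration-limit error carrying the partial result).

Total variance explained (Σ eig1) is **not** used to gate moves: with the
number of clusters free, more clusters always explain more variance (the
all-singletons partition is the global maximum), so variance gating can
never merge a stranded fragment back into its block. The global behavior
the search targets instead is the criterion fixed point: every cluster
satisfies the splitting criterion, and no two clusters could merge while
keeping it satisfied; the tests compare final memberships against an
exhaustive-enumeration oracle of exactly that characterization on
8-variable instances.

*Determinism and ties.* Eigendecompositions fix the sign so the
largest-magnitude loading is positive; equal fits resolve to the lower
cluster index; reporting order is decreasing member count, then the
lexicographically first member.

*Scores and diagnostics.* The FPC score of a cluster is the standardized
first-eigenvector combination of its member columns (so higher-loading
members carry larger weights); `r2_own` is the squared correlation of a
variable with its own cluster's score (exactly 1 for singletons, and
internally consistent with the emitted score columns to 1e-10), `r2_next`
the best squared correlation with any other cluster's score.

*Known limitation.* A variable exactly uncorrelated with every other sits
*exactly at* the 1.0 criterion (its population eigenvalue contribution is
1), so whether a given finite sample isolates it is a coin flip weighted by
O(√(1/n)) fluctuations. Under the generator defaults the singleton species
is isolated — and the published seven-cluster structure recovered — in
roughly 85–90% of replicates, with membership agreement of at least 35/36
in every replicate either way; the occasional six-cluster outcome absorbs
only the singleton.

## Locale aggregation and classification (localemap)

Locale assignment is seeded k-means on raw (latitude, longitude) with
k = 82 by default; the survey's true PSU list is not public, so the locale
count is a parameter. Aggregation takes unweighted arithmetic means per
locale (coordinates, FPC scores, SLG1/SLG2/ERMI).

Natural-breaks classification is the exact Fisher–Jenks optimization: a
dynamic program over sorted values minimizing total within-class sum of
squared deviations, verified against exhaustive enumeration of boundary
placements. Classes are labeled 1..5 ascending; breaks are "≤ upper bound"
half-open intervals (ties fall in the lower class); with fewer distinct
values than classes the class count degrades with a warning. Exported
layers carry integer grey-scale and symbol-size ranks equal to the class
(1 = lightest/smallest), keeping cartography out of the analysis; GeoJSON
output follows RFC 7946 ([longitude, latitude] order) with a CSV mirror.

## Pipeline and reproducibility

`run_pipeline` executes simulate → index → regress → scan → cluster →
locale/classify, writing one directory of CSV/GeoJSON artifacts plus a
manifest with a sha256 per file. All randomness derives from a single root
seed through named per-stage substreams, so (config, seed) determines every
checksum. A failing stage leaves a `<stage>.partial` marker and re-raises
with the stage name.

## Problem sizes

Tests run the full survey scale (n = 1083 homes, 82 locales) for the
cluster-recovery and null-silhouette checks, 20 seeded replicates for the
recovery rate, 500 replicates at n = 250–300 for the regression type-I
calibration, and exhaustive oracles at n ≤ 14 for silhouette and Jenks.
The acceptance script uses n = 1083 with 5 generator seeds for the
silhouette scan.
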