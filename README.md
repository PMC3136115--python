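# ermimap

Geography of the Environmental Relative Moldiness Index (ERMI) in housing
surveys.

The ERMI summarizes the mold burden of a home from mold-specific
quantitative PCR (MSQPCR) concentrations of 36 indicator species in settled
dust: 26 *Group 1* species associated with water-damaged homes and 10
*Group 2* species that occur independently of water damage. With
concentrations `c_s` in cell equivalents per mg of sieved dust,

```
SLG1 = Σ_{s ∈ Group 1} log10(c_s)      SLG2 = Σ_{s ∈ Group 2} log10(c_s)
ERMI = SLG1 − SLG2
```

(concentrations below the detection floor contribute 0), a unitless index
on a national scale of roughly −10 to 20, read in quartiles.

`ermimap` is a tested, reusable implementation of the full analysis chain
used to characterize how these 36 species distribute across the continental
USA:

1. **panel** — the 36-species registry plus the published per-species
   regression and cluster tables, shipped as plain-CSV fixtures;
2. **synth** — a synthetic survey generator (homes around metropolitan
   sampling locales, log10-normal concentrations, weak geographic
   gradients, a 7-block latent-factor correlation structure, left-censoring
   at a detection limit) standing in for the non-public survey data;
3. **ermi** — log transformation, SLG1/SLG2/ERMI, quartile classification;
4. **georeg** — per-species Gaussian maximum-likelihood regression of
   log10 concentration (and of the untransformed indices) on longitude and
   latitude, with Wald Z statistics and two-sided normal p-values;
5. **validity** — partitioning of homes on standardized 36-species
   profiles (k-means, PAM k-medoids; Euclidean, Manhattan, correlation
   distances; k = 2..10) scored by average silhouette width
   `s(i) = (b_i − a_i)/max(a_i, b_i)`;
6. **varclus** — disjoint oblique principal-component variable clustering
   of the 36 species (iterative splitting while any cluster's second
   eigenvalue exceeds 1.0, with full-search reassignment), first-principal-
   component (FPC) scores, and per-species R² diagnostics (own vs
   next-closest cluster);
7. **localemap** — aggregation of homes into sampling locales (seeded
   k-means on coordinates), exact Fisher–Jenks five-category natural-breaks
   classification, and GeoJSON/CSV point-layer export.

## Worked example

```
$ ermi simulate --n-homes 1083 --n-locales 82 --seed 7 --out homes.csv
wrote 1083 homes to homes.csv

$ ermi compute homes.csv --out ermi.csv
$ head -4 ermi.csv
home_id,slg1,slg2,ermi,quartile
H0001,40.677366628048205,25.747258238502134,14.93010838954607,2
H0002,42.93730170991841,27.673660471585592,15.263641238332816,2
H0003,57.231134218422355,23.986679259288376,33.244454959133975,4
```

Each row is one home: the two sums of logs, their difference (the ERMI) and
the home's quartile within this sample. Homes H0001–H0002 sit in the second
quartile; H0003 is a high-burden fourth-quartile home.

```
$ ermi regress homes.csv --out regression.csv
significant at alpha=0.05: 11 Group 1, 8 Group 2 species
```

Per-species longitude/latitude regressions recover the weak gradients the
generator planted (the generator's defaults plant the published gradient
signs; sampling noise moves the exact significance count around the planted
13/8).

```
$ ermi varclus homes.csv
7 clusters; wrote clusters.csv, fpc_scores.csv
$ head -5 clusters.csv
species,cluster,group,r2_own,r2_next
Aspergillus flavus,1,1,0.4460228997281161,0.003280473622747107
Aspergillus niger,1,1,0.4745970958137291,0.004220747326613689
Aspergillus sydowii,1,1,0.4807289704340009,0.002912078091718377
Aspergillus unguis,1,1,0.5286456279237357,0.001008604364614204
```

The 36 species collapse to seven disjoint clusters matching the generating
factor structure; every species fits its own cluster's component far better
than the next-closest one (`r2_own` ≫ `r2_next`).

```
$ ermi map homes.csv --locales 82 --var ermi --seed 7
wrote layer_ermi.geojson / .csv (82 locales, 5 classes)
```

The 1083 homes collapse to 82 plotting positions; each locale's mean ERMI
is assigned one of five natural-break classes exported as grey-scale and
symbol-size ranks (1 = lightest/smallest) in an RFC 7946 GeoJSON point
layer.

`ermi run --config config.yaml` executes the whole chain (simulate → index
→ regress → scan → cluster → map) and writes a checksummed artifact
manifest; identical config and seed reproduce identical checksums.

## Layout

```
src/ermimap/        library (panel, synth, ermi, georeg, validity,
                    varclus, localemap, pipeline, cli)
src/ermimap/data/   plain-CSV fixtures: species panel + published tables
tests/              pytest suite (unit, property and end-to-end checks)
docs/methods.md     models, conventions, parameter choices, limitations
```
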