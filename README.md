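# gutkit

Analysis toolkit for crowd-sourced gut microbiome cohorts: self-collected
16S amplicon surveys where the features are exact sequence variants
(sOTUs), the metadata are self-reported and messy, and samples were
shipped at room temperature so a handful of taxa ("blooms") grew in
transit.

It is written for microbiome data analysts who need the full battery of
statistics such cohorts call for, in one tested place:

- **Bloom filtering and rarefaction** — exact-sequence bloom removal
  prior to rarefaction, per-sample bloom-fraction accounting, and
  hypergeometric subsampling to a fixed depth (1,250 reads by default).
- **Diversity** — Shannon, observed features, Faith's phylogenetic
  diversity (mean over 10 rarefactions), unweighted and weighted
  UniFrac, Bray–Curtis, PCoA, and a Procrustes *M²* fit between
  ordinations.
- **Balance classifier** — a two-way compositional classifier:
  CLR-transform → single-component PLS → 3-Gaussian mixture on the
  feature scores → density-intersection thresholds → the balance
  statistic *b* = √(rs/(r+s)) · log(g(x₊)/g(x₋)), evaluated by ROC/AUC
  and ANOVA.
- **Effect-size ledger** — metadata plausibility curation, sparse-group
  gating, covariate cross-correlation and clustering, quartile binning,
  and mixed-directional-FDR-controlled pairwise Cohen's *d* over alpha-
  and beta-diversity responses.
- **Saturation curves** — sOTU novelty (rare-feature collector's
  curves), minimum-observed beta diversity, and within-individual
  divergence binned by 30-day month lags against a between-subject
  baseline.
- **Spatial statistics** — haversine great-circle distances, banded
  binary row-standardized weights, per-feature Moran's *I* with an MCMC
  permutation null (100 chains × 1,000 transpositions), and a Mantel
  correlogram over neighborhood radii with Benjamini–Hochberg
  adjustment.
- **Group tests** — PERMANOVA, PERMDISP with reported centroid
  distances, per-individual state-change resampling, greedy 1:1
  matched-control selection, and a permuted mean-difference
  differential-abundance test with discrete FDR control.
- **Synthetic cohorts** — a generator that plants known structure
  (discriminating features, bloom spike-ins, correlated metadata,
  longitudinal drift, spatial fields) so every stage above can be
  validated by parameter recovery.

## The balance classifier in brief

Given counts x and a binary covariate, the table is centered-log-ratio
transformed (pseudocount 1), a single NIPALS PLS component scores each
feature by its association with the covariate, and a three-component
Gaussian mixture N(μ₋,σ₋²), N(μ₀,σ₀²), N(μ₊,σ₊²) is fitted to the
scores. The crossings of adjacent component densities give thresholds
θ_lo and θ_hi; features with score < θ_lo form x₋, score > θ_hi form
x₊, the rest stay null. Each sample's balance is

    b = sqrt(r·s / (r + s)) · log( g(x₊) / g(x₋) ),   r = |x₊|, s = |x₋|

with g(·) the geometric mean over pseudocounted counts. AUC (rank
statistic) and one-way ANOVA quantify how well b separates the groups.

## Worked example

```python
from gutkit import synth, bloom, balances

cfg = synth.SimConfig(seed=42)          # 400 samples x 150 features,
                                        # 20 planted 2-fold features
tree = synth.simulate_tree(cfg.n_features, cfg.seed)
table, truth = synth.simulate_counts(cfg, tree)
md = synth.simulate_metadata(cfg, truth)

frac = bloom.bloom_fraction(table, truth.bloom_features)
print(f"median bloom fraction: {frac.median():.3f}")
cleaned = bloom.remove_blooms(table, truth.bloom_features)

res = balances.BalanceClassifier(cleaned, md.column("group")).fit(seed=0)
print(res.summary())
```

prints

```
median bloom fraction: 0.070
Balance classifier results
==========================
samples: 400   features after filter: 145
mixture means: -0.1723 -0.0046 +0.2311
mixture sds:    0.0874  0.0371  0.0412
mixture weights: 0.060 0.878 0.062
thresholds: theta_lo=-0.1071 theta_hi=+0.1248
|x_pos|=9   |x_neg|=7
AUC: 0.9566
ANOVA: F=585.869 p=3.13e-80
```

The median bloom fraction (7.0%) is the transit-growth read share the
generator planted; after exact-sequence bloom removal the classifier
assigns 9 features to the positive and 7 to the negative side of the
covariate and separates the two groups at AUC 0.96 — 16 of the 20
planted discriminating features land in the correct set
(`truth.disc_features` scores the recovery).

A command-line interface mirrors the library:

```
gutkit synth --seed 42 --outdir cohort/
gutkit bloom --table cohort/table.tsv --blooms cohort/blooms.txt \
             --depth 1250 --seed 0 --output bloomed/
gutkit balance --table bloomed/rarefied.tsv --metadata cohort/metadata.tsv \
               --covariate group --seed 0 --output balance/
```

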