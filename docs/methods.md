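# Methods

This note documents the statistical procedures gutkit implements, the
modelling choices made where the procedures are underdetermined, what
the synthetic-data generator does and does not emulate, and the
numerical conventions that affect results.

## Data model

The canonical objects are a samples × features integer count table
(features keyed by opaque IDs or exact 16S fragment sequences, which
are uppercased but never otherwise normalised because bloom matching is
exact string equality), a rooted phylogeny with nonnegative branch
lengths covering the table's features, a typed metadata table
(categorical / ordinal / continuous; ordinal columns carry an explicit
level order; the tokens "", "Unspecified", "not provided" and "NA"
unify to missing), a sample-indexed symmetric distance matrix, and
per-sample latitude/longitude in decimal degrees. Readers reject
invariant violations (duplicate IDs, negative counts, missing branch
lengths, out-of-range coordinates) rather than coercing.

## Bloom removal and rarefaction

Blooms are taxa that replicate during room-temperature transit of
stool swabs. The filter drops the listed exact feature IDs from every
sample — including imported meta-analysis samples — *before*
rarefaction, and the per-sample bloom read fraction is retained as a
covariate. Rarefaction subsamples without replacement
(multivariate-hypergeometric), so each retained row sums exactly to the
depth and no count exceeds its original value; samples below the depth
are dropped and reported. The default depth is 1,250 reads. Without-
replacement subsampling was chosen over multinomial resampling because
it makes the depth-sum and monotonicity invariants exact.

## Diversity

Shannon entropy uses base 2 (bits). Faith's PD is the total branch
length of the union of root-to-leaf paths of the taxa present; the
root's own stem is included, so PD of the full leaf set equals the
tree's total branch length. Alpha diversity is reported as the mean
over 10 independent rarefactions by default. Unweighted UniFrac is
(branch length unique to either sample) / (branch length in the union
of both samples' path sets) — the standard union denominator. Weighted
UniFrac is Σ_branches ℓ·|p_A − p_B| with p the fraction of a sample's
reads descending through the branch; the normalised variant divides by
Σ ℓ·(p_A + p_B), the maximum attainable value. Unnormalised weighted
UniFrac is the default for effect-size work, normalised for spatial
analyses. UniFrac, Faith's PD, PCoA and subsampling are computed by
scikit-bio; the test suite verifies both UniFrac variants and Faith's
PD against an independent per-branch brute-force enumeration to 1e-12
on hundreds of random trees, and checks the triangle inequality for
unweighted UniFrac. PCoA retains negative eigenvalues without
correction (simplest faithful behaviour; corrections can be layered
on). Procrustes M² is the scipy disparity after optimal translation,
scaling and rotation/reflection, with zero-padding when the two
configurations differ in dimensionality.

## Balance classifier

Pipeline: (1) feature filter — ≥ 50 total reads, present in ≥ 20
samples (5 for small-group designs), count variance > 10; a warning is
raised if features still outnumber samples. (2) CLR transform with
pseudocount 1 (rows of the result sum to zero). (3) One PLS component
by NIPALS on column-centered X and centered y; for a single component
the weight vector is X'y/‖X'y‖. X is centered but not scaled because
CLR already puts features on a common log scale. The sign convention
makes the class coded 1 project positively. (4) A three-component
univariate Gaussian mixture is fitted to the feature scores by EM:
k-means++ initialisation, 10 seeded restarts, relative log-likelihood
tolerance 1e-7, a standard-deviation floor of 1e-4 of the score spread,
components relabeled by sorted mean. Mixture weights are free.
Non-convergence of every restart is an error. (5) Thresholds are the
crossings of adjacent weighted component densities, solved in closed
form (quadratic in x) and restricted to the interval between the two
component means; if no real root lies between the means the midpoint of
the means is used and flagged. (6) Features strictly below θ_lo form
x₋, strictly above θ_hi form x₊; scores exactly equal to a threshold
stay unassigned. (7) The balance b = √(rs/(r+s))·log(g(x₊)/g(x₋)) uses
geometric means over pseudocounted raw counts, which makes b invariant
to per-sample read depth; the coefficient is the normalising constant
of an isometric log-ratio contrast. (8) AUC via the Mann–Whitney rank
statistic (pair-enumeration equivalent) and one-way ANOVA F/p.

In-sample AUC is optimistically biased because the feature sets are
selected on the same labels; `BalanceResults.evaluate_on` scores
held-out samples with the fitted sets, and the calibration tests use a
half/half split — planted signal still yields AUC ≥ 0.9 while permuted
labels average AUC ≈ 0.5.

## Effect-size ledger

Curation: heights outside 48–210 cm and weights outside 2.5–200 kg
become missing; BMI is recomputed only from in-bound pairs; an age
under 4 years contradicted by height > 105 cm, weight > 20 kg, or any
alcohol consumption — or a birthdate after collection — invalidates the
age. Nothing is imputed. Group gating merges sparse ordinal extremes
(fewer than 25 observations) into their adjacent level, then drops
groups with fewer than 50 observations or under 3% of respondents
(boundaries inclusive); covariates with fewer than two surviving groups
are dropped with a reason. Continuous covariates are binned at
empirical quartiles, left-closed, ties to the lower bin.

Covariate association: Pearson r for continuous/ordinal pairs (ordinal
via level ranks), bias-corrected (Bergsma) Cramér's V when a
categorical variable is involved with a categorical/ordinal one, and a
Welch t converted to r = √(t²/(t²+df)) for continuous–categorical
pairs; complete cases per pair, no imputation. Covariates are clustered
by average linkage on 1 − |R|; tips whose subtree is entered within
cumulative branch length 0.29 of the tip level share a cluster (for an
ultrametric average-linkage dendrogram this equals a height cut at
0.29, i.e. a cophenetic distance of about 0.5 between covariates
0.58/2). The cluster representative is the member with the fewest
missing values (ties alphabetical) — the representative rule is
otherwise unconstrained, so the least-missing member maximises usable
sample size.

mdFDR: stage 1 runs one global test per covariate (one-way ANOVA by
default or Kruskal–Wallis for an alpha-diversity response, PERMANOVA
for a distance-matrix response) and selects covariates by
Benjamini–Hochberg at level α, giving R of m. Stage 2 runs all pairwise
comparisons within each selected covariate (Welch t for alpha, pairwise
PERMANOVA for beta) with BH at level (R/m)·α inside the covariate;
directions follow the sign of the mean difference. The two-stage
BH-based construction is one standard concretisation of the
mixed-directional FDR family; simulation in the test suite confirms the
directional FDR stays at the nominal 0.05 under a 50-null/5-non-null
design with power ≥ 0.8 at a planted shift of 1.5 pooled SDs. Cohen's d
(|mean difference| / pooled SD) is computed on the response values for
alpha responses; for beta responses — where d on a distance matrix is
not canonically defined — it is computed between the within-group and
between-group distance distributions of the pair, a choice made here
and documented as such.

## Saturation curves

Novelty: for each subset size n (independent draws per size, 10
replicates by default) the count of features whose total reads in the
subset lie in [1, t] for each threshold t — t = 1 counts singletons,
t = 2 singletons plus doubletons, cumulatively. Subsampling is
independent per n rather than nested, matching the resampling
description the curves implement. Beta-added: the minimum off-diagonal
distance among n sampled samples. Within-individual: all within-subject
pairs are binned by ⌊lag days / 30⌋ — fixed 30-day months, chosen over
calendar months for determinism — and each (subject, bin) keeps exactly
one representative pair (earliest first-sample date, ties by sample
ID) so densely sampled subjects do not dominate; the between-subject
baseline is the distribution of all cross-subject distances.

## Spatial statistics

Great-circle distances use the haversine formula on a spherical Earth
of radius 6371.0 km. Neighborhood weights are binary (w_ij = 1 iff
lo ≤ d_ij < hi, zero diagonal), row-standardized by default; samples
with no neighbor in a band are flagged isolated and excluded. The three
default bands 0–50/50–100/100–250 km partition every non-self pair
under 250 km. Moran's I = (n/S₀)·Σw_ij z_i z_j / Σz_i² on centered
values; its permutation null is generated by 100 chains (default), each
started at an independent random permutation and advanced by 1,000
random transpositions, pooling all draws; p = (1 + #{null ≥ obs}) /
(1 + draws), one-sided greater by default (two-sided available), with
Bonferroni control across features at overall 0.05. The
transposition-chain sampler is this package's choice of MCMC; its null
mean matches −1/(n−1) and its p-values are uniform under iid data in
the calibration tests. The Mantel correlogram computes, per radius in
{100, 500, 1000, 2500, 4500} km, the Pearson correlation between
community and geographic distances over pairs *within* the radius
(pairs beyond it are masked, not truncated), a row/column
co-permutation null on one matrix (1,000 permutations), and BH
adjustment across radii; radii with fewer than 3 usable pairs are
reported as missing.

## Group tests

PERMANOVA (scikit-bio, seeded) uses the pseudo-F from the squared-
distance sum-of-squares decomposition with a free label-permutation
null and +1 correction; the suite checks it against an exhaustive
enumeration of all label permutations at n = 8. Repeated measures are
handled not by restricted permutation but by the state-change
resampling wrapper: each of 100 trials draws one sample per (subject,
condition), runs PERMANOVA on the reduced matrix, and the summary is
the fraction of trials with p < 0.05; each trial's permutation seed is
a deterministic function of the drawn subset, so degenerate designs
(one sample per cell) give identical trials with zero p variance.

PERMDISP embeds samples by PCoA, measures each sample's distance to its
group's spatial median (Weiszfeld; mean-centroid optional), and
compares the observed one-way ANOVA F on those distances with a
label-permutation null (distances computed once, the standard
permutation scheme). Per-group mean and maximum centroid distances are
reported; singleton groups are excluded from the F and listed.

Matched controls: greedy 1:1 nearest-match without replacement, cases
in input order, exact-match categorical criteria and toleranced numeric
criteria (age ± 5 years by convention), unmatched cases reported —
deterministic given the input order.

Permuted mean difference: per feature, the difference of group mean
relative abundances, with a two-sided label-permutation p (10,000
permutations by default, computed in vectorised batches). The rejection
set is a discrete BH step-up on the permutation p-values in which
features whose attainable p-value support cannot reach the threshold
(constant features, whose only attainable p is 1) are excluded from the
effective test count — the support-aware step-up was chosen over
thresholding the raw mean-difference statistic because the latter is
scale-sensitive across features of very different abundance. α = 0.1
by default; constant features get p = 1 by convention.

## Synthetic cohorts

`SimConfig` defaults are the calibration study conditions used by the
test suite: 400 samples × 150 features, 20 discriminating features with
a 2-fold log-abundance shift (directions alternating so both balance
sides are populated), 5 bloom features whose per-sample read fraction
is Beta(mean 0.079, concentration 20) — the ~8% scale of transit bloom
reads in shipped swabs — sequencing depth negative-binomial with mean
5,000 (shape 10), and a Dirichlet-multinomial count model with
concentration 50 for realistic overdispersion (and to make rarefaction
nontrivial). Bloom spike-ins are post-hoc multiplicative: the bloom
block of the composition is rescaled to the per-sample target fraction,
so the realized fraction matches up to multinomial noise without
modelling growth kinetics. Metadata includes the true group, a
continuous nuisance with configurable correlation (default 0.4) to the
group indicator, an ordinal and an independent categorical covariate,
and 5% injected missingness. Longitudinal cohorts give each subject a
baseline log-composition and a Gaussian random walk with standard
deviation drift·√(lag/30 d) between collections; dates are integer
days. Geography is uniform in a bounding box; in autocorrelated mode a
Gaussian-process field (squared-exponential kernel) sampled at the
coordinates can drive a designated feature's abundance. Everything is
reproducible from (config, seed).

The generator emulates overdispersed compositional counts, planted
group structure, transit blooms, correlated mixed-type metadata,
within-subject drift and spatial fields. It does **not** emulate real
taxonomic structure, sequencing error or chimeras, subject-level
covariate confounding beyond the single nuisance, food-frequency data,
or the long-tailed feature richness of real gut communities (features
number 150, not tens of thousands). Passing recovery tests therefore
demonstrates correctness and calibration of the statistics, not
real-data effect sizes: the headline numbers from the motivating cohort
(e.g. its specific AUCs, Faith's PD totals, or bloom medians) depend on
that cohort and are not reproduced here.

## Problem sizes and numerics

The test-suite simulations use the calibration cohort (n = 400) once
per session plus smaller replicated designs (n = 25–100, 50–200
replicates; Moran chains of 10 × 50 draws for replicated calibration,
20 × 200 for the null-mean check) — sizes chosen so the whole suite
completes in a couple of minutes while keeping Monte-Carlo error well
inside the asserted margins. Oracle comparisons are exact to 1e-12
(UniFrac) or 1e-10 (PD, CLR); permutation p-values carry the +1/+1
correction so they are never zero. Ties: quartile edges assign to the
lower bin; scores equal to a mixture threshold stay unassigned;
representative-pair ties break by sample ID.
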