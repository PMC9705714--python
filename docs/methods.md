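# Methods

This note records the models, the defaults and the numerical choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model and preprocessing

Counts are non-negative integers, taxa × samples; phylogenies are rooted
`skbio.TreeNode` objects with non-negative branch lengths covering every
table taxon; distance matrices are `skbio.DistanceMatrix` (symmetry and the
zero diagonal are enforced on construction).

- **Rarefaction** is without replacement (multivariate hypergeometric draw
  per sample), seed-controlled; samples below the depth are dropped and
  logged. Default depth 26,000 reads. Rarefaction happens per replicate
  sample, before any replicate-level averaging.
- **Abundance filter** keeps taxa whose *pooled* relative abundance (taxon
  total / grand total) strictly exceeds the threshold (default 0.01%).
  Pooled rather than per-sample so the filter yields a single global taxon
  list for the network stage.
- **Geographic distance** defaults to Euclidean distance on decimal degrees
  (the convention behind "Geo" predictors in bay-scale surveys); a
  great-circle (haversine, km) option exists behind a flag. Missing
  environmental values fail fast; column-mean imputation must be enabled
  explicitly and is logged.

## Diversity

Shannon entropy uses log2 (an option switches the base); Pielou evenness is
H/log2(richness) and is undefined (NaN) for single-taxon samples. Faith's PD
includes the path to the root, so values on unbalanced trees differ from
the unrooted variant. Weighted UniFrac is non-normalized by default, with
the normalized variant exposed; unweighted UniFrac and Faith's PD are
presence-based. These metrics are delegated to scikit-bio and are checked in
the test suite against brute-force per-branch/path-union oracles to 1e-12.

## Permutation engines

All permutation tests use `p = (#{permuted ≥ observed} + 1)/(n_perm + 1)`
with an explicit seed, so p ≥ 1/(n_perm+1) and every run is reproducible.
Defaults are 999 permutations. ANOSIM uses rank-transformed distances;
PERMANOVA partitions squared distances into among/within sums (on 1-D
Euclidean data its pseudo-F equals the classical one-way ANOVA F exactly,
which the suite asserts to 1e-10). Mantel-family tests are one-tailed for
positive association, matching the convention of reporting significant
positive r; Spearman variants rank the off-diagonal entries once and carry
the ranks through the permutations (the rank multiset is permutation-
invariant). The partial Mantel permutes the second matrix; when the second
matrix coincides with the control (a 0/0 partial correlation) the statistic
is reported as 0 rather than raised, since nothing is left to correlate —
a genuinely degenerate control (|r| = 1 with information remaining) still
raises.

The temporal control matrix is binary: 0 for same sampling month, 1
otherwise. This is the weakest assumption available when months are
unordered categories; an ordinal alternative would differ only when months
are treated as a gradient.

## PCNM, forward selection and variance partitioning

PCNM vectors are the positive-eigenvalue PCoA axes of the geographic
distance matrix truncated at t = the largest minimum-spanning-tree edge
(distances above t replaced by 4t). On a regular transect the leading
eigenfunctions are the classical sinusoids; the suite pins the leading
vector to `vegan::pcnm` output computed independently in R.

Distance-based RDA embeds the response distance matrix by PCoA, discarding
negative-eigenvalue axes (their count is reported); adjusted R² is
Ezekiel's, with the predictor count taken as the rank of the centered
design, so duplicated or collinear columns cannot inflate the penalty.

Forward selection is double-stopping with a global pre-test:

1. the model with every candidate is tested by free permutation of the
   response rows — no selection happens unless it is significant (without
   this gate, picking the best of k noise candidates passes ≈ k·α of the
   time);
2. each entering candidate needs a permutation p ≤ α on its partial F;
3. the cumulative adjusted R² may not exceed the full-candidate model's
   adjusted R² (the Blanchet ceiling). Differences within 10% of the global
   residual fraction are treated as ties: the Ezekiel adjustment of pure
   noise predictors is a zero-mean random quantity of exactly that scale,
   and a strict ceiling would reject a single near-perfect predictor whose
   subset adjusted R² sits marginally above the penalized global value.

Variance partitioning solves the seven set-combination adjusted R² values
for the seven fractions (three pure, three pairwise joints, one triple
joint) algebraically; the seven fractions sum to the full-model adjusted R²
exactly (asserted to 1e-10) and the residual is one minus that. Negative
fractions are kept internally and displayed as 0 with the raw value
retained, following the standard reporting rule. Per-set p-values test each
set conditionally on the other two (partial F, free permutation of
samples). When no set survives forward selection the result is flagged "no
testable model" rather than fabricating zeros.

Group letters (compact letter display) use all pairwise Welch t-tests by
default, assigned by the underlining method on mean-sorted groups; Duncan's
multiple range test (studentized range with protection level
1−(1−α)^(p−1), harmonic mean group size) is available for fidelity to
classical agronomic-style tables.

## Assembly null models

Patristic distances are computed once per tree; each tip-shuffle null
replicate relabels the distance matrix rather than re-traversing the tree
(identical by construction, and what makes 999 replicates cheap). The
shuffle pool is every taxon in the filtered, rarefied table — the regional
pool — and the same shuffle is reused for all sample pairs within a
replicate (matrix-wise nulls). βNTI is undefined when the null SD is 0
(e.g. a star phylogeny, where every patristic distance is equal); such
pairs are flagged and excluded from classification with a logged count.
βNTI is invariant to uniform branch-length rescaling (the scale cancels in
the standardization), which the suite asserts.

The Raup–Crick null preserves each sample's observed richness and read
total. Membership is drawn without replacement with probability ∝ regional
occupancy; remaining reads are assigned multinomially ∝ regional relative
abundance restricted to the drawn members. One null community is drawn per
sample per replicate and Bray–Curtis is evaluated for all pairs within the
replicate — sharing draws across pairs mirrors the matrix-wise βNTI
convention and cuts the cost from O(pairs) to O(samples) community draws
per replicate. Ties in the empirical CDF take weight ½ so the metric is
symmetric under exchanging the observed and a null draw; the result is
clamped to [−1, 1].

Classification: βNTI > +2 → heterogeneous selection; < −2 → homogeneous
selection; otherwise RCbray > +0.95 → dispersal limitation; < −0.95 →
homogenizing dispersal; else undominated. Both weighted and unweighted
βMNTD are implemented; classification defaults to the unweighted variant.
Summaries report the five-class percentage per month stratum (within-month
and between-month-pair), which sum to 100 per stratum.

## Synthetic data generator

The generator emulates a three-month coastal-bay survey and is the
package's ground-truth instrument:

- **Phylogeny**: pure-birth tree rescaled to unit depth (ultrametric).
- **Traits**: Brownian-motion environmental optima from root value 0 with
  variance `bm_variance` per unit branch length (default 1, so tip optima
  have SD ≈ 1) — the phylogenetic signal that makes selection detectable by
  a phylogenetic null.
- **Selection**: per month m with environment E_m, taxon fitness
  w = exp(−(optimum − E_m)²/(2σ_sel²)); σ_sel → ∞ disables selection. The
  "selection" scenario separates month environments by 4σ_sel
  (σ_sel = 0.5).
- **Dispersal limitation**: station-local pools are Dirichlet perturbations
  of the month pool with concentration `dispersal_scale·n_taxa` divided by
  station isolation (distance to nearest neighbour) — the simplest
  mechanism RCbray can flag without phylogenetic signal.
- **Drift**: one multinomial resampling round of local pool frequencies
  plus multinomial read sampling at a negative-binomial library size
  (mean 26,000 reads, dispersion 0.003 ≈ 5% CV).
- Environmental covariates are drawn per station per month around
  month-level means/SDs (defaults mirror a May/Aug/Oct surface-seawater
  survey: e.g. temperature 17.48 ± 2.36, 28.09 ± 0.53, 19.55 ± 1.26 °C);
  replicates share their station's values. Station coordinates are uniform
  in a bay-sized box (≈ 117.7–118.8°E, 38.5–39.3°N).
- Truth labels per month stratum follow the generating mechanism: selection
  if σ_sel is finite and |ΔE| > σ_sel between months, dispersal limitation
  if local pools are perturbed, else undominated.
- `plant_season_otus` multiplies chosen OTUs by a fold factor in one
  month's samples and redraws each column multinomially at its original
  depth, recording the planted OTU → month map.

What the generator does **not** emulate: sequencing error and chimeras,
taxon-taxon interactions, temporal autocorrelation within a month,
spatially structured environmental gradients (covariates are independent
across stations given the month), and real phylogenies' non-ultrametric
branch-length heterogeneity. Passing recovery tests therefore show the
inference is correct *under its own assumptions*, not that those
assumptions hold in any particular bay.

## ssOTU and network stage

TMM factors follow the trimmed-mean-of-M recipe: reference = sample whose
75th-percentile count fraction is closest to the mean; M-values trimmed 30%
per tail, A-values 5% per tail; precision-weighted mean of M; factors
normalized to geometric mean 1. CPM divides by the TMM-scaled library.

The negative-binomial LRT fits per-OTU group means by Newton iteration on
the log scale (log link, offset = log effective library size) and compares
against an intercept-only fit: LRT = 2Δll, chi-square with (groups − 1) df,
BH adjustment across OTUs. Dispersion is a single common value estimated by
Cox–Reid adjusted profile likelihood across all OTUs (default; a documented
simplification of tagwise empirical-Bayes shrinkage — it changes p-values
for OTUs whose true dispersion deviates from the common value); per-OTU MLE
and fixed values are options.

Indicator analysis is the point-biserial correlation of each OTU's CPM with
each group's membership indicator; the permutation p compares the observed
best-group correlation against the max-over-groups statistic under label
shuffles (so the p-value is already selection-corrected). Ties for the best
group disqualify an OTU. An ssOTU must pass both tests at their thresholds
(defaults 0.05 on the indicator p and on the BH-adjusted LRT p) *and* both
tests must name the same season.

Network edges require Spearman ρ strictly > 0.7 (positive associations
only) and two-tailed p strictly < 0.001 (t approximation, mid-ranks for
ties; adequate at the survey's 48–188 samples, with a permutation option
behind a flag). Modules come from greedy (CNM) modularity maximization on
the unweighted edge set with nodes and edges inserted in sorted order so
tie-breaking is deterministic; module ids are assigned by decreasing size.
Module abundance (cumulative member CPM) is regressed on each environmental
variable by OLS, reporting slope, R² and the two-tailed slope p.

## Pipeline and reproducibility

`run_full_analysis` derives one child seed per stage from the master seed
via `SeedSequence.spawn`, records them with the full configuration and a
config hash in `manifest.json`, and writes each stage's table as TSV. Rerun
with the same configuration, byte-identical outputs result (asserted in the
suite). Stage failures abort with the stage name; outputs already written
are preserved. The CLI (`assemblage simulate|run|bnti|rcbray`) is a thin
wrapper over these functions.

## Problem sizes in tests and the acceptance script

Null-model calibration runs at 200 taxa × 24 samples × 199 null replicates
× 5 datasets; scenario recovery at 200 taxa, 2 months × 6 stations × 2
replicates, ~2,000 reads per sample; ssOTU recovery at 200 taxa × 72
samples with 30 planted OTUs per month at 8-fold enrichment; NB-LRT
calibration at 200 OTUs × 3 groups × 20 samples with common dispersion 0.2.
These sizes keep the whole suite in the tens of seconds while leaving
Monte-Carlo error well inside the asserted bands; the tolerant calibration
bands ([0.01, 0.10] for P(|βNTI| > 2), [0.02, 0.09] for P(|RCbray| > 0.95))
account for the 199-replicate nulls used in testing versus the 999-replicate
default of a production run.

## Known limitations

- The RCbray null is one of several published variants (richness *and*
  abundance preserved; occupancy-weighted membership); variants that fix
  richness only will shift RC values on abundance-skewed data.
- Common-dispersion NB testing is anti-conservative for OTUs with
  above-common dispersion.
- PCNM + forward selection + VPA inherits the known instability of
  adjusted-R² fractions at small n (per-month strata with 12 stations);
  fractions there should be read qualitatively.
- The greedy modularity algorithm is deterministic but resolution-limited;
  very small modules may be absorbed.
- Weighted UniFrac's non-normalized default is not bounded by 1; compare
  runs only under a fixed choice of variant.
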