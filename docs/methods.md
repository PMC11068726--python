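# Methods

`consica` implements a complete analysis chain for dissecting bulk tumor
transcriptomes into consensus independent transcriptional components (TCs)
and relating those components to disease-free survival (DFS). This note
documents the models, the estimators, the numerical choices, and what the
synthetic-data experiments do and do not establish.

## The mixing model

Expression is modeled as a linear mixture

    X = Aᵀ S + E,          X: genes × samples (log scale)
                           S: components × genes ("TC matrix", i × p)
                           A: components × samples ("mixing matrix", i × n)
                           E: i.i.d. Gaussian noise

Each row of S is a gene-weight vector describing how strongly, and in which
direction, a latent transcriptional program moves each gene; the
corresponding row of A holds that program's activity in each sample. ICA
estimates S by maximizing the non-Gaussianity of the gene-weight rows;
identifiability therefore requires super-Gaussian (sparse, heavy-tailed)
sources, which is what transcriptional programs that touch a minority of
genes look like.

## Consensus ICA (`consica.cica`)

1. **Component count** `i`: genes are mean-centered across samples, and `i`
   is the smallest number of principal components of the between-sample
   covariance matrix whose cumulative explained variance reaches the
   `variance_threshold` (default 0.85).
2. **Repeated ICA**: `n_runs` (default 25) FastICA runs (fixed-point
   iteration, log-cosh negentropy contrast, max 1000 iterations, tolerance
   1e-6), each from a different random initial weight vector; the matrix is
   presented genes-as-observations so sources live in gene space. A run
   that does not converge raises an error naming its seed — on purely
   Gaussian data ICA is unidentifiable and this surfaces instead of being
   silently accepted.
3. **Cross-run clustering**: components from different runs with
   |Pearson r| > `r_threshold` (default 0.9) between gene-weight vectors
   are clustered by greedy agglomeration over the threshold graph in
   descending |r| order. A merge is refused when the cluster would exceed
   `n_runs` members or would contain two components from the same run, so a
   cluster can collect at most one representative per run.
4. **Consensus and credibility**: each cluster's sign-aligned members are
   averaged and re-standardized (mean 0, SD 1 across genes). The
   credibility index is cluster size / `n_runs`; TCs with credibility ≥ 0.5
   are retained. Components are ordered by descending credibility (ties:
   first occurrence).
5. **Sign convention**: ICA signs are arbitrary, so every consensus TC is
   oriented to positive gene-weight skewness (tie-break: the largest-|w|
   gene is made positive). This makes `decompose` bit-reproducible given
   the master seed, from which all run seeds derive.
6. **Mixing estimation**: consensus averaging destroys the exact unmixing
   inverse of any single run, so activities are estimated per sample by
   ordinary least squares of the gene-centered expression on the consensus
   weight matrix. A rank-deficient weight matrix is an error that names the
   collinear components. `reconstruct` reports per-sample and overall R²
   against the gene-centered original.

## Gene-set enrichment (`consica.enrichment`)

Sets are intersected with the profiled gene universe first, then filtered
to 10–500 members. Enrichment of a set in a TC is the two-sample Welch t
statistic (unequal variances, Welch–Satterthwaite degrees of freedom)
comparing in-set gene weights against all out-of-set weights. To compare
sets of different sizes, t is transformed to a signed standard-normal
Z-score through the two-sided p-value: z = sign(t) · Φ⁻¹(1 − p/2). The
transform is evaluated in log space; where the Student t survival function
underflows double precision, the incomplete-beta hypergeometric series is
summed directly in log space (validated to ~1e-4 relative accuracy against
an arbitrary-precision reference), so |t| in the hundreds still maps to a
finite, accurate z. Significance is Bonferroni over the full TC × set
table; the flag is exactly `p ≤ alpha / n_tests`. "Important genes" of a TC
are those with |standardized weight| ≥ 3 (boundary included). Continuous
per-sample covariates are related to TC activities by Spearman rank
correlation with pairwise deletion of missing values.

**Calibration caveat.** For a TC whose weights are extremely heavy-tailed
(a handful of genes carrying most of the variance), the Welch z over small
random sets (10–100 genes) is *not* standard normal — the in-set mean of so
few spike-and-slab draws escapes the CLT, and a KS test against N(0,1)
rejects far above its nominal rate. This is a property of the statistic,
not an implementation defect; the package's calibration check therefore
uses a normal-weight component (where the statistic is exact), and the
detection check uses sparse sources where planted directional sets must
clear |Z| > 6. Interpreting borderline z-scores on very sparse TCs with
very small sets warrants caution on real data too.

## Survival association (`consica.survival`)

`fit_cox` is a Cox proportional-hazards fit via lifelines (Efron ties).
Activities are z-scored per TC so hazard ratios are per SD of activity.
Categorical clinical covariates (sex, MSI, BRAF, KRAS, tumor location,
stage, adjuvant therapy) are dummy-coded with `"unknown"` kept as its own
level — real cohorts are missing up to half of the molecular annotations,
and dropping those rows would gut the sample.

`permutation_fdr_select` implements the multivariate permutation framework:
(time, event) pairs are permuted jointly against the samples (activities
and covariates stay attached to their sample), the full p-vector is
recomputed per permutation (default 10,000; tests use 1,000), and the
selection threshold is the largest observed p-cutoff t such that, with
probability ≥ `confidence` (default 0.8) over the permutation distribution,
the number of null features at or below t is ≤ `fdr` (default 0.05) × the
observed rejection count. The observed vector is counted as one permutation
(add-one convention), which makes P(FDP > fdr) ≤ 1 − confidence hold
exactly under exchangeability rather than approximately; without it the
null probability of any selection is 201/1001 ≈ 20.1%, a hair over the
contract. Per-TC empirical permutation p-values (floor 1/(n_perm+1)) are
reported alongside.

Inside the permutation loop the package uses its own vectorized Cox
partial-likelihood **score test** at β = 0 (Breslow risk sets) rather than
per-permutation Newton fits: the statistic is asymptotically equivalent to
the Wald test, reduces exactly to the two-sample log-rank statistic for
binary covariates (verified against lifelines in the tests, as is the
general case against a naive risk-set oracle), and evaluates thousands of
permutation p-vectors per second where iterative fitting would take hours.
Using the same statistic for observed and permuted vectors preserves the
exchangeability on which the threshold rule relies. When covariates are
present, the nuisance Cox model is refitted per permutation (lightly
ridge-penalized against quasi-separation on rare dummy levels) and the
efficient score — the activity score orthogonalized against the nuisance
information — is used. The synthetic survival times are continuous, so
Breslow and Efron tie handling coincide on generated data.

## Random survival forest (`consica.rsf` module, file `forest.py`)

Each of `n_trees` (default 1000) trees draws 5 TCs (without replacement,
per tree) as candidate classifiers. Nodes are split by the two-sample
log-rank statistic maximized over all midpoints between consecutive
distinct activity values, subject to child-node minima (15 samples, 5
events). There is no bootstrap resampling: every tree sees all patients,
so the element-wise-summed proximity matrix has diagonal exactly
`n_trees`, and off-diagonal entries count the trees in which two patients
share a terminal node.

**Split acceptance.** The best candidate split must clear a
Bonferroni-corrected chi-square threshold: `split_alpha` (default 0.05)
divided by the number of cutpoints examined at the node across all 5
candidates. This multiple-testing guard is what makes trees grown on
survival-irrelevant candidates collapse to (near-)single-node trees, which
in turn keeps the importance score discriminative: a TC's importance is
the fraction of trees, among those where it was a candidate, in which it
is used in at least one split — bounded in [0, 1] by construction. Without
a corrected threshold, greedy splitting uses every candidate somewhere and
all importances saturate at 1.

Patient subgroups come from Ward-D2 hierarchical clustering of the
dissimilarity 1 − proximity/`n_trees`; the retained subgroup count k* is
the largest k in 2..`k_max` whose k-sample log-rank test is significant at
`alpha`, with k* = 1 when none is. Forest robustness across TC input sets
is the Pearson correlation of the upper triangles of the two final
proximity matrices.

## Projection (`consica.projection`)

A TCSet is projected onto new data by least squares on the intersection of
gene universes (≥ 50% of TC genes required by default), with weights
re-standardized on the intersection. Because every weight vector is
zero-mean across genes, the projection is invariant to per-sample additive
offsets, and a zero-variance profile maps to exactly zero activity; the
projection is linear in the expression matrix.

Primary/secondary TC matching is greedy one-to-one in descending |r| of
gene weights; |r| > 0.5 flags a robust pair.

Spatial/single-cell significance uses a permutation null that shuffles the
gene labels of the TC's weight vector and recomputes the projection
(equivalently, breaks the expression–weight pairing), keeping all other
TCs fixed. Spatial maps report the two-sided empirical p with add-one
correction (floor 1/(n_perm+1), default 5000 permutations) as −log10 p per
spot. The single-cell path (default 3000 permutations, 10% cell subsample)
fits a Johnson SU distribution to each TC's null by maximum likelihood and
maps observed activities through its CDF to a standard-normal scale before
computing parametric two-sided p-values — the Johnson step irons
heavy-tailed nulls onto a common scale so per-cell-type box plots are
comparable across TCs; if the fit degenerates the code falls back to plain
z-scoring against the null.

## Synthetic data (`consica.synthetic`)

The generator inverts the mixing model: sparse sources (a fraction
`active_fraction` of genes per component drawn Laplace with scale 3 before
standardization, near-zero Gaussian background elsewhere, active sets
disjoint while capacity allows), standard-normal activities (so |weight| ≥
3 and per-SD hazard ratios keep their z-like reading), Gaussian expression
noise, exponential proportional-hazards event times with independent
exponential censoring, clinical covariates drawn from frequencies matching
a large early-CRC DFS cohort (53% male, 55% stage 2, about half of MSI /
BRAF / KRAS unknown), directional planted gene sets from one tail of a
component's active genes padded to the minimum size, uniform null sets,
and spatial grids in which one component's activity is boosted inside a
region mask.

Study conditions used by the test suite and `scripts/acceptance.py`
(chosen once, as the package's reference conditions):

- **Source recovery**: 5 sources, 1000 genes, 2% active, 300 samples,
  SNR 10 (noise variance = k/10 of mean per-gene signal variance),
  25 ICA runs.
- **Enrichment**: statistic calibration on a normal-weight TC with 1000
  random sets of 10–100 genes; detection on sparse sources at 2000 genes,
  15% active — the denser tail is needed because the Satterthwaite degrees
  of freedom, roughly the set size, cap the attainable z.
- **Survival selection**: global null with 50 TCs, n = 300, 1000
  permutations, 200 replicates; power with one β = 1 TC, n = 400,
  100 replicates.
- **Forest**: 43 TCs, n = 400, 1000 trees, 50 replicates; the hazard is
  driven by the *dichotomized* causal activity (rate ratio e^1.2 between
  the two groups at the median split), so a true two-group structure
  exists for the proximity clustering to recover. With a continuous
  linear hazard there is no planted partition and no clustering method
  could attain high agreement with a median split.
- **Projection**: split halves of the 300-sample mixture; 10×10 spatial
  grid with a 25-spot boosted region; 2000 pure-noise units for p-value
  uniformity.
- **Determinism**: the full pipeline at reduced scale (1000 genes, 300
  samples, 5 runs, 500 permutations, 200 trees) run twice; the manifest
  (SHA-256 of every artifact plus parameter echo, no timestamps) must be
  byte-identical.

What the generator does **not** emulate: probe-level microarray noise,
RMA, batch/platform effects, correlated gene–gene noise beyond the shared
components, informative or non-exponential censoring, and real gene-set
topology (overlapping pathways). Passing tests therefore demonstrate the
estimators' correctness and calibration under the stated model, not
performance on any particular cohort.

## Numerical and design notes

- All randomness flows through `numpy.random.default_rng`; stage seeds
  derive deterministically from one master seed and stay below 2³¹.
- Gene centering across samples is the single centering convention used by
  PCA, ICA and mixing-matrix least squares.
- Degenerate inputs fail loudly: constant matrices (component selection),
  zero-variance activities (Cox), rank-deficient weight matrices (mixing),
  empty region masks, empty retained TC sets.
- The RSF importance score (candidacy-normalized usage) and the
  Bonferroni-corrected split threshold are this package's definitions,
  selected so that importance stays bounded in [0, 1] and null trees stay
  shallow; other RSF implementations use permutation-based variable
  importance and different stopping rules, and will not match numerically.
- Bonferroni correction for enrichment runs per collection by default.
- `n_perm = 1` is allowed but warned about (< 100 permutations); the FDP
  threshold degenerates gracefully to no selection.

## Known limitations

- The permutation framework recomputes univariate (or
  covariate-efficient-score) p-vectors; a fully multivariate joint model of
  all TCs simultaneously is out of scope.
- The covariate-adjusted permutation path refits the nuisance model per
  permutation with lifelines and is therefore ~100× slower than the
  unadjusted path; use it with scaled-down permutation counts or budget
  accordingly.
- Welch-z calibration on extremely sparse TCs with very small sets is
  approximate (see above).
- The confidence statement of the FDP selection is exact only under
  exchangeability of (time, event) against samples, i.e., under the usual
  permutation-test assumptions. Its calibration is also *boundary-exact*:
  under a global null the probability of any selection equals
  ⌊(1−confidence)(B+1)⌋/(B+1) — e.g. 200/1001 ≈ 19.98% at B = 1000,
  confidence 0.8 — so an empirical replicate estimate of that probability
  will land on either side of the nominal 20% with nearly equal odds. A
  finite-replicate measurement slightly above 1 − confidence is expected
  behavior of a correctly calibrated procedure, not evidence of excess
  false discovery.
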