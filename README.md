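# consica

Consensus independent component analysis of bulk tumor transcriptomes,
with survival-association screening, random-survival-forest patient
stratification, and cross-dataset projection.

## The problem

Bulk expression profiles average the transcriptional output of every
process active in a tissue sample. Processes with subtle patterns — or
patterns masked by dominant ones — are invisible to analyses that work on
the profiles directly. Blind source separation addresses this: model the
profile matrix as a linear mixture

    X = Aᵀ S + E

where each row of **S** (components × genes) is a *transcriptional
component* (TC), a gene-weight vector describing a statistically
independent transcriptional pattern, and **A** (components × samples)
holds each TC's *activity* per sample. Because single ICA runs depend on
their random initialization, `consica` runs ICA repeatedly (default 25
runs after PCA selects the component count at ≥ 85% explained variance),
clusters components that recur across runs (|Pearson r| > 0.9 of gene
weights), averages each cluster into a consensus TC, and keeps TCs whose
cluster drew members from at least half the runs (*credibility index*
≥ 0.5).

Downstream, the package

- annotates TCs by gene-set enrichment: Welch's t between in-set and
  out-of-set gene weights, transformed to a standard-normal **Z**, with
  Bonferroni control and a |weight| ≥ 3 "important gene" rule;
- screens TC activities for association with disease-free survival using
  Cox regression (univariate and adjusted for sex, MSI, BRAF, KRAS,
  location, stage, adjuvant therapy) inside a multivariate permutation
  framework (default 10,000 permutations) that controls the false
  discovery proportion at 5% with 80% confidence;
- stratifies patients with a random survival forest (1000 log-rank-split
  trees, 5 randomly drawn TCs each), clusters the element-wise-summed
  proximity matrix with Ward-D2, and scores per-TC importance;
- projects TCs onto independent bulk, spatial, or single-cell profiles,
  with permutation significance maps (5000 / 3000 permutations; Johnson SU
  normalization for the single-cell path) and |r| > 0.5 robustness
  matching between independent decompositions.

A first-class synthetic-data module generates mixtures with known sparse
super-Gaussian sources, proportional-hazards survival, planted gene sets
and spatially boosted regions, so every stage is testable against ground
truth. See `docs/methods.md` for the full model description and design
rationale.

## Worked example

```python
import numpy as np
from consica import synthetic, cica, enrichment
from consica.survival import permutation_fdr_select

# ground-truth mixture: 5 sparse sources, 300 samples, survival driven by
# the first source's activity (hazard ratio e^0.8 per SD)
src = synthetic.generate_sources(n_genes=1000, n_components=5,
                                 active_fraction=0.1, seed=1)
X, A_true = synthetic.generate_expression(src, n_samples=300,
                                          activity_sd=1.0, noise_sd=0.5, seed=2)
surv = synthetic.generate_survival(A_true, hazard_betas=[0.8, 0, 0, 0, 0], seed=3)

tcs, mixing = cica.decompose(X, n_runs=25, master_seed=4)
print(f"consensus TCs: {tcs.n_components}, credibility: {np.round(tcs.credibility, 2)}")

sets = synthetic.generate_gene_sets(src, n_null_sets=50,
                                    set_size_range=(10, 100), seed=5)
table = enrichment.enrichment_table(tcs, enrichment.filter_gene_sets(sets, tcs.gene_ids))
top = table[table.bonferroni_significant].iloc[0]
print(f"top enrichment: {top.set_id} on {top.tc_id}, z = {top.z_score:.2f}")

sel = permutation_fdr_select(mixing, surv, n_perm=1000, seed=6)
print(f"DFS-associated TCs: {sel.selected} (p threshold {sel.p_threshold:.2e})")
```

prints

```
consensus TCs: 5, credibility: [1. 1. 1. 1. 1.]
top enrichment: planted_TC1_0 on TC1, z = 6.55
DFS-associated TCs: ['TC1'] (p threshold 1.50e-22)
```

All five planted sources come back with perfect credibility (every one of
the 25 ICA runs contributed a matching component); the gene set planted
inside the first source's positive tail is the strongest enrichment on the
recovered TC (z = 6.55, Bonferroni-significant); and the permutation
framework selects exactly the one TC whose activity was wired to the
hazard, at a p-value far below the permutation threshold.

The same stages are available from the shell:

```bash
consica run-all --outdir run1 --seed 7          # full synthetic pipeline
consica decompose --expression expr.tsv --out run2 --runs 25 --seed 7
consica survival --mixing run2_mixing.tsv --clinical clinical.csv \
        --out run2 --nperm 10000 --fdr 0.05 --confidence 0.8 --seed 7
```

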