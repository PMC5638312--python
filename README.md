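# genoclim

Two-track analysis toolkit for phylogeographic studies that combine
codominant microsatellite genotypes with ecological niche modeling:

**Genetics track** — per-locus and per-group diversity statistics
(observed/expected heterozygosity, fixation index, rarefied allelic
richness and private allelic richness with exact hypergeometric
combinatorics), gene-diversity decomposition into within/among-group
components, gene-copy-level AMOVA with permutation tests, pairwise F_ST,
contingency chi-square heterogeneity tests, shared-allele and Nei–Li
distances with neighbor-joining trees and locus-bootstrap supports,
genotype PCA, and a STRUCTURE-style Bayesian admixture Gibbs sampler
with Evanno delta-K model choice.

**ENM track** — occurrence thinning at a great-circle radius, Gaussian
kernel-density sampling-bias grids, Pearson correlation pruning of
covariate stacks, an L1-regularized maximum-entropy presence/background
model (linear/quadratic/product/hinge/threshold features, published
default regularization schedules), block cross-validation tuning over a
regularization-multiplier × feature-class grid with AUC/omission/AIC_c
metrics and delta-AIC_c selection, projection onto alternative climate
stacks with clamping, and Schoener's D niche overlap.

A synthetic-data module (Balding–Nichols genotypes, smoothed-noise
landscapes with known log-linear suitability, biased occurrence
sampling, affine "paleo" climate shifts) makes every stage testable with
no external data.

## Test

```sh
python -m pytest -q tests/
```

The suite includes unit tests per module, hypothesis property tests, and
`tests/test_acceptance.py` with worked-example and simulation-recovery
criteria. Three tests skip unless external supplementary data tables are
placed under `tests/data/` (see the skip messages).

## CLI

```sh
# generate a complete synthetic fixture set (genotypes, occurrences, rasters)
genoclim simulate --out fixtures --seed 1

# genetics track: tables, NJ tree, PCA, admixture scan, IDW surfaces
genoclim genetics config.yaml

# ENM track: thinning, bias grid, tuning, projections, overlap matrix
genoclim enm config.yaml

# one-off utilities
genoclim project --model out/selected_model.json --layer cov1 cov1.asc ... --out pred.asc
genoclim overlap pred_a.asc pred_b.asc
```

A config is a flat YAML file; keys mirror `genoclim.pipeline.RunConfig`:

```yaml
output_dir: out
genotypes: fixtures/genotypes.csv          # genetics track
occurrences: fixtures/occurrences.csv      # ENM track
rasters: {cov1: fixtures/cov1.asc, cov2: fixtures/cov2.asc}
thin_km: 10
k_range: [2, 6]
k_replicates: 5
background_size: 10000
seed: 1
```

Genotype tables are CSV/TSV with an `accession` column, optional
`group`/`lon`/`lat` columns, and two columns per locus (`L1_1,L1_2`) or
one `a/b` column; a GenePop-dialect reader is also provided. Rasters use
the ESRI ASCII grid text format.

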