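# cortasym

Population-level cortical asymmetry analysis on synthetic surface data:
consensus delineation of asymmetric regions across datasets, lifespan
trajectory modeling of hemispheric difference, interregional asymmetry
covariance, twin- and SNP-based heritability, and an association screen —
every stage exercisable against planted ground truth.

## Who this is for

Researchers studying structural brain asymmetry typically combine several
analyses: vertex-wise left/right comparison on a symmetric surface
template, cross-dataset consensus clustering, nonlinear mixed models of
hemispheric age trajectories, covariance and replication analysis of
regional asymmetries, and genetic decomposition (GREML on SNP data, AE
models on twins).  `cortasym` packages all of these as tested,
seed-reproducible Python, together with generators that simulate each
stage's inputs with known truth, so the whole pipeline can be validated
end to end without access to restricted cohort data.

## The core quantities

- **Asymmetry index** at homotopic vertices: `AI = (L − R)/((L + R)/2)`,
  positive = leftward, bounded in (−2, 2).
- **Consensus clusters**: vertices with |AI| ≥ threshold (0.05 area /
  0.01 thickness) in ≥ 6 of 7 datasets, edge-connected components ≥
  200 mm².
- **Difference trajectory** from a factor-smooth penalized-spline mixed
  model (cubic B-splines, k = 6, REML):
  `d(age) = (f_L − mean f_L) − (f_R − mean f_R) + β_H`, with pointwise
  CIs from the coefficient posterior and Wald tests for `d ≡ 0` and
  `d` non-constant.
- **Heritability**: `h² = σ²_g/(σ²_g + σ²_e)` from AI-REML under
  `V = σ²_g A + σ²_e I` (SNP) or `a²/(a² + e²)` from AE family
  likelihoods (twin); genetic correlations from the bivariate versions.
- **Mantel test** for replication of cluster-cluster correlation
  matrices (10,000 permutations).

See `docs/methods.md` for the full model descriptions and numerical
choices.

## Worked example

```python
import numpy as np
from cortasym import (build_mesh, mean_ai_map, build_overlap_map,
                      delineate_clusters)
from cortasym.simulate import simulate_datasets

mesh = build_mesh(4, 9e4)                      # 2562-vertex template
datasets, truth = simulate_datasets(mesh, seed=0)   # 7 samples, 30 subjects
maps = [mean_ai_map(obs)[0] for obs in datasets]
overlap = build_overlap_map(maps, threshold=0.05)
clusters = delineate_clusters(overlap, mesh, min_overlap=6, min_area=200.0)
for c in clusters:
    print(c.cluster_id, c.direction, len(c.vertices), round(c.area_mm2, 1))
```

prints

```
L1 leftward 19 672.3
R2 rightward 19 672.3
```

— the two robust planted patches, recovered exactly (Jaccard 1.0 against
the planted supra-threshold sets), while the patch present in only five
datasets and the ~100 mm² patch are excluded by the overlap and size
rules.  Continuing with the lifespan stage:

```python
from cortasym import fit_factor_smooth, difference_trajectory, peak_asymmetry_age
from cortasym.simulate import simulate_lifespan

table, truth = simulate_lifespan(n_subjects=500, seed=0)
fit = fit_factor_smooth(table)                 # REML penalized-spline GAMM
traj = difference_trajectory(fit, np.linspace(*fit.age_range, 100))
peak, _ = peak_asymmetry_age(fit)
print(f"p(asymmetry) = {traj.p_nonzero:.2g}, "
      f"p(change with age) = {traj.p_change:.2g}, peak at {peak:.1f} y")
```

```
p(asymmetry) = 1.8e-263, p(change with age) = 3e-61, peak at 25.0 y
```

— the planted developmental asymmetry peak (24.3 years) is recovered and
both trajectory tests fire.

## The analysis drivers

Numbered scripts under `analysis/` run each study stage end to end and
write summary tables to `results/`:

| script | what it does |
|---|---|
| `01_consensus_mapping.py` | 7-sample AI maps, map correlations, consensus clusters, lateralization proportions |
| `02_lifespan_trajectories.py` | outlier pass, trajectory fit, difference trajectory, peak age, relative change |
| `03_asymmetry_covariance.py` | residualized correlation matrices, Mantel replication, distance decay, global factor |
| `04_heritability.py` | GRM, pruning, GREML uni/bivariate, twin AE uni/bivariate, FDR |
| `05_associations.py` | cognition PC1 via iterative-PCA imputation, 4-predictor screen |

Each takes `--seed` and `--out`.  A thin `cortasym` CLI exposes the same
stages for file-based use (`cortasym simulate`, `map-asymmetry`,
`clusters`, `trajectories`, `covariance`, `heritability`, `associations`).

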