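# covnet — structural covariance network analysis

`covnet` builds and compares **structural covariance networks (SCNs)** from
regional brain-morphometry tables. An SCN is a group-level graph: nodes are
atlas regions, edges are across-subject Pearson correlations of a regional
measure (cortical thickness or structure volume) after age and
intracranial-volume effects have been regressed out. It is aimed at
neuroimaging researchers who already have FreeSurfer-style
`aparcstats2table` / `asegstats2table` outputs and want the standard
graph-theoretic group comparison on top of them.

## What it computes

For each group the positive-rectified correlation matrix
`r_ij = max(0, corr(resid_i, resid_j))` is binarised over a sparsity grid
(default s = 0.05…0.40, step 0.01: at each s the `round(s·N(N−1)/2)`
strongest edges are kept). Per threshold it computes the clustering
coefficient Cp, characteristic path length Lp, global efficiency, nodal
degree/betweenness/nodal/local efficiency, and the small-world indices

    gamma = Cp / Cp_rand,  lambda = Lp / Lp_rand,  sigma = gamma / lambda

normalised against Maslov–Sneppen degree-preserving rewired null graphs
(sigma > 1.1 marks small-worldness). Each property curve is reduced to its
area under the curve (AUC) over the grid, and group differences in these
AUCs are tested by subject-shuffle permutation (or within-pair exchange for
longitudinal two-scan designs), with Benjamini–Hochberg FDR across nodes.

Four atlas node lists are packaged: `desikan_killiany` (68),
`destrieux` (148), `subcortical17` (17), `hipp_amyg_subfields` (56).

## Worked example

```python
from covnet import SCNComparison, SparsityGrid, fixture_spec, generate_cohort

# two synthetic 40-subject cohorts; group B has its block covariance
# lowered from r = 0.7 to r = 0.1 (a planted "covariance loss")
spec_a, spec_b = fixture_spec("effect_17", seed=0)
healthy, patients = generate_cohort(spec_a), generate_cohort(spec_b)

model = SCNComparison(healthy, patients, grid=SparsityGrid(0.10, 0.30, 0.05),
                      properties=["Cp", "Eglob", "sigma", "degree"])
results = model.fit(n_perm=500, n_null=200, n_null_inner=50, seed=1)
print(results.summary())
```

```
Structural covariance network comparison
========================================
design: unpaired   A = 'A'  B = 'B'   statistic: AUC(A) - AUC(B)
atlas: subcortical17 (17 nodes)   grid: 0.1-0.3/0.05
permutations: 500 (seed 1)   small-world fraction A/B: 1.00/0.80

Global properties:
  property     AUC diff   p_perm
  Cp             0.0767   0.0020
  Eglob         -0.0397   0.0180
  sigma          0.9183   0.0579

Nodal properties: 17 tests, 0 significant at FDR q < 0.05
```

Reading the output: the intact group's network is more clustered than the
degraded one across the whole sparsity range (Cp AUC difference +0.077,
permutation p = 0.002 from 500 subject shuffles), slightly *less* globally
efficient (clustered edges are spent locally), and both groups are
small-world over ≥80 % of thresholds. No single node survives FDR — the
planted effect is distributed, not focal.

The same analysis is scriptable from the shell:

```sh
covnet simulate --fixture effect_17 --out sim --seed 0
covnet run --config my_run.yaml         # YAML: tables, atlas, groups, grid, n_perm, seed
covnet run-paired --config followup.yaml
```

Every run writes a deterministic bundle (covariance matrices, metric
curves, AUC tables, permutation results, small-world report, JSON manifest
with the config hash); identical config + seed reproduce it byte for byte.

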