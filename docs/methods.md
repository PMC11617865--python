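# Methods

## The model

A structural covariance network (SCN) is a group-level graph over brain
regions. Given a cohort of subjects with one morphometric value per region
(cortical thickness in mm, or structure volume in mm³), the edge between
regions *i* and *j* is the across-subject Pearson correlation of the two
regional measures. There is exactly one network per group — no
subject-level networks exist in this construction — so group comparison
requires resampling subjects, not averaging networks.

The pipeline is:

1. **Residualisation.** Each regional measure is regressed (OLS, intercept
   always included) on age in years and intracranial volume (ICV) in mm³;
   the residuals replace the raw values. One regression per region is
   fitted pooled across all subjects entering a comparison. Pooled fitting
   keeps genuine between-group covariance differences in the residuals and
   is the common SCN convention; a `per-group` scope is available for
   sensitivity analyses. Covariates are centred internally for
   conditioning only — residuals are invariant to affine rescaling of the
   covariates.
2. **Covariance matrix.** Pearson correlations of the residuals within a
   group, with negative values set to zero: only positive covariance
   defines network edges. The diagonal is exactly zero.
3. **Sparsity thresholding.** At sparsity *s* the strongest
   `round(s·N(N−1)/2)` positive edges are kept and the graph binarised
   (undirected, unweighted). The default grid is s = 0.05 to 0.40 in steps
   of 0.01 (36 thresholds). Rounding is half-up; ties between equal
   correlations are broken by ascending node-index pair, which makes
   thresholding deterministic and edge sets nested across the grid.
4. **Graph properties.** Global: clustering coefficient Cp, characteristic
   path length Lp, global efficiency Eglob. Nodal: degree, unnormalised
   Brandes betweenness, nodal efficiency, local efficiency. Small-world
   indices normalise against Maslov–Sneppen degree-preserving rewired
   graphs: γ = Cp/Cp_rand, λ = Lp/Lp_rand, σ = γ/λ. 1000 rewired
   graphs per threshold are used for reported group curves; the sparsity
   range is conventionally chosen so that >90 % of thresholds give
   σ > 1.1.
5. **AUC summarisation.** Every property curve is integrated over the
   sparsity grid by the trapezoidal rule, giving one threshold-free number
   per property (per node for nodal properties). These AUCs are the test
   statistics.
6. **Permutation inference.** The null distribution of an AUC difference
   re-runs stages 2–5 after relabelling subjects: unpaired designs shuffle
   subjects between groups preserving group sizes; longitudinal designs
   swap the two scans within each subject pair independently. p-values are
   two-tailed. Nodal families are corrected per property across nodes with
   Benjamini–Hochberg FDR (q = 0.05 default). The "backbone" display edges
   of a group are those whose correlation survives a two-tailed t test
   (t = r√((n−2)/(1−r²))) at uncorrected p < 0.001.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| grid | 0.05–0.40 step 0.01 | sparsity thresholds (fraction of possible edges kept) |
| `n_null` | 1000 | rewired graphs per threshold for reported γ/λ/σ curves |
| `n_null_inner` | 100 | rewired graphs per threshold inside each permutation replicate |
| `n_swap_per_edge` | 10 | attempted double-edge swaps per edge when rewiring |
| `n_perm` | 5000 | permutation replicates |
| α / q | 0.05 / 0.05 | significance level and FDR target |
| backbone α | 0.001 | per-edge correlation-significance threshold |

`n_null_inner` < `n_null` is a deliberate tractability deviation: the inner
ensemble only needs to stabilise a difference of ratios, and its Monte
Carlo error enters both the observed and the null statistic symmetrically.

## Numerical and design choices

- **Binary graphs.** Thresholded graphs are unweighted; the sparsity/AUC
  small-world workflow is the standard binary formulation. Consequently
  every statistic depends only on the *ranking* of positive correlations,
  never their magnitudes (thresholding is invariant to monotone
  transforms).
- **Disconnected graphs.** Low-sparsity graphs are routinely disconnected.
  Lp averages finite-distance pairs only; efficiencies use 1/∞ = 0; an
  edgeless graph has Lp = NaN. If a property is NaN at the lowest grid
  values, its AUC is computed on the largest NaN-free suffix of the grid
  (with a warning); an all-NaN curve is an error.
- **σ degeneracy.** If the rewired ensemble has Cp_rand = 0 (very sparse
  graphs with no null triangles), γ and σ are NaN rather than ∞; such
  thresholds count as failures of the σ > 1.1 criterion.
- **Rewiring.** Maslov–Sneppen double-edge swaps preserve the degree
  sequence exactly; 10·E attempted swaps is the standard mixing heuristic.
  Graphs with no legal swap (complete graphs) return unchanged, which
  makes γ = λ = σ = 1 exact there.
- **Permutation estimator.** Monte Carlo p-values use the add-one
  estimator (#{|null| ≥ |obs|}+1)/(n_perm+1), which is valid (never
  anti-conservative) and bounded below by 1/(n_perm+1) — with 5000
  permutations no p below ≈ 0.0002 is attainable, so externally reported
  values like "P < 0.0001" cannot be reproduced by this estimator. When
  the number of distinct relabellings (C(n, n_A) unpaired, 2^n_pairs
  paired) is within `n_perm`, the test switches to exhaustive enumeration
  and p-values are exact proportions.
- **Label-invariance of residualisation.** The permutation contract is
  that the full pipeline is re-run per replicate. With the default pooled
  scope the OLS design contains only intercept + covariates — never group
  — so the residuals are identical under every relabelling and are
  computed once; with `per-group` scope they are genuinely recomputed
  inside every replicate.
- **Determinism.** Every stochastic step takes an explicit seed;
  per-replicate seeds are spawned ahead of the permutation loop, so
  results are bitwise independent of the `n_jobs` worker count.
- **Group sizes.** Correlations are degenerate below 4 subjects (with 2
  they are ±1 exactly); the package warns below 4 but allows ≥ 2 so that
  tiny designs remain exhaustively testable.

## Atlases

Four node lists are packaged: `desikan_killiany` (68 cortical parcels),
`destrieux` (148), `subcortical17`, `hipp_amyg_subfields` (56 = 19
hippocampal subfield + 9 amygdala nucleus labels per hemisphere, matching
FreeSurfer's segmentHA_T1 output vocabulary). The 17-node subcortical list
is 12 bilateral deep-grey structures (left/right interleaved) plus five
cingulate subdivisions (posterior → anterior) taken as bilaterally merged —
the only arithmetic that yields 17 nodes from the listed structures; users
with per-hemisphere cingulate labels should supply a custom node list.

## What the synthetic generator emulates — and what it does not

`covnet.synthetic` draws regional values from a multivariate normal whose
correlation matrix is block-constant: anatomically coherent node sets
(thalamus + basal ganglia, hippocampus + amygdala, cingulate) share a
within-block correlation r on a weak background r0, plus linear age and
ICV effects (the confounds the pipeline removes) and independent
measurement noise. Defaults mirror a realistic elderly cohort: 40 subjects
per group, age ~ N(60, 9.4²) years, ICV ~ N(1.45·10⁶, (1.4·10⁵)²) mm³,
volumes ~4000 mm³ with 10 % between-subject SD, −15 mm³/year age slope.
Three fixtures are packaged: `null_17` (both groups from one generator,
r = 0.6/r0 = 0.1 — also the "well-conditioned" cohort whose thresholded
networks are small-world across >90 % of the default grid), `effect_17`
(block r 0.7 vs 0.1 — a strong planted covariance loss), and `paired_8`
(8 subject pairs, within-subject correlation 0.7, one block's r reduced by
0.4 at the second scan).

The generator is Gaussian by construction (the pipeline's own assumption):
it has no heavy tails, no site or scanner effects, no segmentation error,
no spatially varying noise, and block-constant rather than hierarchical
covariance. Passing tests therefore demonstrate correctness and
calibration of the *method* under its stated model, not robustness of the
method to real-MRI artefacts.

## Problem sizes used in the validation suite

The test suite scales simulations to desk size as its own design choice:
type-I-error calibration uses 200 replicate datasets of 20+20 subjects on
a reduced 0.10–0.30/0.05 grid with 500 permutations and 20 inner nulls;
planted-effect recovery uses 100 runs of the 40+40 `effect_17` fixture
with 200 permutations on the full grid; exhaustive-enumeration checks use
2+2 and 8-pair designs where all 6 and 256 relabellings are enumerated.

## Known limitations

- **Paired-design power.** Group-level SCN statistics are computed from
  correlation matrices whose sampling error at follow-up-scale cohorts
  (8–23 pairs) is large, and the within-pair exchange null cannot cancel
  it the way a paired mean test would. In simulation, even destroying an
  8-node block's covariance almost completely yields well-under-50 % power
  for the global clustering AUC at those sizes, although the *sign* of the
  difference is recovered in ~80 % of replicates. Users should treat
  non-significant paired global results at small n as uninformative rather
  than as evidence of absence.

- Only positive-rectified, binary, sparsity-thresholded networks; no
  weighted metrics, absolute-threshold mode, or signed networks.
- No nonlinear covariate models and no site harmonisation.
- Nodal efficiency follows the mean-inverse-distance convention; the
  backbone test interprets "group average connections" as per-edge
  correlation significance. Both are the dominant conventions but not the
  only possible readings.
- Lattice-based small-world nulls are not implemented; γ uses rewired
  nulls.
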