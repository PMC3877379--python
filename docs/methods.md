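# Methods

`patreg` predicts continuous cognitive composite scores from
multi-modality brain volumes (gray matter and white matter tissue-volume
maps, and a PET-type functional map) with a high-dimensional pattern
regression, and maps each model's spatial reliance back onto the brain.
This document describes the model, its assumptions, every substantive
parameter, and the numerical choices.

## 1. Problem setting

Each subject contributes up to three registered 3-D volumes on a common
grid (modalities `GM`, `WM`, `PET`), an intracranial volume (ICV), and a
battery of neuropsychological test scores grouped into cognitive
domains (long-term memory, short-term memory, semantic retrieval,
manipulation). For one domain, the target is the **composite score**:
each test is z-normalized over subjects with complete data, and the
composites are the per-subject means of the domain's z-scores
(listwise exclusion of subjects missing any test in the battery).
Volumes are ICV-normalized (multiplied by `reference_icv / subject_icv`)
so head size does not masquerade as signal.

## 2. Pipeline

The pipeline is a leave-k-out cross-validation around a three-step
chain. Everything below the split level sees **training subjects
only**.

### Step 1 — regional feature generation

1. **Correlation map.** For each modality, the voxelwise Pearson
   correlation `r` between intensity and the composite score is computed
   over the training subjects. Voxels constant across subjects get
   `r = 0`.
2. **Watershed clustering.** The magnitude `|r|` is optionally
   Gaussian-smoothed (`pre_smooth_fwhm`, default 0 mm — raw magnitude),
   local maxima of the (smoothed) magnitude (3×3×3 neighborhoods;
   plateaus collapse deterministically to their lowest linear index)
   seed a marker-controlled watershed of the relief `−|r|` restricted
   to the brain mask with 26-connectivity.
   The relief is unsigned because the kernel regressor exploits
   associations of either sign; signed maps are provided separately by
   the GLM baseline.
3. **Spatial-consistency constraint.** Clusters smaller than
   `min_cluster_voxels` (default 10) are merged, smallest first, into
   the 26-connected neighbor whose mean `|r|` is closest; ties break to
   the lowest label. Isolated mask islands smaller than the floor are
   kept as-is. The result is an exact partition of the mask into
   26-connected clusters, verified in tests by an independent
   connected-components oracle.
4. **Feature extraction and ranking.** Features are per-cluster mean
   intensities per subject. For combined-modality runs the per-modality
   features are pooled. Features are ranked by `|r(feature, score)|`
   (ties: GM < WM < PET, then lower cluster label) and truncated to
   `multiplier · (N_c − k_c)` (default multiplier 3; at the default
   cohort scale N_c = 80, k_c = 8 this is 216). An optional hard ceiling
   `f_max` bounds the pool at desk scale.

### Step 2 — RVR with recursive feature elimination

**Relevance vector regression (RVR).** A kernel regressor with an
independent zero-mean Gaussian prior of precision `α_i` per basis
weight and Gaussian noise of variance `σ²`. The basis is an RBF kernel
over the standardized features at the training points plus a bias
column. Hyperparameters follow the classical evidence fixed point:

```
Σ  = (diag(α) + ΦᵀΦ/σ²)⁻¹          μ = ΣΦᵀy/σ²
γᵢ = 1 − αᵢΣᵢᵢ                      αᵢ ← γᵢ/μᵢ²
σ² ← ‖y − Φμ‖² / (n − Σᵢγᵢ)
```

Basis functions with `α > 1e9` are pruned; survivors are the relevance
vectors. Convergence is `max |Δ log α| < 1e-3`. If everything is
pruned (typical of signal-free data) the model degrades to predicting
`mean(y)`. The RBF width defaults to the median heuristic
`γ = 1/(d · median²)` over pairwise distances of the standardized
training features — the one substantive hyperparameter, recorded on
every fitted model. Correctness is anchored by an oracle: with a
common fixed `α` and fixed `σ²`, the posterior mean equals the
closed-form ridge solution.

**RFE.** Backward elimination removes, per iteration, the feature whose
removal minimizes held-out MSE, provided that beats the incumbent;
a forward pass then re-considers eliminated features one at a time,
recovering features that are weak alone but useful jointly. Ties
(within 1e-12) prefer removing the lower-ranked and re-adding the
higher-ranked feature. The kernel width is fixed per split from the
full initial feature set so candidate subsets are compared on a stable
scale. The accepted-step MSEs are strictly decreasing, so the final
subset never scores worse than the full initial set, and the search
needs at most `F(F+1)` fits for `F` features.

**Selection-bias correction.** A naive design scores the RFE on the
same left-out subjects whose predictions are afterwards reported.
That tunes the reported predictions toward their own targets: on a
zero-effect null cohort the
end-to-end prediction correlation measured r ≈ 0.8 against a
permutation null band of ±0.22. `patreg` therefore carves a **tuning
subset** out of the training subjects (the same 10% fraction, drawn
deterministically per split), scores the RFE on it, refits the selected
features on the full training set, and only then predicts the outer
left-out subjects. Selected features and left-out predictions are
provably independent of the validation subjects' scores (asserted by an
instrumentation test that shuffles them), and the null-cohort
correlation falls inside its permutation band.

### Step 3 — cross-validation and aggregation

`k_c = round(0.1 · N_c)` subjects are left out per split. Enumerating
all leave-k-out subsets is infeasible (`C(80,8) ≈ 3·10¹⁰`), so a greedy
quota scheduler draws `R` balanced random splits: validation counts per
subject differ by at most one and every subject is left out at least
`floor(R·k/N)` times; the scheduler refuses configurations that cannot
cover every subject. `R` is the central free parameter (default 100;
the acceptance runs use 50 and 10). Left-out predictions are averaged
per subject over the splits that left them out.

## 3. Contribution maps and evaluation

**Discriminative direction.** For each training subject the minimal
feature-space change that moves the prediction toward the actual score
is `sign(actual − predicted) · ∇f/‖∇f‖`, with the analytic RBF
gradient (verified against finite differences). A feature's
contribution is the mean absolute component of this direction over
subjects. Contributions are painted onto their clusters' voxels,
averaged over splits, and min–max normalized **jointly across the
modality set** to [0, 1], so per-modality maps stay mutually
comparable. A categorical modality-maximum map takes the argmax
modality per voxel (ties: GM > WM > PET; 0 where all are zero).

**Accuracy.** MSE mean ± SD and a percentile 95% interval over splits,
plus the Pearson correlation (with t-based p) between averaged
left-out predictions and actual composites.

**Model comparison.** A paired permutation test: per iteration each
subject's two predictions are swapped with probability ½ and the
statistic difference (prediction–score correlation by default, MSE
optionally) recomputed; the two-sided p uses the add-one rule over
10,000 iterations by default. Calibration is verified empirically
(type-I error at α = 0.05 on equally uninformative model pairs).

**GLM baseline.** A conventional mass-univariate map: per-voxel
(partial) Pearson correlation and t statistics of intensity against the
composite, with optional covariate residualization via QR.

## 4. Synthetic cohorts

Real cohort data are not redistributable, so the package generates
cohorts with known ground truth. One latent trait `z ~ N(0,1)` per
subject drives everything: each modality gets `n_regions` disjoint
spherical regions inside an ellipsoid mask where intensity is
`base + β·z`, plus spatially smoothed Gaussian noise (kernel-normalized
so the marginal voxel SD is preserved), scaled by a per-subject ICV
factor. Test scores are `z + ε` with `ε ~ N(0, σ_y²)`, giving the
analytic calibration `corr(test, z) = 1/√(1+σ_y²)` and a center-voxel
correlation of `β/√(β²+σ_noise²)` that the tests check within Fisher-z
intervals. `make_null_cohort` zeroes every `β` while keeping geometry
and traits — the negative control. The default desk scale is 80
subjects on a 32³ grid of 2 mm voxels, two regions per modality of
radius 3 voxels. The phantom deliberately omits realistic anatomy,
registration error, and scanner artifacts; it exists to make planted
signal recoverable and absence of signal testable.

## 5. Parameter summary

| Parameter | Default | Rationale |
|---|---|---|
| smoothing FWHM (input volumes) | 8 mm GM/WM, 12 mm PET | conventional preprocessing scales for structural vs functional maps |
| `pre_smooth_fwhm` (watershed markers) | 0 mm | marker smoothing merges basins beyond the scale of compact effects: at 2–4 mm, clusters measured 3–7× larger than planted regions and truth voxels were diluted ~4:1 inside their basin, degrading both held-out MSE and map localization; raw-magnitude markers keep basins at the effect scale (the input volumes are already spatially smoothed, so the relief is regular) |
| `min_cluster_voxels` | 10 | noise-basin floor; the spatial-consistency constraint |
| ranking multiplier | 3 | cap `3·(N_c−k_c)` ties model capacity to the training sample |
| `f_max` | 60 (runs use 40) | desk-scale ceiling on the RFE pool; the search is quadratic in pool size |
| `k_fraction` | 0.1 | 10% leave-out |
| `n_splits` (R) | 100 (acceptance 50/10) | balanced random approximation to all leave-k-out subsets |
| RBF `γ` | median heuristic | scale-free width; recorded per model |
| `alpha_prune` | 1e9 | precision divergence threshold |
| RVR `tol` / `max_iter` | 1e-3 / 500 | fixed-point convergence |
| `CVConfig.rvr_max_iter` | 40 | inner RFE fits: held-out MSE is flat beyond a few dozen updates while cost keeps growing with the slow divergence of pruned precisions |
| permutation iterations | 10,000 (calibration runs 1,000) | add-one p resolution |

## 6. Numerical choices

- Feature standardization always uses training statistics; zero-SD
  features standardize with SD 1.
- Posterior solves use a jittered (`1e-10`) Cholesky factorization with
  a pseudo-inverse fallback.
- `σ²` is floored at `1e-9 · var(y)` and its denominator at `1e-6`.
- The RFE evaluates all candidates of an iteration as one batched,
  vectorized EM (per-feature squared-distance blocks; pruning emulated
  by clamping `α` at `1e12`; periodic compaction of pruned columns).
  It is asserted equivalent to the sequential path and is ~10× faster.
- Gaussian smoothing uses `σ = FWHM/(voxel·√(8 ln 2))` with reflective
  boundaries (sum-preserving for interior mass).
- All randomness flows from explicit seeds; derived seeds stay below
  2³¹.

## 7. Limitations

- The synthetic phantom is far simpler than real RAVENS/PET data:
  performance numbers on it bound nothing about clinical data.
- The balanced-random split scheduler is an approximation to the
  combinatorial leave-k-out design; `R` trades runtime for averaging.
- The contribution map is unsigned; directionality must be read from
  the GLM baseline.
- Predictive SDs report the noise floor only (the weight-posterior
  covariance is not propagated).
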