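# Methods

This note documents the models, conventions and design choices behind
`tprm`, in the spirit of a methods appendix: what is computed, under which
assumptions, and what a green test does and does not establish.

## 1. PRM voxel classification

Lung voxels of a co-registered inspiration/expiration HU pair are
classified by joint thresholds:

| class | inspiration HU | expiration HU |
|---|---|---|
| Norm | −950 < i ≤ −810 | e ≥ −856 |
| fSAD | −950 < i ≤ −810 | e < −856 |
| Emph | i < −950 | e < −856 |
| PD   | i > −810 | — |

Only voxels with both scans inside [−1000, −250] HU are classified;
everything else, the indeterminate quadrant (i < −950 with e > −856), and
threshold-boundary values that satisfy none of the printed inequalities
(e.g. i exactly −950, or i < −950 with e exactly −856) are routed to
`Unclassified`.  The inequalities are honoured literally and HU values are
compared exactly, without rounding; whether the original software closes
these boundaries on one side is unknown, so fidelity to the printed rules
was chosen over interpolation of intent.  Percent volume divides each
class count by the total expiratory lung voxel count (Unclassified stays
in the denominator, not in any numerator).

**QC surrogate.** The full clinical QC protocol is not public.  The
package's `qc_flag` checks one physiologic necessity: the expiratory air
volume must be smaller than the inspiratory one, and both must be
plausible (1–10 L).  Because the artifact holds a single expiratory-frame
mask, geometric mask volumes cannot differ between phases; air volumes are
therefore estimated from HU by the standard density decomposition (air
fraction = −HU/1000 inside the mask).  This is a minimal surrogate, not a
reproduction of the original protocol.

## 2. Topological maps

For each class mask, volume density `V` and Euler–Poincaré characteristic
`χ` are evaluated in a 21×21×21-voxel moving window on a grid of every 5th
voxel, then trilinearly interpolated to all lung voxels.

* `χ` is computed on the cubical complex formed by the union of closed
  unit voxels (26-connected foreground): `χ = n₀ − n₁ + n₂ − n₃` over
  vertices, edges, faces and cubes.  This is the standard Minkowski-
  functional convention; the connectivity choice is a package decision
  (the original tPRM description does not state one).  The implementation counts cells
  with vectorised logical shifts; an independent brute-force enumeration
  of cell sets serves as the oracle in the tests, including an exhaustive
  battery of canonical shapes (point, cube, ring, hollow shell, disjoint
  unions) and random volumes up to 31³.
* Per window `W` centred at grid node `c`:
  `V(c) = |class ∩ W| / |lung ∩ W|` and `χ(c) = χ(class ∩ W) / |lung ∩ W|`.
  The denominator of `V` is the same cell-counting volume measure applied
  to the lung mask (the parallel construction of the two normalisations).
* Grid origin is anchored at volume index 0 (recorded in the output
  metadata); windows at the volume boundary are clipped, which the
  in-window lung normalisation compensates.  Nodes whose window contains
  no lung are invalid and are filled from the nearest valid node before
  interpolation; lung voxels outside the grid hull take nearest-node
  values (implemented as constant extension by coordinate clipping).
* Whole-lung means are arithmetic means of the interpolated fields over
  the lung mask; the mean of `V` equals percent volume / 100 up to window
  discretisation (verified to 0.02 on phantoms).

Mean breadth and surface area are deliberately out of scope.

## 3. Synthetic phantoms

A phantom is an ellipsoidal "lung" (semi-axes 0.45× the grid extent,
default grid 45³ at 0.65 mm isotropic — typical CT in-plane resolution,
which makes the cm-distance line profiles meaningful) whose voxels start
as Norm.  Lesions are painted as digital spheres:

* **fSAD pockets.** Either an exact pocket count (`n_fsad_pockets`) or a
  target lung fraction.  A `coalescence` parameter in [0, 1] controls the
  spatial arrangement: at 0, exact-count pockets are rejection-sampled
  with a minimum centre distance so they are disjoint (each convex pocket
  contributes +1 to `χ`); as it rises, centres concentrate into a cluster
  ball whose target fill fraction grows to ≈ 0.45 — the regime where
  overlapping spheres form a tunnelled mesh and `χ` goes negative.  The
  fill is deliberately capped there: beyond ≈ 0.6 a Boolean-sphere union
  saturates into a solid blob and `χ` returns to +1, which would break the
  documented monotone pocket→mesh behaviour.
* **Lesion focus.** Pocket placement can be restricted to a sub-ellipsoid
  (default radius 0.7 of the lung semi-axes, random centre) so abnormality
  is spatially localised — the planted region against which patch-map
  co-localisation is scored.
* **HU synthesis.** Each class's (inspiration, expiration) HU pair is
  drawn uniformly inside its admissible threshold rectangle shrunk by a
  margin of 0.5 + 3·σ HU, after which Gaussian noise of SD σ is added.
  At σ = 0 every voxel lies strictly inside its class rectangle, so PRM
  classification recovers the planted labels exactly; at σ > 0
  misclassification is possible but controlled (≈ 3-sigma margin).
* The pocket/coalescence model is a package design: the tPRM literature
  describes the pocket-versus-mesh contrast qualitatively but provides no
  generative model of fSAD spatial structure.

**What phantoms do not emulate:** airway trees, registration error,
scanner kernels and calibration drift, anatomical lobe structure, or the
HU texture of real parenchyma.  A green phantom test establishes the
correctness of the computational chain, not clinical performance.

## 4. Synthetic cohorts

`generate_cohort` emulates the structure of a large smoking cohort:

* GOLD grade sampled from a configurable distribution (default roughly
  43/12/8/19/12/6 % for GOLD 0/PRISm/GOLD 1–4); per-grade spirometry
  (FEV₁ %predicted, FEV₁/FVC, FEF₂₅₋₇₅) drawn from Gaussians with the
  published per-grade means/SDs, truncated into each grade's defining box
  so labels and spirometry are mutually consistent.
* Exactly `round(fast_fraction · n)` subjects are fast progressors; their
  annualised slopes are drawn in [−max_drop, −61] ml/yr (max_drop scaled
  to baseline FEV₁ so 5-year values stay positive) and slow progressors in
  [−59, +100] ml/yr, each with a 1 ml/yr buffer from the −60 boundary so
  the stored label is reproduced exactly by the slope formula.
* Phantom parameters: fSAD lung fraction ~ N(0.08, 0.03) and coalescence
  ~ N(0.25, 0.10) for slow progressors; fast progressors are shifted
  upward by `effect_size` SDs on both.  Base draws happen before labels
  are applied, so `effect_size = 0` yields label-independent parameters by
  construction.  Emphysema (~1.5%) and PD (~4%) burdens are small and
  label-independent.

## 5. Decline prediction

* **Split.** Stratified 35/65 train/test split with per-class training
  counts `round(0.35 · class size)`.
* **Patches.** Multi-channel patches (V_Norm, V_fSAD, χ_Norm, χ_fSAD) at
  random in-lung centres; a patch must lie inside the volume and cover
  ≥ 50% lung.  Channels are rescaled to unit variance using training
  statistics stored in the model — without this, χ (magnitude ~10⁻³)
  would be invisible next to V (~1) in the L2 residual.
* **Dictionaries.** One per class, learned by alternating OMP sparse
  coding (≤ T atoms per patch) with atom-wise updates (approximate K-SVD:
  rank-1 refit of each atom on its users), atoms kept unit-norm; dead
  atoms are re-seeded from the worst-reconstructed patch.  The objective
  is tracked per iteration and the previous dictionary is kept if an
  iteration fails to improve, making it non-increasing by construction.
  All patches of fast cases are labelled abnormal during training (weak
  case-level supervision; the original patch-labelling rule is not
  public).
* **Classification.** Patch → class of the dictionary with the smaller
  sparse-coding residual, ties to slow/normal (conservative toward the
  majority class).  Case score = abnormal-patch fraction; label fast at
  a threshold of 0.5 (the original aggregation rule is not published).
* **Scale.** Full-scale defaults (library API) are 128 atoms, T = 5,
  30 iterations, 500 patches/case, patch edge 21.  The pipeline/test
  profile is scaled to desk hardware: patch edge 7, 40 patches/case,
  24 atoms, T = 3, 10 iterations on 45³ phantoms.  The scaled profile
  keeps the 400-case experiments within minutes while preserving the
  behaviour under test (chance AUC on null cohorts, > 0.9 AUC at 3-SD
  separation, lesion co-localisation).
* **Feature analysis.** mRMR ranking with mutual information on
  8-quantile-binned variables (greedy relevance minus mean redundancy);
  a logistic-regression baseline on the four whole-lung means (ridge
  fallback, flagged, if the unregularised fit does not converge); and a
  stability analysis that retrains single-channel models on resampled
  training patches and fits a Gaussian to the resulting accuracies.

In these synthetic cohorts the class signal (fSAD burden, coalescence)
also moves the whole-lung means, so the logistic baseline is close to the
patch model; the published gap between the two on clinical data reflects
spatial heterogeneity the cohort generator does not attempt to emulate.

## 6. Cohort statistics

* GOLD 1–4 use the standard 80/50/30 %predicted cut-points from the GOLD
  spirometric grading guidelines; published per-grade cohort summary
  statistics are consistent with these.
* Stepwise regression: forward selection with entry p < 0.05 and removal
  p > 0.10 (the conventional p < 0.05 significance level; the exact
  stepwise variant used originally is unpublished), compulsory covariates (age, sex, race,
  BMI, pack-years, CT vendor) forced in every model.  Standardized betas
  come from a z-scored fit; adjusted R² and the SE of estimate from the
  original-scale fit; categorical covariates are reference-coded.
* The fast/slow boundary at −60 ml/yr is fast-inclusive; a 10⁻⁹ tolerance
  keeps ml-printed volumes exactly on the boundary despite binary floats.
* Line profiles sample two fields along a straight segment at ~1 voxel
  steps, both endpoints included, distance in cm from the high-emphysema
  endpoint; endpoints that violate the V_Emph > 0.6 / < 0.2 convention
  warn rather than fail.
* Boxplot summaries use linear interpolation of order statistics and
  1.5·IQR whiskers, recorded in the report metadata.

## 7. Numerical and degenerate-input conventions

* Spearman correlation on constant input, AUC on single-class truth,
  stepwise regression on collinear designs, and empty lung masks raise
  explicit `ValueError`s rather than returning NaN.
* All randomness flows through `numpy.random.default_rng` seeds recorded
  in specs, configs and models; pipeline reruns with the same config are
  byte-identical on CSV outputs.
* Phantom grids must be ≥ 45 voxels per axis (two windows plus stride);
  the window must be odd and the class mask a subset of the lung mask.

## 8. Known limitations

* The boundary-value routing (threshold equalities → Unclassified) may
  differ from the original closed-source implementation.
* Windowed `χ` of small phantoms is boundary-dominated: windows clipped at
  the lung edge carry few lung voxels and hence large normalised values;
  real lungs (10⁷ voxels) are interior-dominated.  Sign behaviour is
  robust; magnitudes are not comparable across lung sizes.
* The dictionary-learning profile at desk scale uses far fewer patches and
  atoms than a clinical-scale run would; reported AUCs on synthetic
  cohorts characterise the pipeline, not expected clinical performance.
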