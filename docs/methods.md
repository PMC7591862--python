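# Methods

## Anomaly model

The unit of analysis is the voxel-wise connectivity profile: row *i* of the
V×V matrix of Fisher z-transformed Pearson correlations between masked BOLD
time series. Averaging the control connectomes element-wise in z space
yields the reference **R**. A subject's per-voxel similarity is the cosine
between their profile and the reference profile after zeroing negative
entries of both rows independently; discarding negative correlations keeps
the statistic in [0, 1] and interpretable as "how much of the normative
positive connectivity pattern is present". The self-connection is excluded
everywhere (NaN diagonal).

Across *n* controls this gives, per voxel, a distribution of similarities,
summarised by its median and raw MAD (median absolute deviation, no
normal-consistency factor). A subject's anomaly score is
(similarity − median)/MAD; scores below −2.3 MAD units are treated as
highly anomalous. Assumptions: all sessions are pre-aligned to one grid
(registration is upstream of this package); every voxel series has nonzero
variance; the control cohort is large enough (≥ 2, in practice ≥ 20) for a
stable median/MAD.

Tumour handling: the exclusion mask is the union of all five tumour tissue
classes (necrotic, enhancing, non-enhancing, oedema, resection), smoothed
with a 3 mm-FWHM Gaussian (σ = FWHM/2.3548 per axis, in mm) and thresholded
at 5 % of the smoothed peak — a deliberately liberal margin. Excluded
voxels are removed as rows *and* columns from the patient and every control
connectome before the reference, the control similarities and the baseline
are recomputed, so the baseline is patient-specific. On lesioned phantoms,
maps computed with and without this exclusion correlate at r > 0.9
(test suite), i.e. the exclusion guards interpretation rather than driving
the result.

## Downstream analyses

**Attribution.** For each enhancing/necrotic tumour voxel, two distance
fields over non-tumour voxels: Euclidean distance (mm) and functional
distance 1 − |r|, with |r| the back-transformed control-reference
correlation to that tumour voxel. Orienting both predictors as distances
makes "anomaly follows X" equal a positive Pearson correlation between
X-distance and score. Correlations are computed over the highly anomalous
voxels (score < −2.3; a switch uses all non-tumour voxels); a voxel needs
at least 3 such voxels, else it is labelled `none` with a reason code. The
label is the distance kind with the larger positive correlation; no
positive correlation, or an exact tie, gives `none`. Per patient the three
labels are reported as percentages of tumour voxels (summing to 100).

**Symmetry.** Per patient and network, median anomaly in the ipsi- and
contralateral hemisphere (relative to the tumour), separately for cerebrum
and cerebellum. Across patients, the 7×7 matrix of Pearson correlations
between network *i* ipsilateral and network *j* contralateral; diagonal
excess (mean diagonal r² minus mean off-diagonal r²) is tested by permuting
the network identity of the contralateral columns. Because a column
relabeling leaves the r² matrix unchanged, the permutation null is
evaluated exactly from the observed matrix over all 7! relabelings.

**Lesion maps.** Voxel v's count of tumour voxels t with reference
z(v, t) > atanh(0.25) (threshold configurable; swept in the overlap
analysis). "Overlap" across patients is the per-voxel count of binarised
maps. Per cerebellar hemisphere, the lesion-map overlap is correlated with
the thresholded-anomaly overlap at score cuts t ∈ {1.5, 2.0, 2.3, 2.6,
3.0}. A constant overlap map (e.g. zero lesion projection into a
hemisphere) carries no concordance and is reported as r = 0 with a
`degenerate` flag, keeping the ipsi/contra contrast defined.

**Trajectories.** Session 0 (pre-surgery) is the baseline; each later
session's network medians are reported as differences from it. The pooled
(session, Δ-anomaly) points are fitted with a + b·s + c·s²; r² = 1 −
SSE/SST and RMSE characterise the fit. Sessions are indexed 0, 1, 2, …
rather than calendar time.

**Recurrence.** Between consecutive sessions t0, t1: new tumour =
(enhancing ∪ necrotic at t1) minus (enhancing ∪ necrotic ∪ resection at
t0); vicinity = voxels whose centre lies within 10 mm of any t0
tumour/resection voxel centre, excluding those voxels themselves (a rim).
Follow-ups are gated on ≥ 3 cm³ of new enhancing tumour (unsmoothed mask).
The test compares t0 anomaly in future-tumour vs remaining-vicinity voxels:
one-sided (future more anomalous) two-sample permutation on the mean
difference, and the AUC of the negated score as a predictor of
future-tumour membership (midrank ties; U/(n₁n₀)), with an AUC p-value by
label permutation.

**Statistics.** All inference is permutation-based. Sampled permutation
p-values use (b + 1)/(n + 1); enumeration switches to exhaustive when the
assignment count fits the permutation budget, returning the exact fraction
(which includes the observed arrangement, so p > 0 always). Paired
contrasts use sign-flipping on the mean difference. Multiple-testing
control is Benjamini–Hochberg at q = 0.05 (statsmodels implementation
behind the package's interface).

## Synthetic cohorts

**Phantom.** A rectangular 3 mm grid with a cerebral slab and a small
cerebellar slab. Networks are assigned to 2×2×2 voxel blocks (2×2×1 in the
cerebellum) scattered randomly over the left hemisphere and mirrored
exactly to the right; cerebellar voxels carry the *contralateral* cerebral
hemisphere's signal (crossed representation). Scattered blocks — rather
than compact per-network patches — are what make functional proximity and
spatial distance separable estimands: a network's voxels are spread across
the slab, so network co-membership is nearly orthogonal to Euclidean
distance. The demo phantom has ~2,520 masked voxels; a ~560-voxel variant
is used for cohort-scale experiments.

**Signals.** Voxel v: x_v = λ·s_net(v) + η·g_net(v),fhemi(v) + σ·ε_v with
independent unit-variance white signals, so expected Pearson r is
(λ² + η²)/(λ² + η² + σ²) within network and functional hemisphere and
λ²/(λ² + η² + σ²) across hemispheres. Defaults λ = 0.55, η = 0.35, σ = 1,
T = 300: within-network voxel-level r ≈ 0.30 (same functional hemisphere)
and 0.23 (across) — the realistic range for 3 mm voxel-wise resting-state
data after nuisance regression. White signals suffice because every
analysis operates on correlations; temporal autocorrelation would add
nuisance without exercising anything in scope.

**Lesions.** A lesion scales voxel v's structured loadings by
f_v = 1 − γ·p_v and returns the removed variance to the noise term (total
per-voxel variance preserved; at γ = 0 the draw is bit-identical to the
control draw for the same seed). Generative proximity p_v:

- *functional mode* — the fraction of structured variance shared with any
  tumour voxel: (λ²·[same network] + η²·[same network and functional
  hemisphere])/(λ² + η²). With η = 0 this is plain network co-membership.
  Because the cerebellum is crossed, a left-cerebral tumour perturbs the
  right cerebellum more strongly — the generative analogue of crossed
  diaschisis.
- *spatial mode* — exp(−d_v/τ), d_v the mm distance to the nearest tumour
  voxel.

Defining proximity by construction (network membership), not by the
measured correlation, keeps the estimand separate from the estimator in
recovery tests.

**Longitudinal schedules.** Ordered sessions pre → post → follow-ups, each
with its own lesion state and segmentation (pre: enhancing tumour; post:
the same territory relabelled resection; late follow-up: a recurrence site
segmented as enhancing). A *silent* recurrence applies a local spatial-mode
perturbation (τ = 3 mm) at a site that only appears in the segmentation of
a later session — the ground truth for precedence testing.

## Reference experiments and their sizes

The experiment functions in `canomap.experiments` (driven by
`scripts/acceptance.py` and the acceptance tests) fix the study designs:

- *null calibration*: 40 controls + 10 held-out, demo phantom, T = 300;
- *lesion recovery*: γ ∈ {0, 0.3, 0.6, 0.9} with common random numbers,
  plus AUC at γ = 0.8; small phantom, 20 controls, T = 200;
- *attribution*: 20 functional-mode and 20 spatial-mode (τ = 2 voxels)
  phantoms, one patient each;
- *symmetry*: 15 left-tumour patients with γ ~ U(0.3, 0.9) and random
  tumour networks, plus 20 unlesioned null cohorts;
- *crossed cerebellum*: 12 left-tumour patients under a
  hemisphere-dominant model (λ = 0.35, η = 0.55), tumour networks drawn at
  random — uneven network coverage is required, since uniform coverage
  makes the across-patient overlap map constant;
- *recurrence*: 20 lesioned and 20 null (γ = 0) five-session schedules
  with a ~27-voxel recurrence site (large enough that the null AUC
  concentrates near 0.5);
- *statistical calibration*: 2,000 null runs per test, 2,000 1,000-test
  null batches for BH.

These sizes keep the full set at a few minutes on one CPU while leaving
each recovery comfortably away from its decision boundary.

## Numerical choices

- correlations clipped to |r| ≤ 1 − 10⁻⁶ before atanh (finite z for
  perfect correlations in toy data);
- z-space averaging for the reference (configurable to r-space), cosine on
  z values (configurable to r);
- MAD floor 10⁻⁶: voxels below it are invalid (NaN), never ±inf; all-zero
  clipped rows give invalid (NaN) similarity, since cosine is undefined at
  the zero vector;
- exact ties in attribution → `none`, for determinism;
- voxel ordering is lexicographic by (i, j, k) index everywhere, so
  connectome row k always denotes the same voxel; masked-array containers
  carry full-length vectors with NaN at invalid entries;
- all seeds derive from a single study seed through `numpy.SeedSequence`
  channels, making every tabular output byte-reproducible;
- row-block streaming bounds per-subject memory to block × V during
  connectome and similarity computation; the V×V reference matrix itself
  is held dense.

## What the phantom does and does not show

The generator reproduces the *structural* features the analyses rely on —
mirrored seven-network covariance, crossed cerebellum, lesions that
propagate functionally or spatially, variance-preserving perturbation,
silent pre-recurrence anomaly — so passing recovery tests shows the
estimators detect and attribute these effects when present and stay at
chance when absent. It does not emulate haemodynamics, autocorrelated
noise, motion, physiological confounds, registration error, or spatially
smooth network topographies; absolute numbers (e.g. how many MADs a lesion
moves a voxel) are not transferable to real data.

Two behaviours of the phantom's *null* deserve emphasis, because they
differ from an idealised white-noise null and are intrinsic to any
generator with a small number of shared latent signals:

1. **Heavy lower tail of null scores.** A voxel's similarity deficit is a
   quadratic form in the handful of latent signal correlations its profile
   loads on (χ²-like with ~8 effective degrees of freedom), so the
   across-control similarity distribution is left-skewed (skew ≈ −1).
   Around 11 % of held-out-control voxels fall below −2.3 raw-MAD units —
   more than the ≈ 6 % a Gaussian would give — and this fraction is
   essentially invariant to the loading parameters and the phantom size.
   Real data, whose profiles load on many more latent dimensions, can be
   expected to sit closer to (or below) the Gaussian figure. Within-map
   contrasts (lesion recovery, recurrence AUC) are unaffected.
2. **Network-specific ipsi–contra coupling under the null.** The same
   shared cross-hemisphere network signals that let lesions propagate
   bilaterally also make an unlesioned scan's per-network anomaly medians
   genuinely correlated between hemispheres. The diagonal-excess
   permutation test therefore rejects on unlesioned cohorts too (null
   diagonal r² ≈ 0.4–0.5): it is detecting real coupling, not a
   false positive. Interpreting the lesioned-cohort diagonal excess
   (r² ≈ 0.95 vs off-diagonal ≈ 0.03) therefore rests on its magnitude
   relative to this floor, not on the null rejecting cleanly.

## Known limitations

- Euclidean distances only (no geodesic or tract-based distance).
- The dense V×V reference matrix bounds the practical mask size (~60,000
  voxels needs ~29 GB); the streaming layer bounds everything else.
- Session spacing is ordinal; calendar-time modelling is out of scope.
- No partial correlation, covariance shrinkage or tangent-space
  connectivity estimators; no cluster-extent or TFCE inference.
- The CLI drives the bundled synthetic study end-to-end; applying the
  library to real NIfTI data uses the same functions but the cohort
  assembly is the caller's responsibility.
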